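"""Structural geometry: distances, quenching-radius calls, superposition.

All fixtures are small synthetic coordinate sets written as PDB text at
test time; oracles are brute-force arithmetic over the raw coordinates.
"""

import numpy as np
import pytest

from glicgate.structure import (
    Atom,
    StructureModel,
    TRP_RULE,
    TYR_RULE,
    cb_cb_distance,
    classify_pair,
    min_group_distance,
    pair_distance_delta,
    read_structure,
    superpose_rmsd,
)


def pdb_line(serial, name, resn, chain, resi, x, y, z, altloc=" ", hetero=False, elem="C"):
    record = "HETATM" if hetero else "ATOM  "
    return (
        f"{record}{serial:>5d}  {name:<3s}{altloc}{resn:>3s} {chain}{resi:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {elem:>2s}"
    )


def toy_model(offset=0.0):
    """Three residues along x, plus a synthetic bimane-like hetero group."""
    atoms = [
        Atom("A", 1, "ALA", "CA", "C", (0.0 + offset, 0.0, 0.0)),
        Atom("A", 1, "ALA", "CB", "C", (0.0 + offset, 0.0, 0.0)),
        Atom("A", 2, "GLY", "CA", "C", (3.0 + offset, 4.0, 0.0)),
        Atom("B", 1, "TRP", "CA", "C", (10.0 + offset, 0.0, 0.0)),
        Atom("B", 1, "TRP", "CB", "C", (3.0 + offset, 4.0, 0.0)),
    ]
    return StructureModel(atoms=tuple(atoms))


@pytest.fixture()
def minimal_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    lines = [
        pdb_line(1, "CA", "ALA", "A", 1, 1.0, 2.0, 3.0),
        pdb_line(2, "CB", "ALA", "A", 1, 1.5, 2.5, 3.5),
        pdb_line(3, "CA", "GLY", "A", 2, 4.0, 5.0, 6.0),
        "END",
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadStructure:
    def test_minimal_fixture_parsed_exactly(self, minimal_pdb):
        model = read_structure(str(minimal_pdb))
        assert len(model.atoms) == 3
        ca = model.select(chain="A", res_seq=1, atom_name="CA")[0]
        assert ca.xyz == pytest.approx((1.0, 2.0, 3.0))

    def test_altloc_A_preferred(self, tmp_path):
        path = tmp_path / "alt.pdb"
        lines = [
            pdb_line(1, "CA", "SER", "A", 1, 0.0, 0.0, 0.0, altloc="A"),
            pdb_line(2, "CA", "SER", "A", 1, 9.0, 9.0, 9.0, altloc="B"),
            "END",
        ]
        path.write_text("\n".join(lines) + "\n")
        model = read_structure(str(path))
        assert len(model.atoms) == 1
        assert model.atoms[0].xyz == pytest.approx((0.0, 0.0, 0.0))

    def test_hetero_group_retained(self, tmp_path):
        path = tmp_path / "het.pdb"
        lines = [
            pdb_line(1, "CA", "VAL", "A", 135, 0.0, 0.0, 0.0),
            pdb_line(2, "C1", "BIM", "A", 900, 1.0, 1.0, 1.0, hetero=True),
            "END",
        ]
        path.write_text("\n".join(lines) + "\n")
        model = read_structure(str(path))
        het = model.select(hetero=True)
        assert len(het) == 1 and het[0].res_name == "BIM"

    def test_unparseable_file_raises(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_bytes(b"\x00\x01 not a pdb")
        with pytest.raises(ValueError):
            read_structure(str(bad))


class TestDistances:
    def test_three_four_five_triangle(self):
        assert cb_cb_distance(toy_model(), "A", 1, "B", 1) == pytest.approx(5.0)

    def test_same_residue_distance_zero(self):
        assert cb_cb_distance(toy_model(), "A", 1, "A", 1) == 0.0

    def test_glycine_falls_back_to_calpha(self):
        assert cb_cb_distance(toy_model(), "A", 1, "A", 2) == pytest.approx(5.0)

    def test_missing_residue_and_atom_named_in_error(self):
        with pytest.raises(KeyError, match="A/99"):
            cb_cb_distance(toy_model(), "A", 99, "B", 1)
        model = StructureModel(atoms=(Atom("A", 1, "LEU", "CA", "C", (0, 0, 0)),))
        with pytest.raises(KeyError, match="CB"):
            cb_cb_distance(model, "A", 1, "A", 1)

    def test_random_pair_matches_brute_force(self):
        rng = np.random.default_rng(1)
        atoms = []
        for chain, resi in (("A", 1), ("B", 2)):
            for name in ("CA", "CB"):
                atoms.append(Atom(chain, resi, "LEU", name, "C", tuple(rng.normal(0, 10, 3))))
        model = StructureModel(atoms=tuple(atoms))
        d = cb_cb_distance(model, "A", 1, "B", 2)
        a = next(x.xyz for x in atoms if x.chain == "A" and x.atom_name == "CB")
        b = next(x.xyz for x in atoms if x.chain == "B" and x.atom_name == "CB")
        manual = sum((p - q) ** 2 for p, q in zip(a, b)) ** 0.5
        assert d == pytest.approx(manual, abs=1e-12)

    def test_min_group_distance_brute_force(self):
        rng = np.random.default_rng(2)
        model = toy_model()
        sel_a = tuple(Atom("A", 5, "BIM", f"C{i}", "C", tuple(rng.normal(0, 5, 3))) for i in range(3))
        sel_b = tuple(Atom("B", 6, "TRP", f"C{i}", "C", tuple(rng.normal(4, 5, 3))) for i in range(3))
        d = min_group_distance(model, sel_a, sel_b)
        brute = min(
            sum((p - q) ** 2 for p, q in zip(a.xyz, b.xyz)) ** 0.5
            for a in sel_a
            for b in sel_b
        )
        assert d == pytest.approx(brute, abs=1e-12)

    def test_single_atom_selections(self):
        a = (Atom("A", 1, "X", "C1", "C", (0.0, 0.0, 0.0)),)
        b = (Atom("B", 1, "Y", "C1", "C", (5.0, 0.0, 0.0)),)
        assert min_group_distance(toy_model(), a, b) == pytest.approx(5.0)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            min_group_distance(toy_model(), (), toy_model().atoms)

    def test_distances_invariant_under_rigid_motion(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(3)
        base = toy_model()
        d0 = cb_cb_distance(base, "A", 1, "B", 1)
        for _ in range(20):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.normal(0, 50, 3)
            moved = StructureModel(
                atoms=tuple(
                    Atom(a.chain, a.res_seq, a.res_name, a.atom_name, a.element,
                         tuple(R @ np.array(a.xyz) + t))
                    for a in base.atoms
                )
            )
            assert cb_cb_distance(moved, "A", 1, "B", 1) == pytest.approx(d0, abs=1e-9)


class TestQuenchClassification:
    @pytest.mark.parametrize(
        "distance,rule,expected",
        [
            (14.9, TRP_RULE, True),
            (15.0, TRP_RULE, True),  # boundary inclusive by convention
            (15.1, TRP_RULE, False),
            (9.9, TYR_RULE, True),
            (10.1, TYR_RULE, False),
        ],
    )
    def test_radius_thresholds(self, distance, rule, expected):
        assert classify_pair(distance, rule) is expected

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(-1.0, TRP_RULE)


class TestSuperposition:
    def grid_model(self, transform=None):
        rng = np.random.default_rng(5)
        coords = rng.normal(0, 8, (12, 3))
        if transform is not None:
            coords = coords @ transform[0].T + transform[1]
        atoms = tuple(
            Atom("A", i + 1, "ALA", "CA", "C", tuple(c)) for i, c in enumerate(coords)
        )
        return StructureModel(atoms=atoms)

    def test_self_superposition_is_zero(self):
        m = self.grid_model()
        rmsd, R, t = superpose_rmsd(m, m)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)

    def test_rigidly_moved_copy_superposes_to_zero(self):
        theta = np.pi / 2
        R90 = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        a = self.grid_model()
        b = self.grid_model(transform=(R90, np.array([10.0, -3.0, 7.0])))
        rmsd, _, _ = superpose_rmsd(a, b)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rmsd_positive_for_distorted_copy(self):
        a = self.grid_model()
        atoms = list(a.atoms)
        atoms[0] = Atom("A", 1, "ALA", "CA", "C", tuple(np.array(atoms[0].xyz) + 2.0))
        b = StructureModel(atoms=tuple(atoms))
        rmsd, _, _ = superpose_rmsd(a, b)
        assert rmsd > 0.1

    def test_too_few_common_atoms_rejected(self):
        a = StructureModel(atoms=(Atom("A", 1, "ALA", "CA", "C", (0, 0, 0)),))
        with pytest.raises(ValueError, match="common atoms"):
            superpose_rmsd(a, a)


class TestPairDeltas:
    def test_identical_structures_unchanged(self):
        m = toy_model()
        reports = pair_distance_delta(m, m, [("A", 1, "B", 1)])
        assert reports[0].classification == "unchanged"
        assert reports[0].delta == 0.0

    def test_constructed_two_angstrom_approach(self):
        closed = toy_model()
        atoms = [
            Atom(a.chain, a.res_seq, a.res_name, a.atom_name, a.element,
                 (a.xyz[0], a.xyz[1] - 2.0 * (a.chain == "B"), a.xyz[2]))
            for a in closed.atoms
        ]
        open_state = StructureModel(atoms=tuple(atoms))
        # pair A1-B1: closed distance 5.0 (3-4-5), open distance 3.0+... B CB moves
        d_closed = cb_cb_distance(closed, "A", 1, "B", 1)
        d_open = cb_cb_distance(open_state, "A", 1, "B", 1)
        reports = pair_distance_delta(closed, open_state, [("A", 1, "B", 1)])
        assert reports[0].delta == pytest.approx(d_open - d_closed)
        assert reports[0].classification == "approach"
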