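"""Structural companion analysis for fluorophore-quencher pairs.

Short-range quenching (tryptophan below ~15 A, tyrosine below ~10 A,
inter-residue distance) makes engineered bimane/aromatic pairs act as
conformational rulers.  This module measures the corresponding
geometry on coordinate models: Cb-Cb distances between residue pairs
(Ca for glycine), minimal heavy-atom distances between a fluorophore
group and a quencher ring, rigid-body superposition RMSD between
conformational states, and per-pair approach/separation calls between
a closed and an open structure.

PDB parsing goes through gemmi; geometry is plain linear algebra
(Kabsch superposition via SVD).
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "StructureModel",
    "QuencherRule",
    "TRP_RULE",
    "TYR_RULE",
    "PairDistanceReport",
    "read_structure",
    "cb_cb_distance",
    "min_group_distance",
    "classify_pair",
    "superpose_rmsd",
    "pair_distance_delta",
]


@dataclass(frozen=True)
class Atom:
    chain: str
    res_seq: int
    res_name: str
    atom_name: str
    element: str
    xyz: tuple[float, float, float]
    hetero: bool = False


@dataclass(frozen=True)
class StructureModel:
    atoms: tuple[Atom, ...]
    model_id: str = "1"

    def __post_init__(self) -> None:
        keys = set()
        for a in self.atoms:
            if not all(np.isfinite(a.xyz)):
                raise ValueError(f"non-finite coordinates for {a}")
            key = (a.chain, a.res_seq, a.atom_name)
            if key in keys:
                raise ValueError(f"duplicate atom record {key}")
            keys.add(key)

    def select(
        self,
        *,
        chain: str | None = None,
        res_seq: int | None = None,
        res_name: str | None = None,
        atom_name: str | None = None,
        hetero: bool | None = None,
        heavy_only: bool = True,
    ) -> tuple[Atom, ...]:
        out = []
        for a in self.atoms:
            if chain is not None and a.chain != chain:
                continue
            if res_seq is not None and a.res_seq != res_seq:
                continue
            if res_name is not None and a.res_name != res_name:
                continue
            if atom_name is not None and a.atom_name != atom_name:
                continue
            if hetero is not None and a.hetero != hetero:
                continue
            if heavy_only and a.element.upper() == "H":
                continue
            out.append(a)
        return tuple(out)

    def coords(self, atoms: tuple[Atom, ...]) -> np.ndarray:
        return np.array([a.xyz for a in atoms], dtype=float)


@dataclass(frozen=True)
class QuencherRule:
    quencher_type: str  # "Trp" | "Tyr"
    max_distance: float  # Angstrom


TRP_RULE = QuencherRule("Trp", 15.0)
TYR_RULE = QuencherRule("Tyr", 10.0)


def read_structure(path: str) -> StructureModel:
    """Parse a PDB file into atom records (first model, altloc A kept).

    Hetero groups (e.g. a covalently linked fluorophore) are retained
    with their deposited residue names.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"unparseable PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.altloc not in ("", "\0", "A"):
                    continue
                atoms.append(
                    Atom(
                        chain=chain.name,
                        res_seq=residue.seqid.num,
                        res_name=residue.name.strip(),
                        atom_name=atom.name.strip(),
                        element=atom.element.name,
                        xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                        hetero=residue.het_flag == "H",
                    )
                )
    if not atoms:
        raise ValueError(f"no atoms parsed from {path}")
    return StructureModel(atoms=tuple(atoms), model_id=str(getattr(model, "num", 1)))


def _reporter_atom(s: StructureModel, chain: str, res_seq: int, selector: str = "CB") -> Atom:
    res_atoms = s.select(chain=chain, res_seq=res_seq)
    if not res_atoms:
        raise KeyError(f"residue {chain}/{res_seq} not found")
    name = selector
    if selector == "CB" and res_atoms[0].res_name == "GLY":
        name = "CA"
    for a in res_atoms:
        if a.atom_name == name:
            return a
    raise KeyError(f"atom {name} missing in residue {chain}/{res_seq} ({res_atoms[0].res_name})")


def cb_cb_distance(
    s: StructureModel,
    chainA: str,
    resA: int,
    chainB: str,
    resB: int,
    *,
    selector: str = "CB",
) -> float:
    """Euclidean Cb-Cb distance between two residues (Ca for glycine).

    ``selector="CA"`` switches to the Ca-Ca convention.
    """
    a = _reporter_atom(s, chainA, resA, selector)
    b = _reporter_atom(s, chainB, resB, selector)
    return float(np.linalg.norm(np.subtract(a.xyz, b.xyz)))


def min_group_distance(
    s: StructureModel, selectionA: tuple[Atom, ...], selectionB: tuple[Atom, ...]
) -> float:
    """Minimum pairwise heavy-atom distance between two atom sets."""
    if not selectionA or not selectionB:
        raise ValueError("both selections must be non-empty")
    A = s.coords(selectionA)
    B = s.coords(selectionB)
    d2 = np.sum((A[:, None, :] - B[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.min()))


def classify_pair(distance: float, rule: QuencherRule) -> bool:
    """Within quenching range? Boundary inclusive (the radii are approximate)."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return distance <= rule.max_distance


def superpose_rmsd(
    sA: StructureModel,
    sB: StructureModel,
    *,
    atom_name: str = "CA",
) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition (Kabsch) on matched atoms.

    Atoms are paired by (chain, residue number, atom name) intersection
    over non-hetero records.  Returns (RMSD in Angstrom, rotation
    matrix, translation vector) mapping B onto A.
    """
    selA = {(a.chain, a.res_seq): a for a in sA.select(atom_name=atom_name, hetero=False)}
    selB = {(a.chain, a.res_seq): a for a in sB.select(atom_name=atom_name, hetero=False)}
    common = sorted(selA.keys() & selB.keys())
    if len(common) < 3:
        raise ValueError(f"only {len(common)} common atoms; need at least 3")
    A = np.array([selA[k].xyz for k in common])
    B = np.array([selB[k].xyz for k in common])
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    U, S, Vt = np.linalg.svd(B0.T @ A0)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = (U @ D @ Vt).T
    B_fit = (R @ B0.T).T + ca
    rmsd = float(np.sqrt(np.mean(np.sum((B_fit - A) ** 2, axis=1))))
    translation = ca - R @ cb
    return rmsd, R, translation


@dataclass(frozen=True)
class PairDistanceReport:
    pair: str
    distance_A: float  # state A (e.g. closed / pH 7)
    distance_B: float  # state B (e.g. open / pH 4)
    delta: float  # B - A, Angstrom
    classification: str  # approach | separation | unchanged


def pair_distance_delta(
    s_closed: StructureModel,
    s_open: StructureModel,
    pairs: list[tuple[str, int, str, int]],
    *,
    tolerance: float = 0.5,
    selector: str = "CB",
) -> list[PairDistanceReport]:
    """Per-pair distance change between two conformational states.

    ``pairs`` rows are (chainA, resA, chainB, resB).  A negative delta
    beyond the tolerance is an "approach" (residues move closer in the
    open state), positive a "separation".
    """
    reports = []
    for chainA, resA, chainB, resB in pairs:
        d_closed = cb_cb_distance(s_closed, chainA, resA, chainB, resB, selector=selector)
        d_open = cb_cb_distance(s_open, chainA, resA, chainB, resB, selector=selector)
        delta = d_open - d_closed
        if abs(delta) < tolerance:
            cls = "unchanged"
        elif delta < 0:
            cls = "approach"
        else:
            cls = "separation"
        reports.append(
            PairDistanceReport(
                pair=f"{chainA}{resA}-{chainB}{resB}",
                distance_A=d_closed,
                distance_B=d_open,
                delta=float(delta),
                classification=cls,
            )
        )
    return reports
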