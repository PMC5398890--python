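"""Kinetic-phase clustering of fitted time constants.

Time constants pooled across sensors and pH conditions are binned on a
log10 grid of width 0.4 anchored at the start of the analysis window
(5.1 ms), so everything faster than the first analyzable point falls in
the "very fast" dead-time phase by construction.  Clusters of occupied
bins separated by empty bins define the kinetic phases (at most three:
fast, intermediate, slow); their boundaries are data-driven, not fixed
constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TauEntry",
    "TauEnsemble",
    "TauHistogram",
    "PhasePartition",
    "log_bin_taus",
    "identify_phases",
    "aggregate_phase_dF",
]

FIT_START = 0.0051  # seconds; dead time + excluded prefix
PHASE_LABELS = ("fast", "intermediate", "slow")


@dataclass(frozen=True)
class TauEntry:
    sensor_id: str
    pH: float
    tau: float  # seconds
    dF_pct: float  # signed relative amplitude, % of maximal variation

    @property
    def direction(self) -> str:
        return "increase" if self.dF_pct > 0 else "decrease"


@dataclass(frozen=True)
class TauEnsemble:
    """Pooled exponential components plus per-trace dead-time amplitudes."""

    entries: tuple[TauEntry, ...]
    deadtime_entries: tuple[TauEntry, ...] = ()

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.tau <= 0:
                raise ValueError("time constants must be positive")

    @property
    def taus(self) -> np.ndarray:
        return np.array([e.tau for e in self.entries])


@dataclass(frozen=True)
class TauHistogram:
    bin_edges: np.ndarray  # log10 seconds
    counts: np.ndarray
    anchor: float  # log10 of the analysis-window start


@dataclass(frozen=True)
class PhasePartition:
    bin_edges: np.ndarray
    cluster_intervals: tuple[tuple[float, float], ...]  # seconds
    labels: tuple[str, ...]
    counts: np.ndarray = field(compare=False, default=None)

    def assign(self, tau: float) -> str:
        """Phase label for a time constant (very-fast below the window)."""
        if tau < 10 ** float(np.min(self.bin_edges)) and tau < self.cluster_intervals[0][0]:
            return "very-fast"
        for (lo, hi), label in zip(self.cluster_intervals, self.labels):
            if lo <= tau <= hi:
                return label
        return self.labels[-1]


def log_bin_taus(
    ensemble: TauEnsemble, bin_width: float = 0.4, *, fit_start: float = FIT_START
) -> TauHistogram:
    """Histogram of log10(tau) on a grid anchored at the fit start."""
    taus = ensemble.taus
    if taus.size == 0:
        raise ValueError("ensemble is empty")
    logs = np.log10(taus)
    anchor = np.log10(fit_start)
    lo_idx = int(np.floor((logs.min() - anchor) / bin_width))
    hi_idx = int(np.floor((logs.max() - anchor) / bin_width)) + 1
    edges = anchor + bin_width * np.arange(lo_idx, hi_idx + 1)
    counts, _ = np.histogram(logs, bins=edges)
    assert counts.sum() == taus.size
    return TauHistogram(bin_edges=edges, counts=counts, anchor=anchor)


def identify_phases(histogram: TauHistogram, max_clusters: int = 3) -> PhasePartition:
    """Partition the tau axis into kinetic phases at empty-bin gaps.

    Runs of occupied bins form clusters; boundaries are drawn through
    the middle of the empty gaps.  Sparse bins (holding at most 10% of
    the pooled counts) do not interrupt a gap: stray components between
    dense clusters are treated as gap noise, though their time
    constants are still assigned to a phase by the tiled intervals.
    When more than ``max_clusters`` runs occur, only the widest gaps
    (resolving ties toward the slow end) act as boundaries and the
    remaining runs merge.  With no gap the histogram is one phase.
    """
    counts = histogram.counts
    if counts.sum() == 0:
        raise ValueError("histogram is empty")
    occupied = counts > 0.10 * counts.sum()
    if not np.any(occupied):
        occupied = counts > 0
    runs: list[tuple[int, int]] = []  # [first_bin, last_bin] inclusive
    i = 0
    while i < counts.size:
        if occupied[i]:
            j = i
            while j + 1 < counts.size and occupied[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1

    gaps = [
        (runs[k + 1][0] - runs[k][1] - 1, k) for k in range(len(runs) - 1)
    ]  # (empty width, left-run index)
    n_boundaries = min(max_clusters - 1, len(gaps))
    chosen = sorted(
        sorted(gaps, key=lambda g: (-g[0], -g[1]))[:n_boundaries], key=lambda g: g[1]
    )

    edges = histogram.bin_edges
    boundary_logs = []
    for width, k in chosen:
        left_edge_idx = runs[k][1] + 1  # first edge inside the gap
        boundary_logs.append(edges[left_edge_idx + width // 2])

    cuts = [edges[0], *boundary_logs, edges[-1]]
    intervals = tuple(
        (10 ** cuts[i], 10 ** cuts[i + 1]) for i in range(len(cuts) - 1)
    )
    labels = PHASE_LABELS[: len(intervals)]
    return PhasePartition(
        bin_edges=edges, cluster_intervals=intervals, labels=labels, counts=counts
    )


def aggregate_phase_dF(
    ensemble: TauEnsemble, partition: PhasePartition
) -> dict[str, dict[str, float]]:
    """Per-phase mean/sd/n of relative amplitude magnitudes (%).

    The very-fast phase aggregates the dead-time amplitudes carried by
    the ensemble; the remaining phases aggregate the exponential
    components assigned to them by the partition.
    """
    groups: dict[str, list[float]] = {"very-fast": [abs(e.dF_pct) for e in ensemble.deadtime_entries]}
    for label in partition.labels:
        groups[label] = []
    for e in ensemble.entries:
        groups[partition.assign(e.tau)].append(abs(e.dF_pct))
    out = {}
    for label, values in groups.items():
        if values:
            arr = np.asarray(values)
            out[label] = {
                "mean_abs_dF_pct": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                "n": int(arr.size),
            }
        else:
            out[label] = {"mean_abs_dF_pct": float("nan"), "sd": float("nan"), "n": 0}
    return out
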