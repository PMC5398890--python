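"""Hill analysis of fluorescence, current and flux dose-response curves.

All fits are performed in proton-concentration space, x = 10^(-pH),
with the Hill form

    y(x) = a * x^nH / (x^nH + EC50^nH)

Decreasing responses are fitted on their mirrored curve (max - y) so a
single functional form serves both directions; the direction is stored.
pH50 = -log10(EC50) by definition.  Comparing the midpoints of a
fluorescence (conformation) curve and a flux (activity) curve detects
an intermediate state: a separation of one pH unit or more means the
conformational change saturates at proton concentrations an order of
magnitude lower than those needed to open the channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseCurve",
    "HillFit",
    "CurveComparison",
    "fit_hill",
    "build_dF_curve",
    "build_dI_curve",
    "compare_curves",
]


@dataclass(frozen=True)
class DoseResponseCurve:
    pH_values: np.ndarray
    responses: np.ndarray
    readout: str  # "dF" | "dI" | "dIf"
    normalization: str = "to-max"
    direction: str = "increase"  # increase | decrease | non-monotonic
    no_variation: bool = False

    def __post_init__(self) -> None:
        ph = np.asarray(self.pH_values, dtype=float)
        if ph.size != np.asarray(self.responses).size:
            raise ValueError("pH_values and responses must have equal length")
        d = np.diff(ph)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("pH_values must be strictly monotonic")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")


@dataclass(frozen=True)
class HillFit:
    a: float
    nH: float
    EC50: float  # proton concentration, mol/L
    direction: str = "increase"
    residual_sd: float = 0.0

    @property
    def pH50(self) -> float:
        return -np.log10(self.EC50)

    def evaluate(self, pH: np.ndarray) -> np.ndarray:
        x = 10.0 ** (-np.asarray(pH, dtype=float))
        return self.a * x**self.nH / (x**self.nH + self.EC50**self.nH)


@dataclass(frozen=True)
class CurveComparison:
    delta_pH50: float
    flag_intermediate: bool
    threshold: float
    labels: tuple[str, str]


def _monotonic_limb(ph: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, str]:
    """Detect direction vs increasing proton concentration; for
    non-monotonic curves keep the dominant limb (largest total change)
    with a warning."""
    order = np.argsort(ph)[::-1]  # decreasing pH = increasing [H+]
    ph_s, y_s = ph[order], y[order]
    d = np.diff(y_s)
    if np.all(d >= -1e-12):
        return ph_s, y_s, "increase"
    if np.all(d <= 1e-12):
        return ph_s, y_s, "decrease"
    # dominant limb: split at the extremum of cumulative excursion
    i_ext = int(np.argmax(np.abs(y_s - y_s[0])))
    left_span = abs(y_s[i_ext] - y_s[0])
    right_span = abs(y_s[-1] - y_s[i_ext])
    if max(left_span, right_span) < 2 * min(left_span, right_span):
        raise ValueError("curve is not Hill-fittable: no dominant monotonic limb")
    warnings.warn("non-monotonic curve; fitting the dominant limb only", stacklevel=3)
    if left_span >= right_span:
        ph_s, y_s = ph_s[: i_ext + 1], y_s[: i_ext + 1]
    else:
        ph_s, y_s = ph_s[i_ext:], y_s[i_ext:]
    return ph_s, y_s, ("increase" if y_s[-1] > y_s[0] else "decrease")


def fit_hill(curve: DoseResponseCurve, *, floating_baseline: bool = False) -> HillFit:
    """Least-squares Hill fit in proton-concentration space."""
    ph = np.asarray(curve.pH_values, dtype=float)
    y = np.asarray(curve.responses, dtype=float)
    if np.unique(ph).size < 4:
        raise ValueError("need at least 4 distinct pH points")
    ph_s, y_s, direction = _monotonic_limb(ph, y)
    x = 10.0 ** (-ph_s)
    # decreasing responses are fitted on their mirror; the mirror level
    # floats so the fit stays exact when the sampled top is unsaturated
    y_fit = np.max(y_s) - y_s if direction == "decrease" else y_s
    free_level = floating_baseline or direction == "decrease"

    a0 = max(np.max(y_fit), 1e-12)
    # midpoint guess: first x where the response crosses half its span
    half = 0.5 * (y_fit.min() + y_fit.max())
    above = y_fit >= half
    ec0 = x[np.argmax(above)] if np.any(above) else np.sqrt(x.min() * x.max())
    p0 = [np.log(a0), np.log(1.5), np.log(max(ec0, 1e-12))]
    if free_level:
        p0.append(0.0)

    def residuals(p):
        a, nH, ec = np.exp(p[0]), np.exp(p[1]), np.exp(p[2])
        base = p[3] if free_level else 0.0
        return base + a * x**nH / (x**nH + ec**nH) - y_fit

    sol = least_squares(residuals, p0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    a, nH, ec50 = np.exp(sol.x[0]), np.exp(sol.x[1]), np.exp(sol.x[2])
    if not (x.min() <= ec50 <= x.max()):
        warnings.warn(
            f"EC50 ({-np.log10(ec50):.2f} in pH units) outside the sampled range",
            stacklevel=2,
        )
    return HillFit(
        a=float(a),
        nH=float(nH),
        EC50=float(ec50),
        direction=direction,
        residual_sd=float(np.std(sol.fun)),
    )


def build_dF_curve(
    intensities_per_pH: dict[float, float],
    normalization: str = "to-SDS",
    *,
    reference_intensity: float | None = None,
    na_threshold: float = 0.10,
) -> DoseResponseCurve:
    """Steady-state fluorescence dose-response curve.

    ``normalization`` is "to-SDS" (divide by the denatured-protein
    intensity, which must be supplied) or "to-max" (divide by the
    intensity at the highest pH recorded).  Curves whose total
    variation is below ``na_threshold`` (10%) of the reference are
    flagged as showing no variation.
    """
    ph = np.array(sorted(intensities_per_pH, reverse=True), dtype=float)
    raw = np.array([intensities_per_pH[p] for p in ph])
    if normalization == "to-SDS":
        if reference_intensity is None:
            raise ValueError("to-SDS normalization requires reference_intensity")
        ref = reference_intensity
    elif normalization == "to-max":
        ref = raw[0]  # highest pH recorded
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if ref <= 0:
        raise ValueError("reference intensity must be positive")
    y = raw / ref
    span = float(np.max(y) - np.min(y))
    rel_ref = y[0] if y[0] > 0 else 1.0
    no_var = span < na_threshold * rel_ref
    # y is listed from the highest pH down, so a falling sequence means
    # fluorescence decreases upon acidification
    d = np.diff(y)
    if np.all(d <= 1e-12):
        direction = "decrease"
    elif np.all(d >= -1e-12):
        direction = "increase"
    else:
        direction = "non-monotonic"
    return DoseResponseCurve(
        pH_values=ph,
        responses=y,
        readout="dF",
        normalization=normalization,
        direction=direction,
        no_variation=no_var,
    )


def build_dI_curve(
    peak_currents_per_pH: dict[float, float],
    exclude_submaximal_lowpH: bool = False,
    *,
    nf_threshold: float = 0.5,
) -> DoseResponseCurve:
    """Peak-current dose-response curve, normalized to the maximum.

    With ``exclude_submaximal_lowpH`` the trailing low-pH points that
    fall below the running maximum (desensitization droop) are dropped
    before fitting.  All-zero or sub-threshold currents (< 0.5 uA)
    raise a "non-functional" error.
    """
    ph = np.array(sorted(peak_currents_per_pH, reverse=True), dtype=float)
    currents = np.array([peak_currents_per_pH[p] for p in ph])
    if np.any(currents < 0):
        raise ValueError("peak currents must be non-negative")
    if np.max(currents) < nf_threshold:
        raise ValueError("non-functional: all peak currents below threshold")
    if exclude_submaximal_lowpH:
        i_max = int(np.argmax(currents))
        keep = np.ones(ph.size, dtype=bool)
        running_max = currents[i_max]
        for i in range(i_max + 1, ph.size):
            if currents[i] < running_max - 1e-12:
                keep[i] = False
        ph, currents = ph[keep], currents[keep]
    y = currents / np.max(currents)
    return DoseResponseCurve(
        pH_values=ph,
        responses=y,
        readout="dI",
        normalization="to-max",
        direction="increase",
    )


def compare_curves(
    fitA: HillFit, fitB: HillFit, threshold: float = 1.0, labels: tuple[str, str] = ("dF", "dIf")
) -> CurveComparison:
    """Midpoint separation between two Hill fits, in pH units.

    ``flag_intermediate`` is set when the separation reaches the
    threshold (default one pH unit: the two processes half-saturate at
    proton concentrations an order of magnitude apart).
    """
    delta = fitA.pH50 - fitB.pH50
    return CurveComparison(
        delta_pH50=float(delta),
        flag_intermediate=bool(delta >= threshold),
        threshold=threshold,
        labels=labels,
    )
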