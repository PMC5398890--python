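"""Synthetic instrument observables for the gating scheme.

Three experiment emulators share one kinetic scheme:

* stopped-flow fluorescence of bimane sensors (pH jump at t = 0,
  2.1 ms mixing dead time, triphasic sampling, Gaussian noise plus a
  slow multiplicative drift, with a matched pH-8 reference trace);
* two-electrode voltage-clamp activation currents (double-exponential
  rise) and peak-current tables whose pH dependence follows the
  scheme's quasi-steady open occupancy;
* sequential-mixing thallium flux assay on ANTS-loaded liposomes with
  lognormal sizes and Poisson channel loading, where intensity relaxes
  pseudo-first-order toward the Stern-Volmer equilibrium level at a
  rate driven by the open probability during the recording.

All randomness flows from one integer seed through per-trace
``numpy.random.SeedSequence`` streams, so any trace is reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .scheme import AllostericScheme, simulate_occupancies, steady_state
from .sensors import SensorModel, observable_fluorescence

__all__ = [
    "StoppedFlowProtocol",
    "StoppedFlowTrace",
    "ActivationParams",
    "FluxAssayConfig",
    "simulate_sf_trace",
    "simulate_tevc_current",
    "simulate_flux_assay",
]


@dataclass(frozen=True)
class StoppedFlowProtocol:
    """Acquisition protocol: dead time, excluded prefix, sampling regimes.

    ``sampling_regimes`` are (start, end, step) triples in seconds that
    must tile the recording contiguously.  The default reproduces a
    30 s recording sampled at 100 us, 1 ms and 50 ms over successive
    intervals, a 2.1 ms mixing dead time and 3 ms of additional early
    data excluded from fits (fits start at 5.1 ms after mixing).
    """

    dead_time: float = 0.0021
    excluded_prefix: float = 0.003
    sampling_regimes: tuple[tuple[float, float, float], ...] = (
        (0.0, 0.5, 1e-4),
        (0.5, 1.5, 1e-3),
        (1.5, 30.0, 5e-2),
    )

    def __post_init__(self) -> None:
        if self.dead_time < 0 or self.excluded_prefix < 0:
            raise ValueError("dead_time and excluded_prefix must be non-negative")
        prev_end = None
        for start, end, step in self.sampling_regimes:
            if not (end > start > -1e-12) or step <= 0:
                raise ValueError("sampling regimes must be increasing with positive step")
            if prev_end is not None and abs(start - prev_end) > 1e-12:
                raise ValueError("sampling regimes must be contiguous")
            prev_end = end

    @property
    def total_duration(self) -> float:
        return self.sampling_regimes[-1][1]

    @property
    def fit_start(self) -> float:
        """Start of analyzable data after mixing (dead time + exclusion)."""
        return self.dead_time + self.excluded_prefix

    def time_grid(self, include_dead_time: bool = False) -> np.ndarray:
        """Strictly increasing sample times (seconds since mixing)."""
        pieces = []
        for start, end, step in self.sampling_regimes:
            n = int(round((end - start) / step))
            pieces.append(start + step * np.arange(n))
        t = np.concatenate(pieces + [np.array([self.total_duration])])
        t = np.unique(t)
        if not include_dead_time:
            t = t[t >= self.dead_time]
        return t

    def sampling_interval(self, t: np.ndarray) -> np.ndarray:
        """Per-point sampling step, for regime-aware fit weighting."""
        dt = np.empty_like(t)
        for start, end, step in self.sampling_regimes:
            dt[(t >= start) & (t < end)] = step
        dt[t >= self.sampling_regimes[-1][1]] = self.sampling_regimes[-1][2]
        return dt


@dataclass(frozen=True)
class StoppedFlowTrace:
    time: np.ndarray
    intensity: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must have the same length")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def simulate_sf_trace(
    scheme: AllostericScheme,
    sensor: SensorModel,
    protocol: StoppedFlowProtocol,
    pH: float,
    seed: int,
    *,
    reference_pH: float = 8.0,
) -> tuple[StoppedFlowTrace, StoppedFlowTrace]:
    """Simulate a stopped-flow trace and its matched pH-8 reference.

    The noiseless signal is the sensor's ensemble fluorescence on the
    protocol grid (samples before the dead time are lost to mixing).
    Both traces receive the same multiplicative drift model
    (1 + drift_rate * t) and independent Gaussian noise.
    """
    t = protocol.time_grid()
    traces = []
    for i, ph in enumerate((pH, reference_pH)):
        occ = simulate_occupancies(scheme, ph, t)
        f = observable_fluorescence(occ, sensor)
        scale = float(np.max(np.abs(f)))
        f = f * (1.0 + sensor.drift_rate * t)
        if sensor.noise_sd > 0:
            rng = _stream(seed, i)
            f = f + rng.normal(0.0, sensor.noise_sd * scale, size=t.size)
        condition = "test" if i == 0 else "pH8-reference"
        traces.append(
            StoppedFlowTrace(
                time=t,
                intensity=f,
                meta={
                    "pH": ph,
                    "sensor": sensor.sensor_id,
                    "condition": condition,
                    "seed": seed,
                    "protocol": {
                        "dead_time": protocol.dead_time,
                        "excluded_prefix": protocol.excluded_prefix,
                        "sampling_regimes": [list(r) for r in protocol.sampling_regimes],
                    },
                },
            )
        )
    return traces[0], traces[1]


@dataclass(frozen=True)
class ActivationParams:
    """Double-exponential activation current parameters (microamps, s)."""

    A1: float = 4.5
    tau1: float = 1.8
    A2: float = 2.2
    tau2: float = 6.5
    C: float = 0.0

    def __post_init__(self) -> None:
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("activation time constants must be positive")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (
            self.A1 * (1.0 - np.exp(-t / self.tau1))
            + self.A2 * (1.0 - np.exp(-t / self.tau2))
            + self.C
        )


def simulate_tevc_current(
    scheme: AllostericScheme,
    pH_series: Sequence[float],
    activation_params: ActivationParams | None = None,
    *,
    i_max: float = 7.0,
    duration: float = 30.0,
    dt: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[str, Any]:
    """Peak-current table and activation traces across a pH series.

    Peak currents follow the scheme's quasi-steady open occupancy
    (desensitization excluded, the "peak before rundown" limit) scaled
    to ``i_max`` microamps.  Activation traces at each pH are the
    double-exponential rise scaled to the same peak.
    """
    params = activation_params or ActivationParams()
    t = np.arange(0.0, duration + dt / 2, dt)
    shape = params.evaluate(t)
    shape_peak = shape[-1] if shape[-1] > 0 else 1.0
    rng = _stream(seed, 7)
    peaks = []
    traces = {}
    for ph in pH_series:
        p_open = steady_state(scheme, ph, truncate=3)[2]
        peak = i_max * p_open
        y = peak * shape / shape_peak
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd * i_max, size=t.size)
            peak = peak + rng.normal(0.0, noise_sd * i_max)
        peaks.append(peak)
        traces[ph] = y
    return {
        "time": t,
        "pH": np.asarray(list(pH_series), dtype=float),
        "peak_current": np.asarray(peaks),
        "traces": traces,
        "params": params,
    }


@dataclass(frozen=True)
class FluxAssayConfig:
    """Liposome population and quench-assay parameters.

    Thallium enters each liposome through its active channels; the ANTS
    intensity relaxes pseudo-first-order toward the Stern-Volmer
    equilibrium 1 / (1 + K_SV * [Tl+]) with a rate proportional to
    (active channels x open probability) / liposome volume.  The
    quencher concentration default is 45 mM (90 mM TlNO3 quenching
    buffer mixed 1:1).
    """

    n_liposomes: int = 300
    mean_diameter_nm: float = 150.0
    diameter_log_sd: float = 0.25
    channels_per_liposome: float = 3.0
    fixed_channel_count: int | None = None  # overrides the Poisson draw
    quencher_concentration: float = 0.045  # mol/L after mixing
    stern_volmer_constant: float = 100.0  # 1/M
    single_channel_influx_rate: float = 58.0  # 1/s per open channel, 150 nm liposome
    leak_rate: float = 0.3  # 1/s, protein-free quench
    noise_sd: float = 0.004
    blocker_active: bool = False
    duration: float = 1.0
    dt: float = 1e-3
    delay_times: tuple[float, ...] = (0.015, 0.025, 0.05, 0.1, 0.2)

    def __post_init__(self) -> None:
        if self.stern_volmer_constant <= 0:
            raise ValueError("Stern-Volmer constant must be positive")
        if self.leak_rate < 0 or self.single_channel_influx_rate < 0:
            raise ValueError("rates must be non-negative")


def simulate_flux_assay(
    scheme: AllostericScheme,
    config: FluxAssayConfig,
    pH: float,
    delay: float,
    seed: int,
) -> tuple[StoppedFlowTrace, StoppedFlowTrace]:
    """ANTS quench trace (1 s) and its no-thallium reference.

    The liposome ensemble is drawn once per call (lognormal diameters,
    Poisson channel counts).  Channels open according to the scheme's
    open-state occupancy O(delay + t), which continues to evolve during
    the recording; the ensemble trace is the volume-weighted average of
    per-liposome intensities.
    """
    if delay < 0.015:
        raise ValueError("delay must be >= 0.015 s (instrument minimum)")
    rng = _stream(seed, 11)
    t = np.arange(0.0, config.duration + config.dt / 2, config.dt)

    diam = config.mean_diameter_nm * np.exp(
        rng.normal(-0.5 * config.diameter_log_sd**2, config.diameter_log_sd, config.n_liposomes)
    )
    volume_factor = (diam / config.mean_diameter_nm) ** 3
    if config.fixed_channel_count is not None:
        channels = np.full(config.n_liposomes, config.fixed_channel_count, dtype=float)
    else:
        channels = rng.poisson(config.channels_per_liposome, config.n_liposomes).astype(float)
    if config.blocker_active:
        channels = np.zeros_like(channels)

    # open probability during the recording, integrated for the
    # pseudo-first-order exponent
    occ = simulate_occupancies(scheme, pH, delay + t + 1e-12)
    p_open = occ[:, 2]
    open_integral = np.concatenate(
        [[0.0], np.cumsum(0.5 * (p_open[1:] + p_open[:-1]) * np.diff(t))]
    )

    f_inf = 1.0 / (1.0 + config.stern_volmer_constant * config.quencher_concentration)
    per_lipo_rate = config.single_channel_influx_rate * channels / volume_factor
    exponent = config.leak_rate * t[None, :] + per_lipo_rate[:, None] * open_integral[None, :]
    intensities = f_inf + (1.0 - f_inf) * np.exp(-exponent)
    weights = volume_factor / volume_factor.sum()
    ensemble = weights @ intensities

    noise = rng.normal(0.0, config.noise_sd, size=(2, t.size)) if config.noise_sd > 0 else np.zeros((2, t.size))
    meta = {
        "pH": pH,
        "delay": delay,
        "seed": seed,
        "condition": "quench",
        "blocker_active": config.blocker_active,
    }
    trace = StoppedFlowTrace(time=t, intensity=ensemble + noise[0], meta=meta)
    reference = StoppedFlowTrace(
        time=t,
        intensity=np.ones_like(t) + noise[1],
        meta={**meta, "condition": "no-Tl-reference"},
    )
    return trace, reference
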