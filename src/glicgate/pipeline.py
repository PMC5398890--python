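"""End-to-end orchestration: simulate -> fit -> bin -> dose-response -> compare.

`generate_fixtures` writes a complete synthetic dataset (stopped-flow
traces with pH-8 references, steady-state intensities, peak-current
tables, flux traces) under a manifest; `run_pipeline` executes every
analysis stage on it and assembles a report with the phase-amplitude
table, the pooled-tau histogram and partition, the Hill-fit table and
the fluorescence/flux midpoint comparison with the intermediate-state
flag.  `intermediate_state_run` is the lightweight end-to-end used for
repeated seeded detection runs (it skips the stopped-flow fits, which
do not enter the midpoint comparison).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np

from . import io
from .doseresponse import DoseResponseCurve, build_dI_curve, compare_curves, fit_hill
from .flux import flux_dose_response, rate_vs_delay
from .phases import TauEnsemble, TauEntry, aggregate_phase_dF, identify_phases, log_bin_taus
from .scheme import AllostericScheme, build_concerted_scheme, build_default_scheme, simulate_occupancies
from .sensors import DEFAULT_SENSORS, SensorModel, observable_fluorescence
from .sfkinetics import decompose_phases, fit_multiexponential, normalize_to_reference
from .simulate import (
    ActivationParams,
    FluxAssayConfig,
    StoppedFlowProtocol,
    simulate_flux_assay,
    simulate_sf_trace,
    simulate_tevc_current,
)

__all__ = [
    "RunConfig",
    "generate_fixtures",
    "run_pipeline",
    "steady_state_intensities",
    "simulate_flux_rates",
    "intermediate_state_run",
]

SF_PH_VALUES = (6.0, 5.0, 4.0)
STEADY_PH_GRID = (7.3, 7.0, 6.5, 6.0, 5.75, 5.5, 5.25, 5.0, 4.75, 4.5, 4.25, 4.0, 3.7, 3.5)
FLUX_PH_GRID = (7.0, 6.0, 5.6, 5.2, 4.8, 4.5, 4.2, 3.9, 3.6)
CURRENT_PH_GRID = (7.3, 6.5, 6.0, 5.5, 5.2, 5.0, 4.7, 4.4, 4.0, 3.7)


@dataclass
class RunConfig:
    sensors: tuple[str, ...] = tuple(DEFAULT_SENSORS)
    sf_pH: tuple[float, ...] = SF_PH_VALUES
    steady_pH: tuple[float, ...] = STEADY_PH_GRID
    flux_pH: tuple[float, ...] = FLUX_PH_GRID
    current_pH: tuple[float, ...] = CURRENT_PH_GRID
    flux_delays: tuple[float, ...] = (0.015, 0.025, 0.05, 0.1, 0.2)
    flux_repeats: int = 3
    seed: int = 1
    outdir: str = "results/run"
    concerted_control: bool = False
    run_stopped_flow: bool = True
    run_flux: bool = True
    run_currents: bool = True

    def scheme(self) -> AllostericScheme:
        return build_concerted_scheme() if self.concerted_control else build_default_scheme()


def steady_state_intensities(
    scheme: AllostericScheme,
    sensor: SensorModel,
    pH_values,
    seed: int,
    *,
    t_steady: float = 30.0,
) -> dict[float, float]:
    """Sensor intensity after ``t_steady`` seconds at each pH (noisy)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(23,)))
    out = {}
    for ph in pH_values:
        occ = simulate_occupancies(scheme, ph, np.array([t_steady]))
        f = float(observable_fluorescence(occ, sensor)[0])
        out[float(ph)] = f + rng.normal(0.0, sensor.noise_sd * f)
    return out


def simulate_flux_rates(
    scheme: AllostericScheme,
    config: FluxAssayConfig,
    pH_values,
    delays,
    repeats: int,
    seed: int,
):
    """Simulate and collect flux traces for every (pH, delay) cell."""
    traces: dict[tuple[float, float], list] = {}
    for i, ph in enumerate(pH_values):
        for j, delay in enumerate(delays):
            cell = []
            for r in range(repeats):
                tr, _ = simulate_flux_assay(
                    scheme, config, ph, delay, seed=seed * 1_000_003 % (2**31) + i * 101 + j * 11 + r
                )
                cell.append(tr)
            traces[(float(ph), float(delay))] = cell
    return traces


def intermediate_state_run(
    seed: int,
    *,
    concerted: bool = False,
    sensor_id: str = "136-101",
    flux_config: FluxAssayConfig | None = None,
    flux_repeats: int = 3,
) -> dict[str, Any]:
    """One seeded end-to-end intermediate-state detection.

    Simulates the steady-state fluorescence dose-response of the chosen
    sensor and the flux-rate dose-response at the 15 ms delay from the
    same scheme (quench rates averaged over ``flux_repeats`` repeat
    traces, as in the assay), Hill-fits both and compares midpoints.
    """
    scheme = build_concerted_scheme() if concerted else build_default_scheme()
    sensor = DEFAULT_SENSORS[sensor_id]
    config = flux_config or FluxAssayConfig()

    intensities = steady_state_intensities(scheme, sensor, STEADY_PH_GRID, seed)
    from .doseresponse import build_dF_curve

    f_curve = build_dF_curve(intensities, normalization="to-max")
    f_fit = fit_hill(f_curve)

    flux_traces = simulate_flux_rates(
        scheme, config, FLUX_PH_GRID, (0.015,), repeats=flux_repeats, seed=seed
    )
    rates = rate_vs_delay(flux_traces, leak_rate=config.leak_rate)
    if_curve, if_fit = flux_dose_response(rates, delay=0.015)
    comparison = compare_curves(f_fit, if_fit, labels=("dF", "dIf"))
    return {
        "pH50_dF": f_fit.pH50,
        "pH50_dIf": if_fit.pH50,
        "delta_pH50": comparison.delta_pH50,
        "flag_intermediate": comparison.flag_intermediate,
        "nH_dF": f_fit.nH,
        "nH_dIf": if_fit.nH,
    }


def generate_fixtures(config: RunConfig, seed: int | None = None) -> Path:
    """Write the full synthetic dataset directory with a manifest."""
    seed = config.seed if seed is None else seed
    outdir = Path(config.outdir) / "dataset"
    outdir.mkdir(parents=True, exist_ok=True)
    scheme = config.scheme()
    protocol = StoppedFlowProtocol()
    manifest: dict[str, Any] = {"seed": seed, "traces": [], "references": []}

    for si, sensor_id in enumerate(config.sensors):
        sensor = DEFAULT_SENSORS[sensor_id]
        ref_written = False
        for pi, ph in enumerate(config.sf_pH):
            trace, reference = simulate_sf_trace(
                scheme, sensor, protocol, ph, seed=seed + 1000 * si + pi
            )
            name = f"sf_{sensor_id}_pH{ph:g}.csv"
            io.write_trace(trace, outdir / name)
            manifest["traces"].append(name)
            if not ref_written:
                ref_name = f"sf_{sensor_id}_ref_pH8.csv"
                io.write_trace(reference, outdir / ref_name)
                manifest["references"].append(ref_name)
                ref_written = True
        intensities = steady_state_intensities(scheme, sensor, config.steady_pH, seed + si)
        io.write_json(intensities, outdir / f"steady_{sensor_id}.json")

    current = simulate_tevc_current(scheme, config.current_pH, seed=seed)
    io.write_json(
        {"pH": current["pH"], "peak_current_uA": current["peak_current"]},
        outdir / "peak_currents.json",
    )

    flux_cfg = FluxAssayConfig()
    flux_traces = simulate_flux_rates(
        scheme, flux_cfg, config.flux_pH, config.flux_delays, config.flux_repeats, seed
    )
    for (ph, delay), repeats in flux_traces.items():
        for r, tr in enumerate(repeats):
            name = f"flux_pH{ph:g}_d{1000 * delay:g}ms_r{r}.csv"
            io.write_trace(tr, outdir / name)
            manifest["traces"].append(name)
    io.write_json(manifest, outdir / "manifest.json")
    return outdir


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage in order and assemble the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scheme = config.scheme()
    protocol = StoppedFlowProtocol()
    report: dict[str, Any] = {"seed": config.seed, "concerted_control": config.concerted_control}

    tau_entries: list[TauEntry] = []
    dead_entries: list[TauEntry] = []
    phase_table = []
    if config.run_stopped_flow:
        for si, sensor_id in enumerate(config.sensors):
            sensor = DEFAULT_SENSORS[sensor_id]
            for pi, ph in enumerate(config.sf_pH):
                trace, reference = simulate_sf_trace(
                    scheme, sensor, protocol, ph, seed=config.seed + 1000 * si + pi
                )
                normalized = normalize_to_reference(trace, reference)
                fit = fit_multiexponential(normalized, protocol=protocol)
                phases_row = decompose_phases(fit)
                phase_table.append(
                    {
                        "sensor": sensor_id,
                        "pH": ph,
                        "deadtime_dF_pct": phases_row.deadtime_dF_pct,
                        "max_dF_pct": phases_row.max_dF_pct,
                        "no_variation": phases_row.no_variation,
                        "components": [
                            {"tau_s": tau, "dF_pct": dfp}
                            for tau, dfp in phases_row.per_component
                        ],
                    }
                )
                if phases_row.no_variation:
                    continue
                dead_entries.append(
                    TauEntry(sensor_id, ph, protocol.fit_start, phases_row.deadtime_dF_pct)
                )
                # keep only components resolved within the recording and
                # with amplitude clearly above the fit noise (2.5 sigma)
                max_dF_abs = phases_row.max_dF_pct / 100.0
                for tau, dfp in phases_row.per_component:
                    amp_abs = abs(dfp) / 100.0 * max_dF_abs
                    if tau <= 30.0 and amp_abs > 2.5 * fit.residual_sd:
                        tau_entries.append(TauEntry(sensor_id, ph, tau, dfp))
        report["phase_table"] = phase_table

        ensemble = TauEnsemble(entries=tuple(tau_entries), deadtime_entries=tuple(dead_entries))
        hist = log_bin_taus(ensemble)
        partition = identify_phases(hist)
        report["tau_histogram"] = {
            "bin_edges_log10_s": hist.bin_edges,
            "counts": hist.counts,
        }
        report["phase_partition"] = {
            "intervals_s": partition.cluster_intervals,
            "labels": partition.labels,
        }
        report["phase_dF"] = aggregate_phase_dF(ensemble, partition)

    hill_table = {}
    from .doseresponse import build_dF_curve

    sensor = DEFAULT_SENSORS["136-101"]
    intensities = steady_state_intensities(scheme, sensor, config.steady_pH, config.seed)
    f_curve = build_dF_curve(intensities, normalization="to-max")
    f_fit = fit_hill(f_curve)
    hill_table["dF_136-101"] = {"pH50": f_fit.pH50, "nH": f_fit.nH, "direction": f_fit.direction}

    if config.run_currents:
        current = simulate_tevc_current(scheme, config.current_pH, seed=config.seed)
        i_curve = build_dI_curve(dict(zip(current["pH"], current["peak_current"])))
        i_fit = fit_hill(i_curve)
        hill_table["dI"] = {"pH50": i_fit.pH50, "nH": i_fit.nH}

    if config.run_flux:
        flux_cfg = FluxAssayConfig()
        flux_traces = simulate_flux_rates(
            scheme, flux_cfg, config.flux_pH, (0.015,), config.flux_repeats, config.seed
        )
        rates = rate_vs_delay(flux_traces, leak_rate=flux_cfg.leak_rate)
        if_curve, if_fit = flux_dose_response(rates, delay=0.015)
        hill_table["dIf"] = {"pH50": if_fit.pH50, "nH": if_fit.nH}
        comparison = compare_curves(f_fit, if_fit, labels=("dF", "dIf"))
        report["comparison"] = {
            "delta_pH50": comparison.delta_pH50,
            "flag_intermediate": comparison.flag_intermediate,
            "threshold": comparison.threshold,
        }
    report["hill_table"] = hill_table
    io.write_json(report, outdir / "report.json")
    return report
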