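"""Stopped-flow analysis: normalization, multi-exponential fits, phases."""

import numpy as np
import pytest

from glicgate.sensors import SensorModel
from glicgate.sfkinetics import (
    decompose_phases,
    fit_activation_current,
    fit_multiexponential,
    infer_tau_upper_bound,
    normalize_to_reference,
    weighted_tau,
)
from glicgate.simulate import ActivationParams, StoppedFlowTrace, simulate_sf_trace

from conftest import multiexp_trace


class TestNormalization:
    def test_trace_identical_to_reference_maps_to_unity(self, scheme, protocol, sensors):
        sensor = SensorModel("x", sensors["136-101"].brightness_per_state, noise_sd=0.0)
        _, ref = simulate_sf_trace(scheme, sensor, protocol, 5.0, seed=1)
        normalized = normalize_to_reference(ref, ref)
        np.testing.assert_allclose(normalized.intensity, 1.0, atol=2e-4)

    def test_constant_scaling_preserved(self, scheme, protocol, sensors):
        sensor = SensorModel("x", sensors["136-101"].brightness_per_state, noise_sd=0.0)
        _, ref = simulate_sf_trace(scheme, sensor, protocol, 5.0, seed=1)
        half = StoppedFlowTrace(time=ref.time, intensity=0.5 * ref.intensity, meta={})
        np.testing.assert_allclose(
            normalize_to_reference(half, ref).intensity, 0.5, atol=1e-4
        )

    def test_shared_drift_is_divided_out(self, scheme, protocol, sensors):
        """A drifting trace normalized by its drifting reference recovers
        the drift-free relative signal within 0.5% RMS."""
        sensor = SensorModel(
            "x", sensors["136-101"].brightness_per_state, noise_sd=0.0, drift_rate=0.001
        )
        trace, ref = simulate_sf_trace(scheme, sensor, protocol, 4.0, seed=1)
        normalized = normalize_to_reference(trace, ref)
        clean = SensorModel("x", sensor.brightness_per_state, noise_sd=0.0, drift_rate=0.0)
        t_clean, r_clean = simulate_sf_trace(scheme, clean, protocol, 4.0, seed=1)
        target = t_clean.intensity / r_clean.intensity
        rms = np.sqrt(np.mean((normalized.intensity - target) ** 2))
        assert rms < 0.005

    def test_grid_mismatch_and_bad_reference_rejected(self, scheme, protocol, sensors):
        trace, ref = simulate_sf_trace(scheme, sensors["136-101"], protocol, 5.0, seed=1)
        short = StoppedFlowTrace(time=ref.time[:-1], intensity=ref.intensity[:-1], meta={})
        with pytest.raises(ValueError, match="grid"):
            normalize_to_reference(trace, short)
        bad = StoppedFlowTrace(time=ref.time, intensity=ref.intensity - 10.0, meta={})
        with pytest.raises(ValueError, match="positive"):
            normalize_to_reference(trace, bad)


class TestMultiExponentialFit:
    def test_single_exponential_exact_recovery(self, protocol):
        trace = multiexp_trace(protocol, offset=0.5, amplitudes=[0.5], rates=[10.0])
        fit = fit_multiexponential(trace, protocol=protocol)
        assert fit.n_components == 1
        assert fit.offset == pytest.approx(0.5, rel=1e-6)
        assert fit.amplitudes[0] == pytest.approx(0.5, rel=1e-6)
        assert fit.rates[0] == pytest.approx(10.0, rel=1e-6)

    def test_triple_exponential_recovery_within_one_percent(self, protocol):
        """Noiseless round trip on a parameter set shaped like a real
        ECD-pair decomposition (9 ms / 100 ms / 2.9 s)."""
        taus = np.array([0.009, 0.1, 2.9])
        trace = multiexp_trace(
            protocol, offset=0.46, amplitudes=[-0.30, -0.10, -0.14], rates=1.0 / taus
        )
        fit = fit_multiexponential(trace, protocol=protocol)
        assert fit.n_components == 3
        np.testing.assert_allclose(sorted(fit.taus), sorted(taus), rtol=0.01)

    def test_rates_sorted_descending(self, protocol):
        trace = multiexp_trace(
            protocol, offset=0.4, amplitudes=[-0.2, -0.1], rates=[0.5, 50.0]
        )
        fit = fit_multiexponential(trace, protocol=protocol)
        assert list(fit.rates) == sorted(fit.rates, reverse=True)

    def test_rate_ordering_stable_under_permuted_starts(self, protocol):
        trace = multiexp_trace(
            protocol, offset=0.4, amplitudes=[-0.2, -0.1], rates=[0.5, 50.0],
            noise_sd=0.005, seed=3,
        )
        a = fit_multiexponential(trace, protocol=protocol, n_rate_seeds=6)
        b = fit_multiexponential(trace, protocol=protocol, n_rate_seeds=9)
        np.testing.assert_allclose(a.rates, b.rates, rtol=1e-3)

    def test_too_few_points_rejected(self, protocol):
        trace = multiexp_trace(protocol, offset=0.5, amplitudes=[0.5], rates=[10.0])
        short = StoppedFlowTrace(time=trace.time[:40], intensity=trace.intensity[:40], meta={})
        with pytest.raises(ValueError, match="at least 50"):
            fit_multiexponential(short, protocol=protocol, fit_start=trace.time[0])

    def test_model_selection_resists_overfitting_single_component(self, protocol):
        """With 2% noise a single-exponential trace should not be read
        as three phases."""
        selected = []
        for seed in range(15):
            trace = multiexp_trace(
                protocol, offset=0.5, amplitudes=[-0.4], rates=[2.0],
                noise_sd=0.02, seed=seed,
            )
            selected.append(fit_multiexponential(trace, protocol=protocol).n_components)
        assert sum(n >= 3 for n in selected) == 0


class TestPhaseDecomposition:
    def test_fully_equilibrated_trace_is_all_dead_time(self, protocol):
        trace = multiexp_trace(protocol, offset=0.6, amplitudes=[1e-9], rates=[5.0])
        fit = fit_multiexponential(trace, protocol=protocol)
        phases = decompose_phases(fit)
        assert phases.deadtime_dF_pct == pytest.approx(-100.0, abs=1e-3)
        for _, dfp in phases.per_component:
            assert abs(dfp) < 1e-3

    def test_bidirectional_amplitudes_sum_to_max_variation(self, protocol):
        """Opposite-sign phases: the maximal variation adds the absolute
        amplitudes (-60% dead time, -30% then +10% components)."""
        t_start = protocol.fit_start
        # positive amplitude coefficients decay downward: choose raw
        # amplitudes whose remaining change from the window start is a
        # 30% decrease then a 10% increase (in baseline units)
        k1, k2 = 20.0, 0.2
        a1 = 0.30 / np.exp(-k1 * t_start)
        a2 = -0.10 / np.exp(-k2 * t_start)
        # dead-time step of -0.60: model(t_start) - 1 = -0.60
        offset = 1.0 - 0.60 - (0.30 - 0.10)
        trace = multiexp_trace(protocol, offset=offset, amplitudes=[a1, a2], rates=[k1, k2])
        fit = fit_multiexponential(trace, protocol=protocol)
        phases = decompose_phases(fit)
        assert phases.max_dF_pct == pytest.approx(100.0, abs=0.5)
        assert phases.deadtime_dF_pct == pytest.approx(-60.0, abs=0.5)
        signed = sorted(dfp for _, dfp in phases.per_component)
        assert signed[0] == pytest.approx(-30.0, abs=0.5)
        assert signed[1] == pytest.approx(10.0, abs=0.5)
        total = abs(phases.deadtime_dF_pct) + sum(abs(d) for _, d in phases.per_component)
        assert total == pytest.approx(100.0, abs=1.0)

    def test_flat_trace_flagged_no_variation(self, protocol):
        trace = multiexp_trace(protocol, offset=1.001, amplitudes=[0.002], rates=[1.0])
        fit = fit_multiexponential(trace, protocol=protocol)
        assert decompose_phases(fit).no_variation

    def test_simulated_loop2_sensor_deadtime_dominates_at_pH4(self, scheme, protocol, sensors):
        trace, ref = simulate_sf_trace(scheme, sensors["33-160"], protocol, 4.0, seed=5)
        fit = fit_multiexponential(normalize_to_reference(trace, ref), protocol=protocol)
        phases = decompose_phases(fit)
        assert abs(phases.deadtime_dF_pct) >= 70.0


class TestTauBoundAndWeightedTau:
    def test_upper_bound_definition(self):
        assert infer_tau_upper_bound(1.0 - np.exp(-1.0), 1.0) == pytest.approx(1.0, rel=1e-12)

    def test_two_ms_completion_implies_submillisecond_tau(self):
        assert infer_tau_upper_bound(0.865, 0.002) == pytest.approx(
            -0.002 / np.log(0.135), rel=1e-9
        )
        assert infer_tau_upper_bound(0.865, 0.002) < 1e-3
        assert infer_tau_upper_bound(0.9, 0.002) < 1e-3

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            infer_tau_upper_bound(1.0, 0.002)
        with pytest.raises(ValueError):
            infer_tau_upper_bound(0.0, 0.002)

    def test_weighted_tau_limits_and_mean(self):
        assert weighted_tau(2.0, 1.5, 0.0, 7.0) == pytest.approx(1.5)
        assert weighted_tau(1.0, 2.0, 1.0, 8.0) == pytest.approx(5.0)
        with pytest.raises(ValueError):
            weighted_tau(0.0, 1.0, 0.0, 2.0)

    def test_reported_weighted_tau_is_consistent_with_amplitude_weights(self):
        # published-style consistency: tau1 = 2.80 s, tau2 = 8.9 s,
        # tau_w = 3.57 s implies a fast-phase weight strictly inside (0, 1)
        w = (8.9 - 3.57) / (8.9 - 2.80)
        assert 0.0 < w < 1.0
        assert weighted_tau(w, 2.80, 1.0 - w, 8.9) == pytest.approx(3.57, abs=1e-9)


class TestActivationFit:
    def test_noiseless_double_exponential_recovery(self):
        t = np.arange(0.0, 30.0, 0.02)
        y = ActivationParams(A1=2.0, tau1=1.5, A2=1.0, tau2=7.0, C=0.0).evaluate(t)
        fit = fit_activation_current(t, y)
        assert fit.A1 == pytest.approx(2.0, rel=1e-6)
        assert fit.tau1 == pytest.approx(1.5, rel=1e-6)
        assert fit.A2 == pytest.approx(1.0, rel=1e-6)
        assert fit.tau2 == pytest.approx(7.0, rel=1e-6)
        assert fit.tau1 <= fit.tau2
        assert fit.tau1 <= fit.tau_w <= fit.tau2

    def test_single_exponential_input_degrades_gracefully(self):
        t = np.arange(0.0, 30.0, 0.02)
        y = ActivationParams(A1=3.0, tau1=2.0, A2=0.0, tau2=5.0).evaluate(t)
        fit = fit_activation_current(t, y)
        assert fit.A2 == 0.0
        assert fit.tau_w == pytest.approx(fit.tau1)
        assert fit.tau1 == pytest.approx(2.0, rel=1e-6)

    def test_default_simulator_kinetics_in_reported_ranges(self, scheme):
        from glicgate.simulate import simulate_tevc_current

        out = simulate_tevc_current(scheme, (4.0,))
        fit = fit_activation_current(out["time"], out["traces"][4.0])
        assert 1.0 <= fit.tau1 <= 2.8
        assert 5.0 <= fit.tau2 <= 8.9
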