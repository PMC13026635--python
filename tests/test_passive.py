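import numpy as np
import pytest

from physio.errors import (
    DegenerateFitError,
    InvalidParameterError,
    NotCorrectedError,
)
from physio.passive import (
    analyze_passive,
    average_sweeps,
    estimate_capacitance,
    estimate_input_resistance,
    estimate_resting,
    estimate_tau_mem,
    fit_biexponential,
)
from physio.synth import (
    PassiveCircuitParams,
    gen_cc_step_response,
    gen_vc_transient,
)
from physio.traceio import CURRENT, VOLTAGE, Sweep, SweepSet

from conftest import flat_voltage_sweep


class TestAverageSweeps:
    def test_identical_sweeps_average_to_themselves(self):
        s = Sweep(np.arange(10, dtype=float), 0.01, kind=CURRENT)
        avg = average_sweeps(SweepSet([s, s]))
        np.testing.assert_array_equal(avg.samples, s.samples)

    def test_opposite_sweeps_average_to_zero(self):
        up = Sweep(np.ones(10), 0.01)
        down = Sweep(-np.ones(10), 0.01)
        np.testing.assert_allclose(
            average_sweeps(SweepSet([up, down])).samples, 0.0)

    def test_noise_shrinks_as_sqrt_of_repetitions(self):
        p = PassiveCircuitParams(noise_sd=5.0, n_repetitions=100)
        ss, _ = gen_vc_transient(p, 7)
        p0 = PassiveCircuitParams(noise_sd=0.0, n_repetitions=1)
        clean, _ = gen_vc_transient(p0, 7)
        resid_sd = np.std(average_sweeps(ss).samples - clean[0].samples)
        assert 0.5 * 0.7 <= resid_sd <= 0.5 * 1.3   # ~sigma/10, +-30%


class TestBiexponentialFit:
    def test_noiseless_parameters_recovered_within_1_percent(
            self, passive_params):
        ss, truth = gen_vc_transient(passive_params, 0)
        fit = fit_biexponential(average_sweeps(ss), 10.0, 20.0)
        assert fit.amplitude_fast == pytest.approx(150.0, rel=0.01)
        assert fit.tau_fast == pytest.approx(0.2, rel=0.01)
        assert fit.amplitude_slow == pytest.approx(50.0, rel=0.01)
        assert fit.tau_slow == pytest.approx(1.0, rel=0.01)
        assert fit.weighted_tau == pytest.approx(truth["tau_w"], rel=0.01)

    def test_single_exponential_input_yields_negligible_second_component(self):
        p = PassiveCircuitParams(amplitude_fast=100.0, tau_fast=1.0,
                                 amplitude_slow=0.0, tau_slow=2.0,
                                 noise_sd=0.0, n_repetitions=1)
        ss, _ = gen_vc_transient(p, 0)
        fit = fit_biexponential(average_sweeps(ss), 10.0, 20.0)
        amps = sorted([abs(fit.amplitude_fast), abs(fit.amplitude_slow)])
        assert amps[0] < 0.01 * amps[1]
        assert fit.weighted_tau == pytest.approx(1.0, rel=0.01)

    def test_flat_trace_fits_to_zero_charge(self):
        flat = Sweep(np.zeros(2000), 0.02, kind=CURRENT)
        fit = fit_biexponential(flat, 0.0, 20.0)
        assert fit.charge == pytest.approx(0.0, abs=1e-6)

    def test_short_window_rejected(self):
        s = Sweep(np.zeros(2000), 0.02, kind=CURRENT)
        with pytest.raises(InvalidParameterError):
            fit_biexponential(s, 0.0, 0.1)


class TestCapacitance:
    def test_single_exponential_closed_form(self):
        from physio.passive import BiexpFit

        fit = BiexpFit(100.0, 1.0, 0.0, 2.0, 0.0, 0.0)
        c = estimate_capacitance(fit, -5.0)
        assert c == pytest.approx(100 * (1 - np.exp(-5)) / 5, rel=1e-9)

    def test_canonical_biexponential_gives_14_65_pf(self):
        from physio.passive import BiexpFit

        fit = BiexpFit(150.0, 0.2, 50.0, 1.0, 0.0, 0.0)
        assert fit.weighted_tau == pytest.approx(0.4)
        assert fit.charge == pytest.approx(73.232, abs=0.01)
        assert estimate_capacitance(fit, -5.0) == pytest.approx(14.65,
                                                                abs=0.01)

    def test_doubling_step_voltage_halves_capacitance(self):
        from physio.passive import BiexpFit

        fit = BiexpFit(150.0, 0.2, 50.0, 1.0, 0.0, 0.0)
        assert estimate_capacitance(fit, -10.0) == pytest.approx(
            estimate_capacitance(fit, -5.0) / 2)

    def test_charge_matches_trapezoid_integral_of_average(self,
                                                          passive_params):
        """Oracle equivalence: closed-form Q from the fit vs numerical
        integration of the baseline-subtracted averaged trace."""
        ss, truth = gen_vc_transient(passive_params, 0)
        avg = average_sweeps(ss)
        fit = fit_biexponential(avg, 10.0, 20.0)
        si = avg.sample_interval
        t_end = 10.0 + 5 * fit.weighted_tau
        seg = avg.slice_time(10.0, t_end + si)
        q_num = np.trapezoid(seg - fit.offset, dx=si)
        assert fit.charge == pytest.approx(abs(q_num), rel=0.02)


class TestInputResistance:
    def test_ohms_law_example(self):
        v = np.concatenate([np.full(500, -76.0), np.full(500, -77.0)])
        s = Sweep(v, 0.02, kind=VOLTAGE, stimulus={"onset_ms": 10.0})
        r = estimate_input_resistance(s, -5.0, (5.0, 10.0), (15.0, 20.0))
        assert r == pytest.approx(200.0)

    def test_zero_deflection_gives_zero(self):
        s = flat_voltage_sweep()
        r = estimate_input_resistance(s, -5.0, (5.0, 10.0), (15.0, 20.0))
        assert r == pytest.approx(0.0)

    def test_recovery_within_2_percent_under_noise(self):
        p = PassiveCircuitParams(true_resistance=150.0, noise_sd=0.05,
                                 n_repetitions=100)
        ss, _ = gen_cc_step_response(p, -5.0, 3)
        avg = average_sweeps(ss)
        r = estimate_input_resistance(
            avg, -5.0, (5.0, 10.0),
            (10.0 + 0.8 * p.cc_step_ms, 10.0 + p.cc_step_ms))
        assert r == pytest.approx(150.0, rel=0.02)


class TestTauMem:
    def test_noiseless_recovery_within_half_percent(self):
        p = PassiveCircuitParams(true_tau_mem=10.0, noise_sd=0.0,
                                 n_repetitions=1)
        ss, _ = gen_cc_step_response(p, -5.0, 0)
        tau = estimate_tau_mem(average_sweeps(ss), 10.0, p.cc_step_ms)
        assert tau == pytest.approx(10.0, rel=0.005)

    def test_instantaneous_step_is_degenerate(self):
        v = np.concatenate([np.full(10, -76.0), np.full(990, -80.0)])
        s = Sweep(v, 0.02, kind=VOLTAGE)
        with pytest.raises(DegenerateFitError):
            estimate_tau_mem(s, 10 * 0.02)

    def test_invariant_to_constant_shift(self):
        p = PassiveCircuitParams(true_tau_mem=6.0, noise_sd=0.0,
                                 n_repetitions=1)
        ss, _ = gen_cc_step_response(p, -5.0, 0)
        avg = average_sweeps(ss)
        tau1 = estimate_tau_mem(avg, 10.0, p.cc_step_ms)
        shifted = Sweep(avg.samples + 30.0, avg.sample_interval,
                        kind=VOLTAGE, stimulus=avg.stimulus)
        tau2 = estimate_tau_mem(shifted, 10.0, p.cc_step_ms)
        assert tau1 == pytest.approx(tau2, rel=1e-6)


class TestResting:
    def test_flat_baseline(self):
        s = flat_voltage_sweep(-76.0)
        assert estimate_resting(s, (0.0, 10.0)) == pytest.approx(-76.0)

    def test_noisy_baseline_within_standard_error(self):
        rng = np.random.default_rng(5)
        n = 2000
        sigma = 0.5
        s = Sweep(-76.0 + rng.normal(0, sigma, n), 0.02, kind=VOLTAGE,
                  stimulus={"onset_ms": n * 0.02}, ljp_corrected=True)
        est = estimate_resting(s, (0.0, n * 0.02))
        assert abs(est + 76.0) < 3 * sigma / np.sqrt(n)

    def test_uncorrected_sweep_refused(self):
        s = flat_voltage_sweep(corrected=False)
        with pytest.raises(NotCorrectedError):
            estimate_resting(s, (0.0, 10.0))

    def test_post_onset_window_refused(self):
        s = flat_voltage_sweep()
        s.stimulus["onset_ms"] = 5.0
        with pytest.raises(InvalidParameterError):
            estimate_resting(s, (0.0, 10.0))


class TestConsistencyAndInvariance:
    def test_rc_product_matches_tau_on_parameter_grid(self):
        """R_in x C (MΩ·pF = µs) agrees with the fitted tau_mem within 5%
        when the cell's true tau equals R·C (noiseless grid)."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            r = rng.uniform(80, 300)
            c = rng.uniform(10, 30)
            tau_true = r * c * 1e-3
            p = PassiveCircuitParams(true_resistance=r,
                                     true_tau_mem=tau_true,
                                     noise_sd=0.0, n_repetitions=1)
            ss, _ = gen_cc_step_response(p, -5.0, 0)
            avg = average_sweeps(ss)
            r_est = estimate_input_resistance(
                avg, -5.0, (5.0, 10.0),
                (10.0 + 0.8 * p.cc_step_ms, 10.0 + p.cc_step_ms))
            tau_est = estimate_tau_mem(avg, 10.0, p.cc_step_ms)
            assert r_est * c * 1e-3 == pytest.approx(tau_est, rel=0.05)

    def test_estimates_invariant_to_repetition_count(self, passive_params):
        import dataclasses

        p1 = dataclasses.replace(passive_params, n_repetitions=1)
        p5 = dataclasses.replace(passive_params, n_repetitions=5)
        c_est = []
        for p in (p1, p5):
            ss, _ = gen_vc_transient(p, 0)
            fit = fit_biexponential(average_sweeps(ss), 10.0, 20.0)
            c_est.append(estimate_capacitance(fit, -5.0))
        assert c_est[0] == pytest.approx(c_est[1], rel=1e-9)


def test_full_passive_battery_on_synthetic_cell(passive_params):
    vc, vc_truth = gen_vc_transient(passive_params, 1)
    cc, cc_truth = gen_cc_step_response(passive_params, -5.0, 1)
    props = analyze_passive(vc, cc)
    assert props.capacitance == pytest.approx(vc_truth["capacitance_pf"],
                                              rel=0.01)
    assert props.input_resistance == pytest.approx(200.0, rel=0.01)
    assert props.tau_mem == pytest.approx(4.0, rel=0.01)
    assert props.resting == pytest.approx(-76.0, abs=0.01)
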