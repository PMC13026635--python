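import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from physio.errors import NoAHPError, NoEventError
from physio.spikes import (
    RampFamily,
    analyze_first_ap,
    ap_amplitude,
    ap_halfwidth,
    detect_events,
    detect_threshold,
    dvdt_extrema,
    first_suprathreshold,
    fit_ahp,
    phase_plane,
)
from physio.synth import (
    ParametricAPParams,
    gen_parametric_ap,
    gen_ramp_family,
    parametric_ap_voltage,
)
from physio.traceio import Sweep, VOLTAGE

from conftest import flat_voltage_sweep


class TestDetectEvents:
    def test_subthreshold_sweep_yields_empty_list(self):
        t = np.arange(0, 30, 0.01)
        v = -76 + 20 * np.exp(-((t - 10) / 3) ** 2)   # hump peaking at -56
        s = Sweep(v, 0.01, kind=VOLTAGE)
        assert detect_events(s) == []

    def test_single_parametric_ap_gives_one_event_containing_peak(
            self, canonical_ap_sweep):
        sweep, truth = canonical_ap_sweep
        events = detect_events(sweep)
        assert len(events) == 1
        t_peak = events[0].peak_index * sweep.sample_interval
        assert t_peak == pytest.approx(truth["t_peak"], abs=0.011)

    def test_two_aps_two_disjoint_windows(self):
        p = ParametricAPParams(ahp_tau=0.3, ahp_depth=3.0, tail_ms=0.2)
        si = 0.01
        t = np.arange(0, 25, si)
        v1 = parametric_ap_voltage(t, p)
        p2 = ParametricAPParams(ahp_tau=0.3, ahp_depth=3.0, tail_ms=0.2,
                                onset_time=p.onset_time + 2.0)
        v2 = parametric_ap_voltage(t, p2)
        v = np.maximum(v1, v2)
        events = detect_events(Sweep(v, si, kind=VOLTAGE))
        assert len(events) == 2
        assert events[0].stop <= events[1].start


class TestFirstSuprathreshold:
    def test_returns_smallest_spiking_current(self, canonical_ap):
        ss, currents, truth = gen_ramp_family(canonical_ap, 600.0)
        fam = RampFamily(ss, currents)
        current, sweep, event = first_suprathreshold(fam)
        assert current == 600.0
        assert sweep.samples[event.peak_index] > 0

    def test_all_spiking_returns_lowest(self, canonical_ap):
        ss, currents, _ = gen_ramp_family(canonical_ap, 50.0)
        current, _, _ = first_suprathreshold(RampFamily(ss, currents))
        assert current == 50.0

    def test_none_spiking_raises(self, canonical_ap):
        ss, currents, _ = gen_ramp_family(canonical_ap, 2000.0,
                                          max_current=1000.0)
        with pytest.raises(NoEventError):
            first_suprathreshold(RampFamily(ss, currents))


class TestThreshold:
    def test_detected_at_slope_break_within_one_sample(self,
                                                       canonical_ap_sweep):
        sweep, truth = canonical_ap_sweep
        event = detect_events(sweep)[0]
        thr = detect_threshold(phase_plane(sweep, event), 0.03)
        # one sample of the rise changes V by rise-slope * dt = 3 mV
        assert thr == pytest.approx(truth["v_thres"], abs=3.0)

    def test_criterion_above_dvdt_max_raises(self, canonical_ap_sweep):
        sweep, truth = canonical_ap_sweep
        event = detect_events(sweep)[0]
        with pytest.raises(NoEventError):
            detect_threshold(phase_plane(sweep, event),
                             truth["dvdt_max"] * 2)

    def test_shift_equivariance_under_ljp(self, canonical_ap_sweep):
        from physio.traceio import apply_ljp_correction

        sweep, _ = canonical_ap_sweep
        raw = Sweep(sweep.samples.copy(), sweep.sample_interval,
                    kind=VOLTAGE, ljp_corrected=False)
        corrected = apply_ljp_correction(raw, 16.0)
        ev = detect_events(sweep)[0]
        thr0 = detect_threshold(phase_plane(sweep, ev))
        thr1 = detect_threshold(phase_plane(corrected,
                                            detect_events(corrected)[0]))
        assert thr1 == pytest.approx(thr0 - 16.0, abs=1e-9)


class TestAmplitudeHalfwidthDerivatives:
    def test_amplitude_examples(self, canonical_ap_sweep):
        sweep, truth = canonical_ap_sweep
        event = detect_events(sweep)[0]
        assert ap_amplitude(sweep, event, truth["resting"]) == pytest.approx(
            truth["amplitude"], abs=0.5)
        assert ap_amplitude(sweep, event,
                            sweep.samples[event.peak_index]) == 0.0

    def test_canonical_halfwidth_quarter_ms(self, canonical_ap_sweep):
        sweep, truth = canonical_ap_sweep
        event = detect_events(sweep)[0]
        hw = ap_halfwidth(sweep, event, truth["v_thres"])
        assert hw == pytest.approx(0.25, abs=0.011)

    def test_symmetric_triangle_halfwidth(self):
        p = ParametricAPParams(rise_duration=0.2, fall_duration=0.2)
        sweep, truth = gen_parametric_ap(p, 100.0)
        event = detect_events(sweep)[0]
        hw = ap_halfwidth(sweep, event, truth["v_thres"])
        assert hw == pytest.approx(0.20, abs=0.011)

    def test_derivative_extrema_match_segment_slopes(self,
                                                     canonical_ap_sweep):
        sweep, truth = canonical_ap_sweep
        event = detect_events(sweep)[0]
        dmax, dmin = dvdt_extrema(sweep, event)
        assert dmax == pytest.approx(truth["dvdt_max"], rel=0.02)
        assert dmin == pytest.approx(truth["dvdt_min"], rel=0.02)

    def test_flat_trace_has_zero_extrema(self):
        from physio.spikes import EventWindow

        s = flat_voltage_sweep()
        dmax, dmin = dvdt_extrema(s, EventWindow(0, 100, 500))
        assert dmax == dmin == 0.0

    def test_time_compression_doubles_extrema(self):
        p = ParametricAPParams()
        fast = ParametricAPParams(rise_duration=0.1, fall_duration=0.15,
                                  ahp_tau=2.5)
        assert fast.truth()["dvdt_max"] == pytest.approx(
            2 * p.truth()["dvdt_max"])
        assert fast.truth()["dvdt_min"] == pytest.approx(
            2 * p.truth()["dvdt_min"])


class TestAHP:
    def test_tau_and_halftime_recovered(self, canonical_ap_sweep):
        sweep, truth = canonical_ap_sweep
        event = detect_events(sweep)[0]
        tau, halftime = fit_ahp(sweep, event, truth["resting"])
        assert tau == pytest.approx(5.0, rel=0.02)
        assert halftime == pytest.approx(5.0 * np.log(2), rel=0.02)

    def test_no_undershoot_raises(self):
        p = ParametricAPParams(ahp_depth=0.0)
        sweep, _ = gen_parametric_ap(p, 100.0)
        event = detect_events(sweep)[0]
        with pytest.raises(NoAHPError):
            fit_ahp(sweep, event, p.resting)

    def test_invariant_to_vertical_shift(self, canonical_ap_sweep):
        sweep, truth = canonical_ap_sweep
        event = detect_events(sweep)[0]
        tau0, _ = fit_ahp(sweep, event, truth["resting"])
        shifted = Sweep(sweep.samples + 10.0, sweep.sample_interval,
                        kind=VOLTAGE)
        tau1, _ = fit_ahp(shifted, detect_events(shifted)[0],
                          truth["resting"] + 10.0)
        assert tau1 == pytest.approx(tau0, rel=1e-3)


@st.composite
def ap_params(draw):
    resting = draw(st.floats(-85, -65))
    threshold = draw(st.floats(resting + 15, -35))
    peak = draw(st.floats(-10, 40))
    rise = draw(st.floats(0.1, 0.4))
    fall = draw(st.floats(0.1, 0.5))
    ahp_tau = draw(st.floats(2.0, 8.0))
    return ParametricAPParams(resting=resting, threshold=threshold,
                              peak=peak, rise_duration=rise,
                              fall_duration=fall, ahp_tau=ahp_tau)


class TestFeatureExactnessProperties:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(ap_params())
    def test_features_match_closed_form_at_100khz(self, p):
        """Threshold, amplitude, halfwidth, derivative extrema and AHP tau
        all match the closed-form waveform truth to within one sample
        interval (time) / one sample's voltage change (voltage)."""
        sweep, truth = gen_parametric_ap(p, 100.0)
        si = sweep.sample_interval
        event = detect_events(sweep)[0]
        plane = phase_plane(sweep, event)
        thr = detect_threshold(plane, 0.03)
        dv_per_sample = truth["dvdt_max"] * 1000 * si
        assert thr == pytest.approx(truth["v_thres"],
                                    abs=dv_per_sample + 1e-9)
        amp = ap_amplitude(sweep, event, truth["resting"])
        assert amp == pytest.approx(truth["amplitude"],
                                    abs=dv_per_sample + 1e-9)
        hw = ap_halfwidth(sweep, event, thr)
        assert hw == pytest.approx(truth["halfwidth"], abs=1.5 * si)
        dmax, dmin = dvdt_extrema(sweep, event)
        assert dmax == pytest.approx(truth["dvdt_max"], rel=0.05)
        assert dmin == pytest.approx(truth["dvdt_min"], rel=0.05)
        tau, _ = fit_ahp(sweep, event, truth["resting"])
        assert tau == pytest.approx(truth["ahp_tau"], rel=0.03)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(ap_params(), st.floats(-20, 20))
    def test_halfwidth_invariant_under_voltage_offset(self, p, offset):
        sweep, truth = gen_parametric_ap(p, 100.0)
        event = detect_events(sweep)[0]
        hw0 = ap_halfwidth(sweep, event, truth["v_thres"])
        shifted = Sweep(sweep.samples + offset, sweep.sample_interval,
                        kind=VOLTAGE)
        hw1 = ap_halfwidth(shifted, event, truth["v_thres"] + offset)
        assert hw1 == pytest.approx(hw0, abs=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(ap_params(), st.sampled_from([0.5, 2.0, 3.0]))
    def test_halfwidth_scales_with_time_dilation(self, p, k):
        truth = p.truth()
        import dataclasses

        dilated = dataclasses.replace(p, rise_duration=p.rise_duration * k,
                                      fall_duration=p.fall_duration * k)
        assert dilated.truth()["halfwidth"] == pytest.approx(
            k * truth["halfwidth"])


def test_full_battery_on_ramp_family(canonical_ap):
    ss, currents, truth = gen_ramp_family(canonical_ap, 600.0)
    feats = analyze_first_ap(RampFamily(ss, currents), truth["resting"])
    assert feats.ramp_current_at_first_ap == 600.0
    assert feats.halfwidth == pytest.approx(truth["halfwidth"], abs=0.011)
    assert feats.ahp_tau == pytest.approx(truth["ahp_tau"], rel=0.02)
    assert feats.ahp_halftime == pytest.approx(feats.ahp_tau * np.log(2))
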