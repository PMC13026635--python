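"""Passive membrane properties from averaged step responses.

Capacitance comes from the −5 mV voltage-clamp step: the averaged charging
transient is fitted with a biexponential, and the capacitive charge is the
closed-form integral of the fitted decay (baseline-subtracted) from
stimulus onset to five times the weighted decay time constant
τ_w = (A1·τ1 + A2·τ2)/(A1 + A2).  C = |Q| / |ΔV| (pA·ms/mV ≡ pF).

Input resistance is Ohm's law at steady state of the averaged −5 pA
current-clamp response; the membrane time constant is a mono-exponential
fit at stimulus onset of the same trace; the resting potential is the mean
of the pre-stimulus segment (LJP-corrected voltages required).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    DegenerateFitError,
    FitFailureError,
    InvalidParameterError,
    NotCorrectedError,
    SignalKindError,
)
from .synth import biexp_charge
from .traceio import CURRENT, VOLTAGE, Sweep, SweepSet


@dataclass
class BiexpFit:
    """Result of the biexponential transient fit (pA / ms / fC units)."""

    amplitude_fast: float
    tau_fast: float
    amplitude_slow: float
    tau_slow: float
    offset: float
    residual_rms: float

    @property
    def weighted_tau(self) -> float:
        denom = self.amplitude_fast + self.amplitude_slow
        if denom == 0:
            return float("nan")
        return (self.amplitude_fast * self.tau_fast
                + self.amplitude_slow * self.tau_slow) / denom

    @property
    def charge(self) -> float:
        """Capacitive charge (fC): closed-form integral of the fitted decay
        over [0, 5·τ_w]."""
        return abs(biexp_charge(self.amplitude_fast, self.tau_fast,
                                self.amplitude_slow,
                                self.tau_slow)["charge_fc"])


@dataclass
class PassiveProperties:
    capacitance: float        # pF
    input_resistance: float   # MΩ
    tau_mem: float            # ms
    resting: float            # mV

    def __post_init__(self):
        if self.resting is not None and not -120 <= self.resting <= 0:
            raise InvalidParameterError(
                f"E_rest {self.resting} mV outside physiological bounds")


def average_sweeps(sweep_set: SweepSet) -> Sweep:
    """Pointwise arithmetic mean of all repetitions; metadata inherited
    from the first sweep."""
    s0 = sweep_set.sweeps[0]
    mean = sweep_set.as_array().mean(axis=0)
    return Sweep(mean, s0.sample_interval, kind=s0.kind,
                 stimulus=dict(s0.stimulus), cell_id=s0.cell_id,
                 group=s0.group, ljp_corrected=s0.ljp_corrected)


def _peel_init(t: np.ndarray, y: np.ndarray, offset: float):
    """Two-stage tail-peeling initialization for the biexponential fit.

    Fits log|y − offset| linearly on the late tail for the slow component,
    subtracts it, and repeats on the early segment for the fast one.
    """
    resid = y - offset
    sign = 1.0 if resid[: max(3, resid.size // 20)].mean() >= 0 else -1.0
    r = sign * resid
    n = r.size
    tail = slice(n // 2, int(0.9 * n))
    good = r[tail] > 0
    if good.sum() >= 3:
        b, a = np.polyfit(t[tail][good], np.log(r[tail][good]), 1)
        tau2 = -1.0 / b if b < 0 else t[-1]
        a2 = np.exp(a)
    else:
        tau2, a2 = t[-1] / 3.0, max(r.max(), 1e-9) / 2.0
    early = r - a2 * np.exp(-t / tau2)
    head = slice(0, max(4, n // 10))
    good = early[head] > 0
    if good.sum() >= 3:
        b, a = np.polyfit(t[head][good], np.log(early[head][good]), 1)
        tau1 = -1.0 / b if b < 0 else tau2 / 5.0
        a1 = np.exp(a)
    else:
        tau1, a1 = tau2 / 5.0, max(r.max() - a2, 1e-9)
    return sign * a1, max(tau1, 1e-4), sign * a2, max(tau2, 2e-4)


def fit_biexponential(avg: Sweep, onset: float, window: float) -> BiexpFit:
    """Least-squares fit of I(t) = I_ss + A1·e^(−(t−onset)/τ1) +
    A2·e^(−(t−onset)/τ2) over [onset, onset + window].

    τ1 ≤ τ2 is enforced by relabeling.  Initialization is deterministic
    tail-peeling with up to 5 perturbed restarts on failure.
    """
    if avg.kind != CURRENT:
        raise SignalKindError("biexponential transient fit expects a current sweep")
    y = avg.slice_time(onset, onset + window)
    if y.size < 10:
        raise InvalidParameterError("fit window shorter than 10 samples")
    t = np.arange(y.size) * avg.sample_interval
    offset0 = float(y[int(0.9 * y.size):].mean())

    def model(tt, a1, t1, a2, t2, off):
        return off + a1 * np.exp(-tt / t1) + a2 * np.exp(-tt / t2)

    a1, t1, a2, t2 = _peel_init(t, y, offset0)
    # bounded fit: taus within the window, amplitudes within a generous
    # multiple of the data range — prevents the slow component degenerating
    # into a constant traded off against the offset
    span = float(np.ptp(y)) or 1.0
    t_lo, t_hi = avg.sample_interval / 4.0, 2.0 * t[-1]
    lo = (-10 * span, t_lo, -10 * span, t_lo, y.min() - span)
    hi = (10 * span, t_hi, 10 * span, t_hi, y.max() + span)

    def clip(p0):
        return tuple(np.clip(p0, np.asarray(lo) + 1e-12,
                             np.asarray(hi) - 1e-12))

    rng = np.random.default_rng(0)
    last_err = None
    for attempt in range(6):
        if attempt == 0:
            p0 = clip((a1, t1, a2, t2, offset0))
        else:
            f = rng.uniform(0.5, 2.0, 4)
            p0 = clip((a1 * f[0], t1 * f[1], a2 * f[2], t2 * f[3], offset0))
        try:
            popt, _ = curve_fit(model, t, y, p0=p0, bounds=(lo, hi),
                                maxfev=20000)
            break
        except RuntimeError as exc:
            last_err = exc
    else:
        raise FitFailureError(f"biexponential fit did not converge: {last_err}",
                              residual=float(np.std(y)))
    A1, T1, A2, T2, off = popt
    T1, T2 = abs(T1), abs(T2)
    if T1 > T2:
        A1, A2, T1, T2 = A2, A1, T2, T1
    resid = float(np.sqrt(np.mean((model(t, *popt) - y) ** 2)))
    return BiexpFit(A1, T1, A2, T2, float(off), resid)


def estimate_capacitance(fit: BiexpFit, step_voltage: float) -> float:
    """C = |Q| / |ΔV| in pF, with Q the closed-form charge of the fit."""
    if step_voltage == 0:
        raise InvalidParameterError("step_voltage must be non-zero")
    tau_w = fit.weighted_tau
    if not np.isfinite(tau_w) or tau_w <= 0:
        raise DegenerateFitError("non-positive weighted tau")
    return fit.charge / abs(step_voltage)


def estimate_input_resistance(avg: Sweep, step_current: float,
                              baseline_window: tuple[float, float],
                              steady_window: tuple[float, float]) -> float:
    """R_in = ΔV/ΔI at steady state, in MΩ (µV/pA × 1e3)."""
    if avg.kind != VOLTAGE:
        raise SignalKindError("input resistance expects a voltage sweep")
    if step_current == 0:
        raise InvalidParameterError("step_current must be non-zero")
    base = avg.slice_time(*baseline_window)
    steady = avg.slice_time(*steady_window)
    if base.size == 0 or steady.size == 0:
        raise InvalidParameterError("empty analysis window")
    deflection = steady.mean() - base.mean()   # mV
    return float(deflection / step_current * 1e3)


def estimate_tau_mem(avg: Sweep, onset: float,
                     window: float | None = None) -> float:
    """Mono-exponential fit V(t) = V_ss + (V_0 − V_ss)·e^(−(t−onset)/τ) at
    stimulus onset of the averaged trace; returns τ in ms."""
    if avg.kind != VOLTAGE:
        raise SignalKindError("tau_mem expects a voltage sweep")
    end = avg.duration if window is None else onset + window
    y = avg.slice_time(onset, end)
    if y.size < 10:
        raise DegenerateFitError("step response shorter than 10 samples")
    t = np.arange(y.size) * avg.sample_interval
    v0, vss = float(y[0]), float(y[int(0.9 * y.size):].mean())
    if abs(vss - v0) < 1e-12:
        raise DegenerateFitError("no detectable step response")

    def model(tt, v_ss, dv, tau):
        return v_ss + dv * np.exp(-tt / tau)

    tau0 = max(t[-1] / 10.0, avg.sample_interval)
    try:
        popt, _ = curve_fit(model, t, y, p0=(vss, v0 - vss, tau0),
                            maxfev=20000)
    except RuntimeError as exc:
        raise FitFailureError(f"tau_mem fit did not converge: {exc}") from exc
    tau = abs(float(popt[2]))
    if tau < 0.5 * avg.sample_interval:
        raise DegenerateFitError("fitted tau below one sample interval")
    return tau


def estimate_resting(avg: Sweep, pre_stimulus_window: tuple[float, float]
                     ) -> float:
    """Mean voltage over a pre-stimulus window of an LJP-corrected sweep."""
    if avg.kind != VOLTAGE:
        raise SignalKindError("resting potential expects a voltage sweep")
    if not avg.ljp_corrected:
        raise NotCorrectedError(
            "sweep must be LJP-corrected before estimating E_rest")
    onset = avg.stimulus.get("onset_ms")
    t0, t1 = pre_stimulus_window
    if onset is not None and t1 > onset + 1e-9:
        raise InvalidParameterError("window extends past stimulus onset")
    seg = avg.slice_time(t0, t1)
    if seg.size == 0:
        raise InvalidParameterError("empty pre-stimulus window")
    return float(seg.mean())


def default_windows(avg: Sweep) -> dict:
    """Default analysis windows: baseline = final 20% of the pre-stimulus
    segment, steady state = final 20% of the step."""
    onset = avg.stimulus.get("onset_ms", 0.0)
    dur = avg.stimulus.get("duration_ms", avg.duration - onset)
    end = min(onset + dur, avg.duration)
    return {
        "baseline": (0.8 * onset, onset),
        "steady": (end - 0.2 * dur, end),
    }


def analyze_passive(vc_set: SweepSet, cc_set: SweepSet,
                    step_voltage: float = -5.0,
                    step_current: float = -5.0,
                    fit_window: float | None = None) -> PassiveProperties:
    """Full passive battery on one cell: average both protocol sets, fit
    the VC transient for C, apply Ohm's law and the onset fit on the CC
    average for R_in and τ_mem, and read E_rest before the step."""
    vc_avg = average_sweeps(vc_set)
    onset = vc_avg.stimulus.get("onset_ms", 0.0)
    dur = vc_avg.stimulus.get("duration_ms", vc_avg.duration - onset)
    fit = fit_biexponential(vc_avg, onset,
                            fit_window if fit_window is not None else dur)
    c = estimate_capacitance(fit, step_voltage)

    cc_avg = average_sweeps(cc_set)
    w = default_windows(cc_avg)
    r_in = estimate_input_resistance(cc_avg, step_current,
                                     w["baseline"], w["steady"])
    cc_onset = cc_avg.stimulus.get("onset_ms", 0.0)
    cc_dur = cc_avg.stimulus.get("duration_ms",
                                 cc_avg.duration - cc_onset)
    tau = estimate_tau_mem(cc_avg, cc_onset, cc_dur)
    e_rest = estimate_resting(cc_avg, w["baseline"])
    return PassiveProperties(capacitance=c, input_resistance=abs(r_in),
                             tau_mem=tau, resting=e_rest)
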