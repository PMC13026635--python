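"""Action-potential feature extraction from ramp-current families.

The analyzed event is the *first suprathreshold event*: the sweep with the
smallest ramp amplitude containing at least one spike.  From it the module
extracts the voltage threshold (phase-plane dV/dt criterion), AP amplitude
(resting → peak), halfwidth (crossings of the level halfway between
threshold and peak, sub-sample by linear interpolation), the derivative
extrema, and the after-hyperpolarization decay (mono-exponential fit at the
post-spike minimum; the reported decay time is τ·ln 2).

Derivatives are central differences on the raw trace (acquisition-filtered
data need no further smoothing); all level crossings use linear
interpolation for sub-sample precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import argrelmax

from .errors import (
    FitFailureError,
    InvalidParameterError,
    NoAHPError,
    NoEventError,
    SignalKindError,
)
from .traceio import VOLTAGE, Sweep, SweepSet

#: default phase-plane slope criterion, V/ms (= 30 V/s): "rapid increase"
DVDT_CRITERION = 0.03
#: default event peak criterion, mV (post-LJP)
PEAK_CRITERION = -20.0


@dataclass
class RampFamily:
    """Sweeps ordered by ramp peak current (0.2 ms rise / 0.8 ms descent,
    default 50 pA increments)."""

    sweeps: SweepSet
    currents: np.ndarray

    def __post_init__(self):
        self.currents = np.asarray(self.currents, dtype=float)
        if len(self.sweeps) != self.currents.size:
            raise InvalidParameterError("one current per sweep required")
        if np.any(np.diff(self.currents) <= 0):
            raise InvalidParameterError("currents must be strictly increasing")


@dataclass
class EventWindow:
    """One detected spike: sample indices into its source sweep."""

    start: int
    peak_index: int
    stop: int


@dataclass
class PhasePlane:
    """Paired (V, dV/dt) series over one event window; dV/dt in V/ms by
    central differences."""

    voltage: np.ndarray
    dvdt: np.ndarray
    sample_interval: float

    def __post_init__(self):
        if self.voltage.size != self.dvdt.size:
            raise InvalidParameterError("V and dV/dt must have equal length")


@dataclass
class APFeatures:
    ramp_current_at_first_ap: float | None
    v_thres: float
    amplitude: float
    halfwidth: float
    dvdt_max: float
    dvdt_min: float
    ahp_tau: float | None = None
    ahp_halftime: float | None = None


def central_dvdt(samples: np.ndarray, sample_interval: float) -> np.ndarray:
    """Central-difference derivative in V/ms (input mV, ms)."""
    return np.gradient(samples, sample_interval) / 1000.0


def phase_plane(sweep: Sweep, window: EventWindow | None = None) -> PhasePlane:
    """Phase-plane series (V vs dV/dt) of a sweep or one event window."""
    v = sweep.samples
    dv = central_dvdt(v, sweep.sample_interval)
    if window is not None:
        v = v[window.start:window.stop]
        dv = dv[window.start:window.stop]
    return PhasePlane(v, dv, sweep.sample_interval)


def detect_events(sweep: Sweep,
                  peak_criterion: float = PEAK_CRITERION,
                  dvdt_criterion: float = DVDT_CRITERION,
                  pre_ms: float = 2.0, post_ms: float = 10.0
                  ) -> list[EventWindow]:
    """Spike windows around local maxima above ``peak_criterion`` whose
    preceding upstroke exceeded ``dvdt_criterion`` (V/ms).

    Windows are time-ordered and non-overlapping (split midway between
    adjacent peaks).  An empty list is a valid result.
    """
    if sweep.kind != VOLTAGE:
        raise SignalKindError("event detection expects a voltage sweep")
    v = sweep.samples
    si = sweep.sample_interval
    dv = central_dvdt(v, si)
    cand = [i for i in argrelmax(v, order=2)[0] if v[i] >= peak_criterion]
    # require a fast upstroke in the 2 ms preceding the peak
    pre = max(1, int(round(2.0 / si)))
    peaks = [i for i in cand if np.any(dv[max(0, i - pre):i + 1]
                                       >= dvdt_criterion)]
    # deduplicate plateaus: keep first of any run closer than 0.5 ms
    dedup: list[int] = []
    for i in peaks:
        if not dedup or (i - dedup[-1]) * si > 0.5:
            dedup.append(i)
    n_pre = int(round(pre_ms / si))
    n_post = int(round(post_ms / si))
    windows = []
    for j, i in enumerate(dedup):
        lo = max(0, i - n_pre)
        hi = min(v.size, i + n_post)
        if j > 0:
            lo = max(lo, (dedup[j - 1] + i) // 2 + 1)
        if j + 1 < len(dedup):
            hi = min(hi, (i + dedup[j + 1]) // 2)
        windows.append(EventWindow(lo, i, hi))
    return windows


def first_suprathreshold(family: RampFamily,
                         peak_criterion: float = PEAK_CRITERION,
                         dvdt_criterion: float = DVDT_CRITERION
                         ) -> tuple[float, Sweep, EventWindow]:
    """Smallest ramp current whose sweep spikes; that current, the sweep
    and its first event window."""
    for current, sweep in zip(family.currents, family.sweeps):
        events = detect_events(sweep, peak_criterion, dvdt_criterion)
        if events:
            return float(current), sweep, events[0]
    raise NoEventError("no sweep in the ramp family is suprathreshold")


def detect_threshold(plane: PhasePlane,
                     criterion: float = DVDT_CRITERION) -> float:
    """Voltage threshold: V where dV/dt first exceeds ``criterion`` (V/ms)
    and stays above it for >= 2 consecutive samples, with linear
    interpolation between the bracketing samples."""
    dv = plane.dvdt
    v = plane.voltage
    above = dv >= criterion
    hits = np.where(above[:-1] & above[1:])[0]
    if hits.size == 0:
        raise NoEventError("dV/dt criterion never reached for 2 samples")
    i = int(hits[0])
    if i == 0 or dv[i - 1] >= criterion:
        return float(v[i])
    frac = (criterion - dv[i - 1]) / (dv[i] - dv[i - 1])
    return float(v[i - 1] + frac * (v[i] - v[i - 1]))


def ap_amplitude(sweep: Sweep, window: EventWindow, e_rest: float) -> float:
    """Peak V minus resting potential, mV."""
    return float(sweep.samples[window.peak_index] - e_rest)


def _cross_time(t0: float, t1: float, v0: float, v1: float,
                level: float) -> float:
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def ap_halfwidth(sweep: Sweep, window: EventWindow, v_thres: float) -> float:
    """Duration between rising and falling crossings of the half level
    V_thres + (V_peak − V_thres)/2, sub-sample by linear interpolation."""
    v = sweep.samples
    si = sweep.sample_interval
    pk = window.peak_index
    half = v_thres + 0.5 * (v[pk] - v_thres)
    # rising crossing: last sample below half before the peak
    i = pk
    while i > window.start and v[i - 1] > half:
        i -= 1
    if v[i - 1] > half if i > 0 else True:
        raise NoEventError("rising flank never crosses the half level")
    t_rise = _cross_time((i - 1) * si, i * si, v[i - 1], v[i], half)
    # falling crossing: first sample below half after the peak
    j = pk
    while j + 1 < window.stop and v[j + 1] >= half:
        j += 1
    if j + 1 >= v.size or v[j + 1] >= half:
        raise NoEventError("falling flank never recrosses the half level")
    t_fall = _cross_time(j * si, (j + 1) * si, v[j], v[j + 1], half)
    return float(t_fall - t_rise)


def dvdt_extrema(sweep: Sweep, window: EventWindow) -> tuple[float, float]:
    """(max, min) of the central-difference derivative in the window, V/ms."""
    dv = central_dvdt(sweep.samples, sweep.sample_interval)
    seg = dv[window.start:window.stop]
    return float(seg.max()), float(seg.min())


def fit_ahp(sweep: Sweep, window: EventWindow, e_rest: float,
            max_window_ms: float = 20.0) -> tuple[float, float]:
    """Mono-exponential fit at the post-spike minimum.

    Fits V(t) = V_∞ − (V_∞ − V_min)·e^(−(t−t_min)/τ) from the AHP minimum
    until the trace returns within 5% of baseline or ``max_window_ms``.
    Returns (τ, halftime = τ·ln 2) in ms.
    """
    v = sweep.samples
    si = sweep.sample_interval
    pk = window.peak_index
    tail = v[pk:]
    i_min = int(np.argmin(tail)) + pk
    v_min = v[i_min]
    if v_min >= e_rest:
        raise NoAHPError("no undershoot below the resting potential")
    depth = e_rest - v_min
    seg_end = v.size
    for k in range(i_min, v.size):
        if e_rest - v[k] <= 0.05 * depth:
            seg_end = k + 1
            break
    seg_end = min(seg_end, i_min + int(round(max_window_ms / si)))
    y = v[i_min:seg_end]
    if y.size < 5:
        raise FitFailureError("AHP window too short to fit")
    t = np.arange(y.size) * si

    def model(tt, v_inf, tau):
        return v_inf - (v_inf - v_min) * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(model, t, y, p0=(e_rest, max(1.0, y.size * si / 3)),
                            maxfev=20000)
    except RuntimeError as exc:
        raise FitFailureError(f"AHP fit did not converge: {exc}") from exc
    tau = abs(float(popt[1]))
    return tau, tau * float(np.log(2.0))


def analyze_first_ap(family: RampFamily, e_rest: float,
                     peak_criterion: float = PEAK_CRITERION,
                     dvdt_criterion: float = DVDT_CRITERION) -> APFeatures:
    """Full first-suprathreshold-event battery on a ramp family."""
    current, sweep, window = first_suprathreshold(family, peak_criterion,
                                                  dvdt_criterion)
    plane = phase_plane(sweep, window)
    v_thres = detect_threshold(plane, dvdt_criterion)
    amp = ap_amplitude(sweep, window, e_rest)
    hw = ap_halfwidth(sweep, window, v_thres)
    dmax, dmin = dvdt_extrema(sweep, window)
    try:
        tau, halftime = fit_ahp(sweep, window, e_rest)
    except (NoAHPError, FitFailureError):
        tau, halftime = None, None
    return APFeatures(ramp_current_at_first_ap=current, v_thres=v_thres,
                      amplitude=amp, halfwidth=hw, dvdt_max=dmax,
                      dvdt_min=dmin, ahp_tau=tau, ahp_halftime=halftime)
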