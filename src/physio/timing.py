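"""Spike latency, jitter and train-entrainment metrics.

Rheobase precision: 100 repetitions of a square current at rheobase give a
mix of sub- and suprathreshold responses; latency is the time from stimulus
onset to the AP peak, jitter its sample standard deviation (n−1) over the
suprathreshold repetitions only.

Train entrainment: 30-pulse trains at 500 Hz.  Each AP is assigned to a
pulse by peak time within the half-open inter-pulse window
[onset, onset + period); per pulse the median latency and jitter (SD across
repetitions) are computed, the median-latency series is normalized to the
first pulse, and the precision summary is the mean jitter of the last five
pulses divided by the first-pulse jitter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InvalidParameterError,
    NoEventError,
    UndefinedLatencyError,
    UndefinedRatioError,
)
from .spikes import DVDT_CRITERION, PEAK_CRITERION, detect_events
from .traceio import Sweep, SweepSet

logger = logging.getLogger(__name__)


@dataclass
class LatencyStats:
    """Latency/jitter of suprathreshold repetitions at rheobase."""

    latencies: np.ndarray       # ms, one per suprathreshold repetition
    n_total: int
    rheobase_current: float | None = None

    def __post_init__(self):
        self.latencies = np.asarray(self.latencies, dtype=float)
        if np.any(self.latencies <= 0):
            raise InvalidParameterError("latencies must all be > 0")

    @property
    def n_supra(self) -> int:
        return self.latencies.size

    @property
    def mean_latency(self) -> float:
        return float(self.latencies.mean())

    @property
    def jitter(self) -> float:
        """Sample SD (n−1) of the latencies, ms."""
        return float(self.latencies.std(ddof=1))


@dataclass
class TrainResult:
    """Per-pulse latency/jitter of a 30-pulse train over repetitions.

    ``latencies`` is (n_repetitions, n_pulses) with NaN for pulses without
    an AP in that repetition.
    """

    latencies: np.ndarray
    pulse_onsets: np.ndarray
    amplitude: float | None = None

    def __post_init__(self):
        self.latencies = np.atleast_2d(np.asarray(self.latencies, float))
        self.pulse_onsets = np.asarray(self.pulse_onsets, float)
        if self.latencies.shape[1] != self.pulse_onsets.size:
            raise InvalidParameterError("one latency slot per pulse required")

    @property
    def n_pulses(self) -> int:
        return self.pulse_onsets.size

    @property
    def median_latency(self) -> np.ndarray:
        """Per-pulse median latency across repetitions (NaN-aware), ms."""
        out = np.full(self.n_pulses, np.nan)
        any_finite = ~np.isnan(self.latencies).all(axis=0)
        out[any_finite] = np.nanmedian(self.latencies[:, any_finite], axis=0)
        return out

    @property
    def jitter(self) -> np.ndarray:
        """Per-pulse sample SD of latency across repetitions, ms; NaN when
        fewer than two repetitions fired that pulse."""
        out = np.full(self.n_pulses, np.nan)
        for k in range(self.n_pulses):
            col = self.latencies[:, k]
            col = col[~np.isnan(col)]
            if col.size >= 2:
                out[k] = col.std(ddof=1)
        return out

    @property
    def complete(self) -> bool:
        """True when every pulse fired in every repetition."""
        return not np.isnan(self.latencies).any()


def rheobase_latency(sweep_set: SweepSet, stimulus_onset: float | None = None,
                     peak_criterion: float = PEAK_CRITERION,
                     dvdt_criterion: float = DVDT_CRITERION) -> LatencyStats:
    """Latency statistics over the suprathreshold repetitions of a square
    rheobase set; latency = first AP peak time − stimulus onset."""
    if stimulus_onset is None:
        stimulus_onset = sweep_set.sweeps[0].stimulus.get("onset_ms")
        if stimulus_onset is None:
            raise InvalidParameterError("stimulus onset unknown")
    latencies = []
    for sweep in sweep_set:
        events = detect_events(sweep, peak_criterion, dvdt_criterion)
        events = [e for e in events
                  if e.peak_index * sweep.sample_interval >= stimulus_onset]
        if events:
            t_peak = events[0].peak_index * sweep.sample_interval
            latencies.append(t_peak - stimulus_onset)
    if not latencies:
        raise UndefinedLatencyError("zero suprathreshold repetitions")
    amp = sweep_set.sweeps[0].stimulus.get("amplitude_pa")
    return LatencyStats(np.asarray(latencies), n_total=len(sweep_set),
                        rheobase_current=amp)


def train_latencies(sweep_set: SweepSet,
                    pulse_onsets: np.ndarray | None = None,
                    peak_criterion: float = PEAK_CRITERION,
                    dvdt_criterion: float = DVDT_CRITERION) -> TrainResult:
    """Assign AP peaks of train repetitions to pulses and collect per-pulse
    latencies.

    The assignment window for pulse k is [onset_k, onset_{k+1}); a second
    AP in one window is resolved to the first and logged; a pulse without
    an AP is recorded NaN and excluded from that pulse's statistics.
    """
    if pulse_onsets is None:
        pulse_onsets = sweep_set.sweeps[0].stimulus.get("pulse_onsets_ms")
        if pulse_onsets is None:
            raise InvalidParameterError("pulse onsets unknown")
    pulse_onsets = np.asarray(pulse_onsets, dtype=float)
    n_pulses = pulse_onsets.size
    period = float(np.median(np.diff(pulse_onsets))) if n_pulses > 1 else 2.0
    edges = np.append(pulse_onsets, pulse_onsets[-1] + period)
    lat = np.full((len(sweep_set), n_pulses), np.nan)
    for r, sweep in enumerate(sweep_set):
        events = detect_events(sweep, peak_criterion, dvdt_criterion,
                               pre_ms=0.5, post_ms=1.5)
        peak_times = np.array([e.peak_index * sweep.sample_interval
                               for e in events])
        for k in range(n_pulses):
            sel = peak_times[(peak_times >= edges[k])
                             & (peak_times < edges[k + 1])]
            if sel.size == 0:
                continue
            if sel.size > 1:
                logger.info("repetition %d pulse %d: %d APs in window, "
                            "using the first", r, k, sel.size)
            lat[r, k] = sel[0] - pulse_onsets[k]
    amp = sweep_set.sweeps[0].stimulus.get("amplitude_pa")
    return TrainResult(lat, pulse_onsets, amplitude=amp)


def normalize_latency_series(result: TrainResult) -> np.ndarray:
    """Per-pulse median latency divided by the pulse-1 median; the first
    element is exactly 1.0."""
    med = result.median_latency
    if not np.isfinite(med[0]) or med[0] <= 0:
        raise UndefinedLatencyError("pulse-1 median latency absent")
    out = med / med[0]
    out[0] = 1.0
    return out


def jitter_ratio_last5(result: TrainResult) -> float:
    """Mean jitter of the last five pulses divided by the first-pulse
    jitter."""
    jit = result.jitter
    if result.n_pulses < 6:
        raise InvalidParameterError("need more than five pulses")
    first = jit[0]
    if not np.isfinite(first) or first == 0:
        raise UndefinedRatioError("first-pulse jitter is zero or undefined")
    last5 = jit[-5:]
    last5 = last5[np.isfinite(last5)]
    if last5.size == 0:
        raise UndefinedRatioError("no jitter defined over the last 5 pulses")
    return float(last5.mean() / first)


def find_min_sustain_current(results: list[TrainResult],
                             completion_fraction: float = 1.0) -> float:
    """Smallest train amplitude for which the required fraction of
    (pulse, repetition) slots fired — default: every pulse in every
    repetition (constant firing)."""
    if not results:
        raise InvalidParameterError("no train results given")
    ordered = sorted(results, key=lambda r: (r.amplitude is None,
                                             r.amplitude))
    for res in ordered:
        if res.amplitude is None:
            raise InvalidParameterError("train result lacks an amplitude")
        frac = 1.0 - np.isnan(res.latencies).mean()
        if frac >= completion_fraction:
            return float(res.amplitude)
    raise NoEventError("no amplitude sustains constant firing")
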