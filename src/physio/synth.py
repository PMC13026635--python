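"""Seeded synthetic-data generators with known ground truth.

The raw recordings and image stacks this kind of analysis runs on are not
publicly deposited, so every input class the pipeline consumes is emulated
here with analytically (or numerically) known ground truth:

* voltage-clamp −5 mV step charging transients with biexponential decay,
* current-clamp −5 pA step responses,
* parametric action-potential waveforms with closed-form feature values,
* conductance-model simulations (see :mod:`physio.model`),
* square-pulse latency sets and 30-pulse 500 Hz train sets,
* 3-D soma image stacks with dye-excluding vacuoles,
* whole study cohorts (4 groups, per-group parameter distributions).

Every generator is a pure function of (params, seed): two calls with the
same arguments return bitwise-identical data.  Ground truths are emitted
alongside the data in closed form and never recomputed from the rendered
samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError
from .model import NeuronModelParams, simulate_neuron  # re-exported
from .traceio import CURRENT, VOLTAGE, ImageStack, Sweep, SweepSet

__all__ = [
    "PassiveCircuitParams", "ParametricAPParams", "VacuoleStackParams",
    "NeuronModelParams", "simulate_neuron",
    "gen_vc_transient", "gen_cc_step_response", "gen_parametric_ap",
    "parametric_ap_voltage", "gen_ramp_family", "gen_square_latency_set",
    "gen_train_set", "gen_vacuole_stack",
]


# ---------------------------------------------------------------------------
# Passive circuit
# ---------------------------------------------------------------------------

@dataclass
class PassiveCircuitParams:
    """Ground-truth passive parameters for the step protocols.

    The voltage-clamp transient is rendered from the biexponential
    amplitudes/taus directly; the current-clamp response from
    ``true_resistance`` / ``true_tau_mem`` / ``true_resting``.  ``noise_sd``
    is in the units of the generated trace (pA for voltage clamp, mV for
    current clamp).
    """

    amplitude_fast: float = 150.0      # pA
    tau_fast: float = 0.2              # ms
    amplitude_slow: float = 50.0       # pA
    tau_slow: float = 1.0              # ms
    steady_state_current: float = 0.0  # pA
    step_voltage: float = -5.0         # mV (ΔV of the VC step)
    true_resistance: float = 200.0     # MΩ
    true_tau_mem: float = 4.0          # ms
    true_resting: float = -76.0        # mV (post-LJP)
    noise_sd: float = 0.0              # pA (VC) or mV (CC)
    sample_rate: float = 50.0          # kHz
    n_repetitions: int = 100
    baseline_ms: float = 10.0
    vc_step_ms: float = 20.0
    cc_step_ms: float = 100.0
    cc_post_ms: float = 20.0
    ljp_offset: float = 0.0            # mV added to emitted CC voltages

    def __post_init__(self):
        if self.tau_fast <= 0 or self.tau_slow <= 0:
            raise InvalidParameterError("time constants must be > 0")
        if not self.tau_fast < self.tau_slow:
            raise InvalidParameterError("tau_fast must be < tau_slow")
        if self.sample_rate <= 0:
            raise InvalidParameterError("sample_rate must be > 0")
        if self.n_repetitions < 1:
            raise InvalidParameterError("n_repetitions must be >= 1")
        if self.true_tau_mem <= 0:
            raise InvalidParameterError("true_tau_mem must be > 0")

    @property
    def sample_interval(self) -> float:
        return 1.0 / self.sample_rate


def biexp_charge(a1: float, t1: float, a2: float, t2: float) -> dict:
    """Closed-form weighted tau and capacitive charge of a biexponential
    transient, integrated over [0, 5·tau_w].

    Q = A1·τ1·(1−e^(−5τw/τ1)) + A2·τ2·(1−e^(−5τw/τ2)),  fC when pA·ms.
    """
    denom = a1 + a2
    if denom == 0:
        return {"tau_w": float("nan"), "charge_fc": 0.0}
    tau_w = (a1 * t1 + a2 * t2) / denom
    span = 5.0 * tau_w
    q = a1 * t1 * (1.0 - math.exp(-span / t1)) \
        + a2 * t2 * (1.0 - math.exp(-span / t2))
    return {"tau_w": tau_w, "charge_fc": q}


def gen_vc_transient(params: PassiveCircuitParams, seed: int = 0
                     ) -> tuple[SweepSet, dict]:
    """Voltage-clamp −5 mV step: current sweeps with biexponential decay.

    Returns the repetition set and a ground-truth dict holding the closed
    form weighted tau, capacitive charge Q (fC) and capacitance
    ``|Q| / |ΔV|`` (pF).
    """
    rng = np.random.default_rng(seed)
    si = params.sample_interval
    n_base = int(round(params.baseline_ms / si))
    n_step = int(round(params.vc_step_ms / si))
    t_step = np.arange(n_step) * si
    decay = (params.steady_state_current
             + params.amplitude_fast * np.exp(-t_step / params.tau_fast)
             + params.amplitude_slow * np.exp(-t_step / params.tau_slow))
    clean = np.concatenate([np.zeros(n_base), decay])
    stim = {"protocol": "vc_step", "step_mv": params.step_voltage,
            "onset_ms": params.baseline_ms, "duration_ms": params.vc_step_ms}
    sweeps = []
    for _ in range(params.n_repetitions):
        trace = clean if params.noise_sd == 0 else \
            clean + rng.normal(0.0, params.noise_sd, clean.size)
        sweeps.append(Sweep(trace, si, kind=CURRENT, stimulus=dict(stim)))
    truth = biexp_charge(params.amplitude_fast, params.tau_fast,
                         params.amplitude_slow, params.tau_slow)
    truth["capacitance_pf"] = (abs(truth["charge_fc"])
                               / abs(params.step_voltage)
                               if params.step_voltage != 0 else float("nan"))
    truth.update(amplitude_fast=params.amplitude_fast,
                 tau_fast=params.tau_fast,
                 amplitude_slow=params.amplitude_slow,
                 tau_slow=params.tau_slow,
                 steady_state_current=params.steady_state_current)
    return SweepSet(sweeps), truth


def gen_cc_step_response(params: PassiveCircuitParams,
                         step_current: float = -5.0, seed: int = 0
                         ) -> tuple[SweepSet, dict]:
    """Current-clamp step (default −5 pA): voltage sweeps relaxing with the
    membrane time constant toward the Ohmic deflection.

    MΩ·pA = µV, so the deflection in mV is ``I·R·1e-3``.  If
    ``params.ljp_offset`` is non-zero the emitted sweeps are shifted by it
    and flagged uncorrected (recorded-potential convention); otherwise they
    are at true potentials and flagged corrected.
    """
    if step_current == 0:
        raise InvalidParameterError("step_current must be non-zero")
    rng = np.random.default_rng(seed)
    si = params.sample_interval
    n_base = int(round(params.baseline_ms / si))
    n_step = int(round(params.cc_step_ms / si))
    n_post = int(round(params.cc_post_ms / si))
    deflect = step_current * params.true_resistance * 1e-3  # mV
    tau = params.true_tau_mem
    t_step = np.arange(n_step) * si
    during = deflect * (1.0 - np.exp(-t_step / tau))
    v_end = during[-1] if n_step else 0.0
    t_post = np.arange(n_post) * si
    after = v_end * np.exp(-t_post / tau)
    clean = params.true_resting + np.concatenate(
        [np.zeros(n_base), during, after])
    corrected = params.ljp_offset == 0
    clean = clean + params.ljp_offset
    stim = {"protocol": "cc_step", "amplitude_pa": step_current,
            "onset_ms": params.baseline_ms, "duration_ms": params.cc_step_ms}
    sweeps = []
    for _ in range(params.n_repetitions):
        trace = clean if params.noise_sd == 0 else \
            clean + rng.normal(0.0, params.noise_sd, clean.size)
        sweeps.append(Sweep(trace, si, kind=VOLTAGE, stimulus=dict(stim),
                            ljp_corrected=corrected))
    truth = {"resistance_mohm": params.true_resistance,
             "tau_mem_ms": params.true_tau_mem,
             "resting_mv": params.true_resting,
             "deflection_mv": deflect,
             "step_current_pa": step_current}
    return SweepSet(sweeps), truth


# ---------------------------------------------------------------------------
# Parametric action potentials
# ---------------------------------------------------------------------------

@dataclass
class ParametricAPParams:
    """Piecewise action-potential waveform with closed-form features.

    Geometry: baseline at ``resting`` until ``onset_time``; a slow linear
    approach from resting to ``threshold`` at ``approach_slope`` (kept well
    below spike-detection dV/dt criteria); a linear rise threshold→peak over
    ``rise_duration``; a linear fall from the peak at slope
    ``(peak−threshold)/fall_duration`` down to ``resting − ahp_depth``; then
    exponential recovery to resting with time constant ``ahp_tau``.

    With this geometry the half-level (midway threshold/peak) is crossed at
    half of ``rise_duration`` and half of ``fall_duration``, so the true
    halfwidth is ``(rise_duration + fall_duration) / 2`` and the derivative
    extrema are the two linear slopes.
    """

    resting: float = -76.0        # mV
    threshold: float = -45.0      # mV
    peak: float = 15.0            # mV
    rise_duration: float = 0.2    # ms (threshold -> peak)
    fall_duration: float = 0.3    # ms (peak -> threshold, sets fall slope)
    ahp_depth: float = 6.0        # mV below resting
    ahp_tau: float = 5.0          # ms
    onset_time: float = 5.0       # ms (start of the slow approach)
    approach_slope: float = 10.0  # mV/ms (= 0.01 V/ms)
    tail_ms: float | None = None  # post-AHP-minimum window; default 8·ahp_tau

    def __post_init__(self):
        if not (self.resting < self.threshold < self.peak):
            raise InvalidParameterError(
                "need resting < threshold < peak")
        if self.rise_duration <= 0 or self.fall_duration <= 0:
            raise InvalidParameterError("durations must be > 0")
        if self.ahp_depth < 0:
            raise InvalidParameterError("ahp_depth must be >= 0")
        if self.ahp_tau <= 0:
            raise InvalidParameterError("ahp_tau must be > 0")
        if self.approach_slope <= 0:
            raise InvalidParameterError("approach_slope must be > 0")

    # -- derived geometry (all ms / mV) -------------------------------
    @property
    def approach_duration(self) -> float:
        return (self.threshold - self.resting) / self.approach_slope

    @property
    def t_threshold(self) -> float:
        return self.onset_time + self.approach_duration

    @property
    def t_peak(self) -> float:
        return self.t_threshold + self.rise_duration

    @property
    def fall_slope(self) -> float:
        """mV/ms, positive magnitude."""
        return (self.peak - self.threshold) / self.fall_duration

    @property
    def t_ahp_min(self) -> float:
        total_drop = self.peak - (self.resting - self.ahp_depth)
        return self.t_peak + total_drop / self.fall_slope

    def truth(self) -> dict:
        """Closed-form feature values of the waveform."""
        out = {
            "resting": self.resting,
            "v_thres": self.threshold,
            "peak": self.peak,
            "amplitude": self.peak - self.resting,
            "halfwidth": 0.5 * (self.rise_duration + self.fall_duration),
            "dvdt_max": (self.peak - self.threshold) / self.rise_duration
            / 1000.0,   # V/ms
            "dvdt_min": -self.fall_slope / 1000.0,  # V/ms
            "t_peak": self.t_peak,
            "t_threshold": self.t_threshold,
        }
        if self.ahp_depth > 0:
            out["ahp_tau"] = self.ahp_tau
            out["ahp_halftime"] = self.ahp_tau * math.log(2.0)
            out["t_ahp_min"] = self.t_ahp_min
        return out


def parametric_ap_voltage(t: np.ndarray, p: ParametricAPParams) -> np.ndarray:
    """Evaluate the piecewise waveform at arbitrary times (ms)."""
    t = np.asarray(t, dtype=float)
    v = np.full(t.shape, p.resting)
    t_on, t_thr, t_pk, t_min = (p.onset_time, p.t_threshold, p.t_peak,
                                p.t_ahp_min)
    seg = (t >= t_on) & (t < t_thr)
    v[seg] = p.resting + p.approach_slope * (t[seg] - t_on)
    seg = (t >= t_thr) & (t < t_pk)
    v[seg] = p.threshold + (p.peak - p.threshold) * (t[seg] - t_thr) \
        / p.rise_duration
    seg = (t >= t_pk) & (t < t_min)
    v[seg] = p.peak - p.fall_slope * (t[seg] - t_pk)
    seg = t >= t_min
    if p.ahp_depth > 0:
        v[seg] = p.resting - p.ahp_depth * np.exp(-(t[seg] - t_min)
                                                  / p.ahp_tau)
    return v


def gen_parametric_ap(params: ParametricAPParams, sample_rate: float = 100.0
                      ) -> tuple[Sweep, dict]:
    """Render one parametric AP sweep at ``sample_rate`` kHz.

    The ground-truth feature dict (closed form, independent of sampling) is
    returned alongside.
    """
    if sample_rate <= 0:
        raise InvalidParameterError("sample_rate must be > 0")
    si = 1.0 / sample_rate
    tail = params.tail_ms if params.tail_ms is not None \
        else max(20.0, 8.0 * params.ahp_tau)
    total = params.t_ahp_min + tail
    t = np.arange(int(round(total / si))) * si
    v = parametric_ap_voltage(t, params)
    sweep = Sweep(v, si, kind=VOLTAGE, ljp_corrected=True,
                  stimulus={"protocol": "parametric_ap",
                            "onset_ms": params.onset_time})
    return sweep, params.truth()


# ---------------------------------------------------------------------------
# Ramp families (parametric)
# ---------------------------------------------------------------------------

def gen_ramp_family(ap: ParametricAPParams,
                    first_ap_current: float,
                    currents: np.ndarray | None = None,
                    current_increment: float = 50.0,
                    max_current: float = 1000.0,
                    sample_rate: float = 100.0,
                    ramp_onset: float = 5.0,
                    noise_sd: float = 0.0,
                    seed: int = 0) -> tuple[SweepSet, np.ndarray, dict]:
    """Family of voltage responses to ramp currents of increasing amplitude.

    Sweeps at currents below ``first_ap_current`` contain a subthreshold
    depolarizing hump scaling with the ramp amplitude; sweeps at or above it
    contain the parametric AP.  Returns (sweep set, currents, truth).
    """
    if currents is None:
        currents = np.arange(current_increment, max_current + 1e-9,
                             current_increment)
    currents = np.asarray(currents, dtype=float)
    if np.any(np.diff(currents) <= 0):
        raise InvalidParameterError("ramp currents must be strictly increasing")
    rng = np.random.default_rng(seed)
    si = 1.0 / sample_rate
    ap_on = ParametricAPParams(**{**asdict(ap), "onset_time": ramp_onset})
    tail = ap_on.tail_ms if ap_on.tail_ms is not None \
        else max(20.0, 8.0 * ap_on.ahp_tau)
    total = ap_on.t_ahp_min + tail
    t = np.arange(int(round(total / si))) * si
    sub_peak = 0.8 * (ap.threshold - ap.resting)
    sweeps = []
    for amp in currents:
        if amp >= first_ap_current:
            v = parametric_ap_voltage(t, ap_on)
        else:
            # subthreshold alpha-shaped hump, peak scaled by amplitude
            scale = sub_peak * amp / first_ap_current
            tt = np.clip(t - ramp_onset, 0.0, None)
            v = ap.resting + scale * (tt / 1.0) * np.exp(1.0 - tt / 1.0)
        if noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd, v.size)
        sweeps.append(Sweep(v, si, kind=VOLTAGE, ljp_corrected=True,
                            stimulus={"protocol": "ramp",
                                      "amplitude_pa": float(amp),
                                      "onset_ms": ramp_onset,
                                      "rise_ms": 0.2, "fall_ms": 0.8}))
    truth = dict(ap_on.truth())
    supra = currents[currents >= first_ap_current]
    truth["ramp_current_at_first_ap"] = float(supra[0]) if supra.size \
        else None
    return SweepSet(sweeps), currents, truth


# ---------------------------------------------------------------------------
# Latency / train sets (parametric)
# ---------------------------------------------------------------------------

def _compact_ap(ap: ParametricAPParams, onset_time: float
                ) -> ParametricAPParams:
    d = asdict(ap)
    d["onset_time"] = onset_time
    return ParametricAPParams(**d)


def gen_square_latency_set(ap: ParametricAPParams,
                           n_repetitions: int = 100,
                           latency_mean: float = 2.2,
                           latency_sd: float = 0.15,
                           p_supra: float = 0.6,
                           stimulus_onset: float = 5.0,
                           amplitude_pa: float = 270.0,
                           duration_ms: float = 30.0,
                           sample_rate: float = 50.0,
                           seed: int = 0) -> tuple[SweepSet, dict]:
    """Rheobase square-step repetitions: a mix of sub- and suprathreshold
    responses with AP peak latencies drawn Normal(mean, sd²).

    Truth carries the drawn latencies (continuous, ms from stimulus onset to
    AP peak) and the suprathreshold mask.
    """
    if not 0 <= p_supra <= 1:
        raise InvalidParameterError("p_supra must be in [0, 1]")
    rng = np.random.default_rng(seed)
    si = 1.0 / sample_rate
    total = stimulus_onset + duration_ms
    t = np.arange(int(round(total / si))) * si
    supra = rng.random(n_repetitions) < p_supra
    lat = np.clip(rng.normal(latency_mean, latency_sd, n_repetitions),
                  0.3, None)
    stim = {"protocol": "square", "amplitude_pa": amplitude_pa,
            "onset_ms": stimulus_onset, "duration_ms": duration_ms}
    # subthreshold template: relax toward just under threshold
    sub_target = ap.resting + 0.7 * (ap.threshold - ap.resting)
    tt = np.clip(t - stimulus_onset, 0.0, None)
    sub_v = ap.resting + (sub_target - ap.resting) * (1 - np.exp(-tt / 3.0))
    sweeps = []
    for r in range(n_repetitions):
        if supra[r]:
            # place the AP so its peak sits at onset + latency
            pk_target = stimulus_onset + lat[r]
            ap_r = _compact_ap(ap, onset_time=pk_target
                               - ap.approach_duration - ap.rise_duration)
            v = parametric_ap_voltage(t, ap_r)
        else:
            v = sub_v.copy()
        sweeps.append(Sweep(v, si, kind=VOLTAGE, ljp_corrected=True,
                            stimulus=dict(stim)))
    truth = {"latencies_ms": lat[supra],
             "supra_mask": supra,
             "mean_latency": float(np.mean(lat[supra])) if supra.any()
             else float("nan"),
             "jitter": float(np.std(lat[supra], ddof=1))
             if supra.sum() > 1 else float("nan"),
             "rheobase_current_pa": amplitude_pa}
    return SweepSet(sweeps), truth


#: compact AP shape that fits inside a 2 ms inter-pulse window
TRAIN_AP = ParametricAPParams(resting=-76.0, threshold=-45.0, peak=10.0,
                              rise_duration=0.1, fall_duration=0.15,
                              ahp_depth=3.0, ahp_tau=0.25, onset_time=0.0,
                              approach_slope=120.0, tail_ms=0.5)


def gen_train_set(n_repetitions: int = 20,
                  n_pulses: int = 30,
                  frequency_hz: float = 500.0,
                  onset: float = 5.0,
                  latency_profile: np.ndarray | float = 0.5,
                  jitter_profile: np.ndarray | float = 0.0,
                  p_missing: np.ndarray | float = 0.0,
                  amplitude_pa: float = 1200.0,
                  ap: ParametricAPParams = TRAIN_AP,
                  sample_rate: float = 100.0,
                  seed: int = 0) -> tuple[SweepSet, dict]:
    """Repetitions of a 30-pulse 500 Hz train with per-pulse latency model.

    ``latency_profile`` gives the mean AP-peak latency per pulse (ms after
    each pulse onset), ``jitter_profile`` the per-pulse latency SD, and
    ``p_missing`` a per-pulse failure probability; scalars broadcast over
    pulses.  Truth carries the realized latency matrix (NaN = missing).
    """
    period = 1000.0 / frequency_hz
    mean_lat = np.broadcast_to(np.asarray(latency_profile, float),
                               (n_pulses,)).copy()
    sd_lat = np.broadcast_to(np.asarray(jitter_profile, float),
                             (n_pulses,)).copy()
    p_miss = np.broadcast_to(np.asarray(p_missing, float),
                             (n_pulses,)).copy()
    if np.any(mean_lat <= 0):
        raise InvalidParameterError("latencies must be > 0")
    rng = np.random.default_rng(seed)
    si = 1.0 / sample_rate
    pulse_onsets = onset + period * np.arange(n_pulses)
    total = onset + n_pulses * period + 5.0
    t = np.arange(int(round(total / si))) * si
    lat = rng.normal(mean_lat, sd_lat, size=(n_repetitions, n_pulses))
    lat = np.clip(lat, 0.25, period - 0.35)
    missing = rng.random((n_repetitions, n_pulses)) < p_miss
    lat[missing] = np.nan
    stim = {"protocol": "train", "amplitude_pa": amplitude_pa,
            "onset_ms": onset, "n_pulses": n_pulses,
            "frequency_hz": frequency_hz,
            "pulse_onsets_ms": list(pulse_onsets)}
    sweeps = []
    for r in range(n_repetitions):
        v = np.full(t.size, ap.resting)
        for k in range(n_pulses):
            if missing[r, k]:
                continue
            pk_target = pulse_onsets[k] + lat[r, k]
            ap_k = _compact_ap(ap, onset_time=pk_target
                               - ap.approach_duration - ap.rise_duration)
            win = (t >= pulse_onsets[k]) & (t < pulse_onsets[k] + period)
            v[win] = parametric_ap_voltage(t[win], ap_k)
        sweeps.append(Sweep(v, si, kind=VOLTAGE, ljp_corrected=True,
                            stimulus=dict(stim)))
    truth = {"latencies_ms": lat, "pulse_onsets_ms": pulse_onsets,
             "missing": missing}
    return SweepSet(sweeps), truth


# ---------------------------------------------------------------------------
# Vacuole stacks
# ---------------------------------------------------------------------------

@dataclass
class VacuoleStackParams:
    """Synthetic confocal stack of one dye-filled soma with dark vacuoles.

    Intensities are 8-bit levels; the rendered stack is 16-bit (level × 257
    plus noise).  Voxel sizes follow the acquisition convention of 320 nm
    x/y steps and a 290 nm z step.  Vacuoles are spheres (in voxel units)
    that must lie fully inside the soma ellipsoid; alternatively a target
    in-soma volume fraction can be requested and spheres are placed by the
    seeded generator until it is reached.
    """

    shape: tuple[int, int, int] = (21, 128, 128)      # (z, y, x) voxels
    voxel_size_nm: tuple[float, float, float] = (320.0, 320.0, 290.0)
    soma_center: tuple[float, float, float] | None = None  # (z, y, x)
    soma_semiaxes: tuple[float, float, float] = (8.0, 40.0, 40.0)
    cytoplasm_level: float = 200.0
    background_level: float = 10.0
    vacuole_level: float = 40.0
    vacuoles: list[tuple[float, float, float, float]] | None = None
    target_volume_fraction: float | None = None
    vacuole_radius_range: tuple[float, float] = (4.0, 7.0)
    blur_sigma: float = 0.5            # voxels (~160 nm, confocal PSF scale)
    noise_sd: float = 8.0              # 8-bit intensity units
    seed: int = 0

    def __post_init__(self):
        for lvl in (self.cytoplasm_level, self.background_level,
                    self.vacuole_level):
            if not 0 <= lvl <= 255:
                raise InvalidParameterError("intensity levels must be 8-bit")
        if self.target_volume_fraction is not None and \
                not 0 <= self.target_volume_fraction < 1:
            raise InvalidParameterError("target fraction must be in [0, 1)")
        if self.soma_center is None:
            self.soma_center = tuple(s / 2.0 for s in self.shape)


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    zz, yy, xx = np.ogrid[:shape[0], :shape[1], :shape[2]]
    return (((zz - center[0]) / semiaxes[0]) ** 2
            + ((yy - center[1]) / semiaxes[1]) ** 2
            + ((xx - center[2]) / semiaxes[2]) ** 2) <= 1.0


def _sphere_inside_soma(c, r, center, semiaxes) -> bool:
    # sufficient condition: center within the ellipsoid shrunk by r
    shrunk = [max(a - r, 1e-9) for a in semiaxes]
    return sum(((c[i] - center[i]) / shrunk[i]) ** 2 for i in range(3)) <= 1.0


def gen_vacuole_stack(params: VacuoleStackParams
                      ) -> tuple[ImageStack, dict]:
    """Render the stack and its ground truth.

    Truth is the black/white pixel ratio of the *noiseless, unblurred*
    3-plane maximum projection centred on the nucleus plane (the soma
    centre plane), restricted to the projected soma mask; a projected pixel
    is black when its ideal intensity is below the midpoint of the vacuole
    and cytoplasm levels.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    soma = _ellipsoid_mask(p.shape, p.soma_center, p.soma_semiaxes)
    vac_mask = np.zeros(p.shape, dtype=bool)

    vacuoles = list(p.vacuoles) if p.vacuoles else []
    for (cz, cy, cx, r) in vacuoles:
        if not _sphere_inside_soma((cz, cy, cx), r, p.soma_center,
                                   p.soma_semiaxes):
            raise InvalidParameterError(
                f"vacuole at ({cz},{cy},{cx}) r={r} lies outside the soma")
        vac_mask |= _ellipsoid_mask(p.shape, (cz, cy, cx), (r, r, r))
    if p.target_volume_fraction:
        n_soma = soma.sum()
        guard = 0
        while vac_mask[soma].sum() / n_soma < p.target_volume_fraction:
            guard += 1
            if guard > 10_000:
                raise InvalidParameterError(
                    "cannot reach target volume fraction with given geometry")
            r = rng.uniform(*p.vacuole_radius_range)
            # uniform in the bounding box, rejected if not inside soma - r
            c = [rng.uniform(p.soma_center[i] - p.soma_semiaxes[i],
                             p.soma_center[i] + p.soma_semiaxes[i])
                 for i in range(3)]
            if not _sphere_inside_soma(c, r, p.soma_center, p.soma_semiaxes):
                continue
            vac_mask |= _ellipsoid_mask(p.shape, c, (r, r, r))
            vacuoles.append((*c, r))

    ideal = np.full(p.shape, p.background_level, dtype=float)
    ideal[soma] = p.cytoplasm_level
    ideal[vac_mask & soma] = p.vacuole_level

    # ground truth from the ideal projection
    zc = int(round(p.soma_center[0]))
    z0 = max(0, zc - 1)
    proj = ideal[z0:z0 + 3].max(axis=0)
    proj_mask = soma[z0:z0 + 3].any(axis=0)
    cut = 0.5 * (p.vacuole_level + p.cytoplasm_level)
    black = int(((proj < cut) & proj_mask).sum())
    white = int(proj_mask.sum() - black)
    truth = {
        "nucleus_plane": zc,
        "black_pixels": black,
        "white_pixels": white,
        "bw_ratio": black / white if white else float("inf"),
        "n_vacuoles": len(vacuoles),
        "volume_fraction": float(vac_mask[soma].sum() / soma.sum()),
    }

    rendered = ideal.copy()
    if p.blur_sigma > 0:
        rendered = ndimage.gaussian_filter(rendered, p.blur_sigma)
    if p.noise_sd > 0:
        rendered = rendered + rng.normal(0.0, p.noise_sd, rendered.shape)
    stack16 = np.clip(rendered * 257.0, 0, 65535).astype(np.uint16)
    return ImageStack(stack16, voxel_size_nm=p.voxel_size_nm), truth
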