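"""Single-compartment conductance-model neuron used as a simulation harness.

The model is a generic Na / low-threshold K (KLT) / high-threshold K (KHT) /
leak point neuron in the style of classic ventral-brainstem models.  It is a
test harness for the feature extractors, not a biophysical claim about any
particular cell type: the KHT (Kv3-flavoured) conductance is the dial of
interest, because fast high-threshold potassium current speeds action
potential repolarization — scaling it down must broaden the spike, make the
repolarization slope shallower, and degrade entrainment to fast pulse
trains.

State variables: membrane voltage V (mV) and gates m, h (Na activation /
inactivation), n (KHT activation), w (KLT activation).  Currents in pA,
conductances in nS, capacitance in pF, time in ms — with these units
C dV/dt = I balances dimensionally without conversion factors.

Integration is fixed-step classical Runge-Kutta (RK4), default dt = 5 µs,
vectorized across repetitions.  Optional noise is an additive Gaussian
current, constant within each stimulus sample, drawn per repetition from the
seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import IntegrationFailureError, InvalidParameterError
from .traceio import CURRENT, Sweep, SweepSet, VOLTAGE


@dataclass
class NeuronModelParams:
    """Conductances (nS), reversals (mV), capacitance (pF) and gating rate
    scale of the point-neuron model.

    ``rate_scale`` multiplies all gating rates (divides all time constants);
    the default of 6 brings the room-temperature kinetics of the underlying
    rate functions into the fast regime needed for sub-millisecond spikes
    and 500 Hz entrainment.
    """

    capacitance: float = 20.0          # pF
    leak_conductance: float = 4.0      # nS
    na_conductance: float = 2000.0     # nS
    klt_conductance: float = 120.0     # nS
    kht_conductance: float = 300.0     # nS
    e_na: float = 55.0                 # mV
    e_k: float = -90.0                 # mV
    e_leak: float = -66.0              # mV
    rate_scale: float = 6.0            # dimensionless, divides gating taus
    integration_dt: float = 0.005      # ms

    def __post_init__(self):
        for name in ("leak_conductance", "na_conductance",
                     "klt_conductance", "kht_conductance"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if not 0 < self.integration_dt <= 0.01:
            raise InvalidParameterError("integration_dt must be in (0, 0.01] ms")
        if self.capacitance <= 0:
            raise InvalidParameterError("capacitance must be > 0")


def _gate_steady_tau(v: np.ndarray):
    """Steady states and time constants (ms) of all gates at voltage v."""
    m_inf = 1.0 / (1.0 + np.exp(-(v + 38.0) / 7.0))
    tau_m = 0.04 + 10.0 / (5.0 * np.exp((v + 60.0) / 18.0)
                           + 36.0 * np.exp(-(v + 60.0) / 25.0))
    h_inf = 1.0 / (1.0 + np.exp((v + 65.0) / 6.0))
    tau_h = 0.6 + 100.0 / (7.0 * np.exp((v + 60.0) / 11.0)
                           + 10.0 * np.exp(-(v + 60.0) / 25.0))
    n_inf = 1.0 / (1.0 + np.exp(-(v + 15.0) / 5.0))
    tau_n = 0.5 + 100.0 / (11.0 * np.exp((v + 60.0) / 24.0)
                           + 21.0 * np.exp(-(v + 60.0) / 23.0))
    w_inf = (1.0 / (1.0 + np.exp(-(v + 48.0) / 6.0))) ** 0.25
    tau_w = 1.5 + 100.0 / (6.0 * np.exp((v + 60.0) / 6.0)
                           + 16.0 * np.exp(-(v + 60.0) / 45.0))
    return (m_inf, tau_m, h_inf, tau_h, n_inf, tau_n, w_inf, tau_w)


def _derivatives(state: np.ndarray, i_stim: np.ndarray,
                 p: NeuronModelParams) -> np.ndarray:
    v, m, h, n, w = state
    m_inf, tau_m, h_inf, tau_h, n_inf, tau_n, w_inf, tau_w = _gate_steady_tau(v)
    i_na = p.na_conductance * m ** 3 * h * (v - p.e_na)
    i_kht = p.kht_conductance * n ** 2 * (v - p.e_k)
    i_klt = p.klt_conductance * w ** 4 * (v - p.e_k)
    i_leak = p.leak_conductance * (v - p.e_leak)
    dv = (i_stim - i_na - i_kht - i_klt - i_leak) / p.capacitance
    r = p.rate_scale
    return np.stack([
        dv,
        r * (m_inf - m) / tau_m,
        r * (h_inf - h) / tau_h,
        r * (n_inf - n) / tau_n,
        r * (w_inf - w) / tau_w,
    ])


def resting_state(p: NeuronModelParams, v0: float = -65.0,
                  settle_ms: float = 200.0) -> np.ndarray:
    """Relax the model to its resting fixed point with no stimulus.

    Uses a coarse forward relaxation (gates clamped to steady state each
    step) which converges to the same fixed point as the full dynamics.
    """
    v = np.array([v0])
    for _ in range(int(settle_ms / 0.05)):
        m_inf, _, h_inf, _, n_inf, _, w_inf, _ = _gate_steady_tau(v)
        state = np.stack([v, m_inf, h_inf, n_inf, w_inf])
        dv = _derivatives(state, np.zeros_like(v), p)[0]
        v = v + 0.05 * dv
    m_inf, _, h_inf, _, n_inf, _, w_inf, _ = _gate_steady_tau(v)
    return np.stack([v, m_inf, h_inf, n_inf, w_inf])


def integrate_batch(model: NeuronModelParams, drive: np.ndarray,
                    sample_interval: float) -> np.ndarray:
    """RK4-integrate a (batch, n_samples) array of current drives.

    Low-level core shared by :func:`simulate_neuron` and cohort code; the
    drive is held constant within each stimulus sample.  Returns the
    (batch, n_samples) voltage array.
    """
    dt = model.integration_dt
    n_sub = sample_interval / dt
    if abs(n_sub - round(n_sub)) > 1e-9:
        raise InvalidParameterError(
            f"integration_dt {dt} ms must divide sample interval "
            f"{sample_interval} ms")
    n_sub = int(round(n_sub))
    batch, n_samp = drive.shape
    state = np.repeat(resting_state(model), batch, axis=1)
    out = np.empty((batch, n_samp))
    out[:, 0] = state[0]
    half = 0.5 * dt
    sixth = dt / 6.0
    for i in range(1, n_samp):
        i_stim = drive[:, i - 1]
        for _ in range(n_sub):
            k1 = _derivatives(state, i_stim, model)
            k2 = _derivatives(state + half * k1, i_stim, model)
            k3 = _derivatives(state + half * k2, i_stim, model)
            k4 = _derivatives(state + dt * k3, i_stim, model)
            state = state + sixth * (k1 + 2 * k2 + 2 * k3 + k4)
        out[:, i] = state[0]
        if np.any(np.abs(state[0]) > 200.0):
            raise IntegrationFailureError(
                f"voltage diverged beyond 200 mV at dt={dt} ms")
    return out


def simulate_neuron(model: NeuronModelParams, stimulus: Sweep,
                    seed: int = 0, n_repetitions: int = 1,
                    noise_sd: float = 0.0) -> SweepSet:
    """Integrate the model under a current stimulus with fixed-step RK4.

    Parameters
    ----------
    stimulus
        A current sweep (pA).  ``model.integration_dt`` must divide its
        sample interval so output samples land exactly on stimulus samples.
    n_repetitions, noise_sd
        Number of repetitions integrated in parallel; each receives its own
        additive Gaussian current noise (pA, constant within one stimulus
        sample) drawn from ``numpy.random.default_rng(seed)``.

    Returns
    -------
    SweepSet of voltage sweeps (mV), one per repetition, already at true
    membrane potential (flagged LJP-corrected).
    """
    if stimulus.kind != CURRENT:
        raise InvalidParameterError("stimulus must be a current sweep")
    dt = model.integration_dt
    si = stimulus.sample_interval
    n_sub = si / dt
    if abs(n_sub - round(n_sub)) > 1e-9:
        raise InvalidParameterError(
            f"integration_dt {dt} ms must divide sample interval {si} ms")
    n_sub = int(round(n_sub))
    rng = np.random.default_rng(seed)
    n_samp = stimulus.n_samples
    stim = stimulus.samples
    if noise_sd > 0:
        drive = stim[None, :] + rng.normal(0.0, noise_sd,
                                           size=(n_repetitions, n_samp))
    else:
        drive = np.broadcast_to(stim[None, :], (n_repetitions, n_samp)).copy()
    out = integrate_batch(model, drive, si)
    sweeps = [
        Sweep(out[r], si, kind=VOLTAGE, stimulus=dict(stimulus.stimulus),
              cell_id=stimulus.cell_id, group=stimulus.group,
              ljp_corrected=True)
        for r in range(n_repetitions)
    ]
    return SweepSet(sweeps)


# ---------------------------------------------------------------------------
# Stimulus builders (current sweeps, pA)
# ---------------------------------------------------------------------------

def ramp_stimulus(peak_pa: float, sample_interval: float = 0.01,
                  onset: float = 5.0, rise: float = 0.2, fall: float = 0.8,
                  total: float = 20.0) -> Sweep:
    """Asymmetric current ramp: linear rise then linear descent to zero."""
    t = np.arange(int(round(total / sample_interval))) * sample_interval
    i = np.zeros_like(t)
    up = (t >= onset) & (t < onset + rise)
    i[up] = peak_pa * (t[up] - onset) / rise
    down = (t >= onset + rise) & (t < onset + rise + fall)
    i[down] = peak_pa * (1.0 - (t[down] - onset - rise) / fall)
    return Sweep(i, sample_interval, kind=CURRENT,
                 stimulus={"protocol": "ramp", "amplitude_pa": peak_pa,
                           "onset_ms": onset, "rise_ms": rise,
                           "fall_ms": fall})


def square_stimulus(amplitude_pa: float, sample_interval: float = 0.01,
                    onset: float = 5.0, duration: float = 500.0,
                    post: float = 5.0) -> Sweep:
    """Square current step of given amplitude and duration."""
    total = onset + duration + post
    t = np.arange(int(round(total / sample_interval))) * sample_interval
    i = np.where((t >= onset) & (t < onset + duration), amplitude_pa, 0.0)
    return Sweep(i, sample_interval, kind=CURRENT,
                 stimulus={"protocol": "square", "amplitude_pa": amplitude_pa,
                           "onset_ms": onset, "duration_ms": duration})


def train_stimulus(amplitude_pa: float, n_pulses: int = 30,
                   frequency_hz: float = 500.0,
                   sample_interval: float = 0.01, onset: float = 5.0,
                   rise: float = 0.2, fall: float = 0.8,
                   post: float = 5.0) -> Sweep:
    """Train of ramp-shaped current pulses (default 30 pulses at 500 Hz)."""
    period = 1000.0 / frequency_hz
    total = onset + n_pulses * period + post
    t = np.arange(int(round(total / sample_interval))) * sample_interval
    i = np.zeros_like(t)
    onsets = onset + period * np.arange(n_pulses)
    for t0 in onsets:
        up = (t >= t0) & (t < t0 + rise)
        i[up] = amplitude_pa * (t[up] - t0) / rise
        down = (t >= t0 + rise) & (t < t0 + rise + fall)
        i[down] = amplitude_pa * (1.0 - (t[down] - t0 - rise) / fall)
    return Sweep(i, sample_interval, kind=CURRENT,
                 stimulus={"protocol": "train", "amplitude_pa": amplitude_pa,
                           "onset_ms": onset, "n_pulses": n_pulses,
                           "frequency_hz": frequency_hz,
                           "pulse_onsets_ms": list(onsets),
                           "rise_ms": rise, "fall_ms": fall})
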