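"""Whole-cohort synthesis: four groups of cells with per-group parameter
distributions, written as a directory bundle the pipeline consumes
end-to-end.

Groups follow the study design: wild type (WT), untreated knockout (KO)
and knockout under low-/high-dose substrate-reduction treatment (LD/HD).
Group medians default to the published group medians where those are
printed (ramp current at first AP, voltage threshold, AP amplitude,
halfwidth, dV/dt min, rheobase, latency, jitter, minimum sustain current,
B/W vacuolization ratio); within-group variability is not reported
anywhere, so scale parameters draw lognormal around the median with a
default coefficient of variation of 0.12 and voltages draw normal with a
1.5 mV SD — documented as a package choice.

Every cell's drawn ground-truth parameters are written to a JSON sidecar;
:func:`gen_feature_table` returns the drawn values alone (no waveform
rendering), which is what the null-calibration simulations use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .synth import (
    ParametricAPParams,
    PassiveCircuitParams,
    VacuoleStackParams,
    biexp_charge,
    gen_cc_step_response,
    gen_ramp_family,
    gen_square_latency_set,
    gen_train_set,
    gen_vacuole_stack,
    gen_vc_transient,
)
from .traceio import (
    CellRecord,
    GROUPS,
    SweepSet,
    write_json,
    write_stack,
    write_sweeps,
)

#: train amplitude ladder used for the minimum-sustain-current protocol (pA)
TRAIN_LADDER = (1000.0, 1200.0, 1400.0, 1600.0, 1800.0, 2000.0)


@dataclass
class GroupSpec:
    """Median cell parameters of one group (units as named)."""

    name: str
    n_cells: int = 6
    capacitance_pf: float = 20.0
    r_in_mohm: float = 150.0
    e_rest_mv: float = -76.0
    v_thres_mv: float = -44.72
    ap_amplitude_mv: float = 73.39
    halfwidth_ms: float = 0.194
    dvdt_min_vpms: float = -0.493
    ahp_halftime_ms: float = 2.0
    ramp_first_pa: float = 700.0
    rheobase_pa: float = 270.0
    latency_ms: float = 2.16
    jitter_ms: float = 0.162
    min_sustain_pa: float = 1200.0
    train_latency_plateau: float = 1.25   # normalized plateau of the series
    train_latency_slope: float = 0.0      # extra per-pulse drift (KO-like)
    train_jitter_ratio: float = 1.0       # last-5 / first jitter target
    vacuole_fraction: float = 0.048       # target projected dark fraction
    cv: float = 0.12                      # lognormal CV for scale params
    voltage_sd_mv: float = 1.5            # normal SD for voltages

    def __post_init__(self):
        if self.n_cells < 1:
            raise InvalidParameterError(f"empty group {self.name!r}")


@dataclass
class CohortConfig:
    """Cohort composition and rendering sizes.

    Rendering sizes (repetition counts, durations) are deliberately
    smaller than the acquisition protocol defaults so a full cohort stays
    desk-scale; the estimators are invariant to the number of identical
    repetitions, and the per-protocol generators keep the study-scale
    defaults.
    """

    groups: list[GroupSpec]
    sample_rate_khz: float = 50.0
    ap_sample_rate_khz: float = 100.0
    n_vc_reps: int = 25
    n_cc_reps: int = 25
    n_square_reps: int = 30
    n_train_reps: int = 8
    square_duration_ms: float = 30.0
    vc_noise_pa: float = 2.0
    cc_noise_mv: float = 0.05
    ramp_noise_mv: float = 0.05
    stack_shape: tuple[int, int, int] = (15, 110, 110)
    soma_semiaxes: tuple[float, float, float] = (5.0, 34.0, 34.0)

    def __post_init__(self):
        if not self.groups:
            raise InvalidParameterError("cohort needs at least one group")
        seen = set()
        for g in self.groups:
            if g.name in seen:
                raise InvalidParameterError(f"duplicate group {g.name!r}")
            seen.add(g.name)


def default_cohort_config(n_cells: int = 6) -> CohortConfig:
    """Four-group cohort at the published group medians."""
    wt = GroupSpec("WT", n_cells)
    ko = GroupSpec("KO", n_cells, v_thres_mv=-38.78, ap_amplitude_mv=59.37,
                   halfwidth_ms=0.358, dvdt_min_vpms=-0.173,
                   ahp_halftime_ms=3.5, ramp_first_pa=475.0,
                   rheobase_pa=175.0, latency_ms=2.36, jitter_ms=0.336,
                   min_sustain_pa=1800.0, train_latency_plateau=1.0,
                   train_latency_slope=0.02, train_jitter_ratio=2.0,
                   vacuole_fraction=0.387)
    ld = GroupSpec("LD", n_cells, v_thres_mv=-41.41, ap_amplitude_mv=63.67,
                   halfwidth_ms=0.264, dvdt_min_vpms=-0.24,
                   ahp_halftime_ms=3.2, ramp_first_pa=525.0,
                   rheobase_pa=175.0, latency_ms=2.26, jitter_ms=0.326,
                   min_sustain_pa=1400.0, train_latency_plateau=1.3,
                   train_jitter_ratio=1.2, vacuole_fraction=0.258)
    hd = GroupSpec("HD", n_cells, v_thres_mv=-39.27, ap_amplitude_mv=69.01,
                   halfwidth_ms=0.229, dvdt_min_vpms=-0.38,
                   ahp_halftime_ms=3.0, ramp_first_pa=575.0,
                   rheobase_pa=237.5, latency_ms=2.14, jitter_ms=0.204,
                   min_sustain_pa=1400.0, train_latency_plateau=1.28,
                   train_jitter_ratio=1.1, vacuole_fraction=0.261)
    return CohortConfig(groups=[wt, ko, ld, hd])


def _lognormal(rng: np.random.Generator, median: float, cv: float) -> float:
    """Lognormal draw with the requested median (sign preserved)."""
    if median == 0:
        return 0.0
    return math.copysign(abs(median) * rng.lognormal(0.0, cv), median)


def draw_cell_params(spec: GroupSpec, rng: np.random.Generator) -> dict:
    """One cell's true parameter draw from the group distributions."""
    r_in = _lognormal(rng, spec.r_in_mohm, spec.cv)
    cap = _lognormal(rng, spec.capacitance_pf, spec.cv)
    e_rest = rng.normal(spec.e_rest_mv, spec.voltage_sd_mv)
    v_thres = rng.normal(spec.v_thres_mv, spec.voltage_sd_mv)
    amp = rng.normal(spec.ap_amplitude_mv, 2.0)
    peak = e_rest + amp
    hw = _lognormal(rng, spec.halfwidth_ms, spec.cv)
    dvdt_min = _lognormal(rng, spec.dvdt_min_vpms, spec.cv)
    # waveform geometry: fall time fixed by the repolarization slope,
    # rise time takes up the rest of the halfwidth
    fall = (peak - v_thres) / (abs(dvdt_min) * 1000.0)
    rise = max(2.0 * hw - fall, 0.05)
    hw_true = 0.5 * (rise + fall)
    ahp_halftime = _lognormal(rng, spec.ahp_halftime_ms, spec.cv)
    ramp_first = 50.0 * max(1, round(
        _lognormal(rng, spec.ramp_first_pa, spec.cv) / 50.0))
    min_sustain = min(TRAIN_LADDER,
                      key=lambda a: abs(a - _lognormal(
                          rng, spec.min_sustain_pa, spec.cv / 2)))
    return {
        "group": spec.name,
        "capacitance_pf": cap,
        "input_resistance_mohm": r_in,
        "tau_mem_ms": r_in * cap * 1e-3,
        "resting_mv": e_rest,
        "v_thres_mv": v_thres,
        "ap_amplitude_mv": amp,
        "ap_peak_mv": peak,
        "rise_ms": rise,
        "fall_ms": fall,
        "halfwidth_ms": hw_true,
        "dvdt_min_vpms": -(peak - v_thres) / fall / 1000.0,
        "ahp_halftime_ms": ahp_halftime,
        "ahp_tau_ms": ahp_halftime / math.log(2.0),
        "ramp_current_pa": float(ramp_first),
        "rheobase_pa": _lognormal(rng, spec.rheobase_pa, spec.cv),
        "latency_ms": rng.normal(spec.latency_ms, 0.08),
        "jitter_ms": _lognormal(rng, spec.jitter_ms, spec.cv),
        "min_sustain_pa": float(min_sustain),
        "train_latency_plateau": spec.train_latency_plateau,
        "train_latency_slope": spec.train_latency_slope,
        "train_jitter_ratio": _lognormal(rng, spec.train_jitter_ratio,
                                         spec.cv / 2),
        "vacuole_fraction": float(np.clip(
            rng.normal(spec.vacuole_fraction, 0.04), 0.0, 0.8)),
    }


def gen_feature_table(config: CohortConfig, seed: int = 0) -> pd.DataFrame:
    """Drawn true parameters for every cell of the cohort — the random part
    of cohort generation without waveform rendering."""
    rng = np.random.default_rng(seed)
    rows = []
    for spec in config.groups:
        for i in range(spec.n_cells):
            row = draw_cell_params(spec, rng)
            row["cell_id"] = f"{spec.name}_{i:03d}"
            rows.append(row)
    cols = ["cell_id", "group"] + [c for c in rows[0] if c not in
                                   ("cell_id", "group")]
    return pd.DataFrame(rows)[cols]


def _train_profiles(cell: dict, n_pulses: int = 30):
    """Per-pulse mean-latency and jitter profiles from the cell draw."""
    k = np.arange(n_pulses)
    base = 0.5
    plateau = cell["train_latency_plateau"]
    lat = base * (1.0 + (plateau - 1.0) * (1.0 - np.exp(-k / 4.0))
                  + cell["train_latency_slope"] * k)
    j0 = 0.03
    ratio = cell["train_jitter_ratio"]
    jit = j0 * (1.0 + (ratio - 1.0) * k / (n_pulses - 1))
    return lat, jit


def render_cell(cell: dict, config: CohortConfig, seed: int) -> dict:
    """Render every protocol of one cell from its drawn parameters.

    Returns a dict of in-memory objects: sweep sets, the image stack and
    the ground-truth record.
    """
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2 ** 31 - 1))  # noqa: E731

    # passive protocols: amplitudes solved so that the transient's
    # closed-form charge matches the drawn capacitance
    tau1, tau2, rho = 0.2, 1.0, 1.0 / 3.0
    unit = biexp_charge(1.0, tau1, rho, tau2)["charge_fc"]
    a1 = cell["capacitance_pf"] * 5.0 / unit
    passive = PassiveCircuitParams(
        amplitude_fast=a1, tau_fast=tau1, amplitude_slow=rho * a1,
        tau_slow=tau2, true_resistance=cell["input_resistance_mohm"],
        true_tau_mem=cell["tau_mem_ms"], true_resting=cell["resting_mv"],
        noise_sd=config.vc_noise_pa, sample_rate=config.sample_rate_khz,
        n_repetitions=config.n_vc_reps)
    vc_set, vc_truth = gen_vc_transient(passive, sub())
    passive_cc = replace(passive, noise_sd=config.cc_noise_mv,
                         n_repetitions=config.n_cc_reps)
    cc_set, cc_truth = gen_cc_step_response(passive_cc, -5.0, sub())

    ap = ParametricAPParams(
        resting=cell["resting_mv"], threshold=cell["v_thres_mv"],
        peak=cell["ap_peak_mv"], rise_duration=cell["rise_ms"],
        fall_duration=cell["fall_ms"], ahp_depth=6.0,
        ahp_tau=cell["ahp_tau_ms"], approach_slope=5.0)
    ramp_set, currents, ramp_truth = gen_ramp_family(
        ap, cell["ramp_current_pa"], max_current=1000.0,
        sample_rate=config.ap_sample_rate_khz,
        noise_sd=config.ramp_noise_mv, seed=sub())
    family_stim = {"protocol": "ramp_family",
                   "amplitudes_pa": list(map(float, currents)),
                   "onset_ms": 5.0, "rise_ms": 0.2, "fall_ms": 0.8}
    for s in ramp_set:
        s.stimulus = dict(family_stim)

    square_set, square_truth = gen_square_latency_set(
        ap, n_repetitions=config.n_square_reps,
        latency_mean=cell["latency_ms"], latency_sd=cell["jitter_ms"],
        amplitude_pa=cell["rheobase_pa"],
        duration_ms=config.square_duration_ms,
        sample_rate=config.sample_rate_khz, seed=sub())

    lat_prof, jit_prof = _train_profiles(cell)
    trains = {}
    for amp in TRAIN_LADDER:
        p_miss = 0.12 if amp < cell["min_sustain_pa"] else 0.0
        tset, ttruth = gen_train_set(
            n_repetitions=config.n_train_reps, latency_profile=lat_prof,
            jitter_profile=jit_prof, p_missing=p_miss, amplitude_pa=amp,
            sample_rate=config.ap_sample_rate_khz, seed=sub())
        trains[amp] = tset

    stack_params = VacuoleStackParams(
        shape=config.stack_shape, soma_semiaxes=config.soma_semiaxes,
        target_volume_fraction=cell["vacuole_fraction"] or None,
        seed=sub())
    stack, stack_truth = gen_vacuole_stack(stack_params)

    truth = dict(cell)
    truth.update(vc=vc_truth, cc=cc_truth, ramp=ramp_truth,
                 square={k: v for k, v in square_truth.items()
                         if k not in ("latencies_ms", "supra_mask")},
                 vacuole=stack_truth)
    return {"vc": vc_set, "cc": cc_set, "ramp": ramp_set,
            "square": square_set, "trains": trains, "stack": stack,
            "nucleus_plane": stack_truth["nucleus_plane"], "truth": truth}


def gen_cohort(outdir: str | Path, config: CohortConfig | None = None,
               seed: int = 0) -> pd.DataFrame:
    """Generate a full cohort bundle on disk.

    Layout::

        outdir/
          metadata.tsv            one row per cell with relative paths
          cells/<cell_id>/vc.tsv, cc.tsv, ramp.tsv, square.tsv,
                          train_<amp>.tsv, stack.tif
          truth/<cell_id>.json    drawn parameters + per-protocol truths

    Returns the metadata table.
    """
    if config is None:
        config = default_cohort_config()
    outdir = Path(outdir)
    (outdir / "cells").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    table = gen_feature_table(config, seed)
    rng = np.random.default_rng(seed + 1)
    rows = []
    for _, cell in table.iterrows():
        cid = cell["cell_id"]
        cdir = outdir / "cells" / cid
        cdir.mkdir(exist_ok=True)
        rendered = render_cell(cell.to_dict(), config,
                               int(rng.integers(0, 2 ** 31 - 1)))
        write_sweeps(rendered["vc"], cdir / "vc.tsv")
        write_sweeps(rendered["cc"], cdir / "cc.tsv")
        write_sweeps(rendered["ramp"], cdir / "ramp.tsv")
        write_sweeps(rendered["square"], cdir / "square.tsv")
        for amp, tset in rendered["trains"].items():
            write_sweeps(tset, cdir / f"train_{int(amp)}.tsv")
        write_stack(rendered["stack"], cdir / "stack.tif")
        write_json(rendered["truth"], outdir / "truth" / f"{cid}.json")
        rows.append({
            "cell_id": cid, "group": cell["group"],
            "nucleus_plane": rendered["nucleus_plane"],
            "path": str(Path("cells") / cid),
        })
    meta = pd.DataFrame(rows)
    meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    return meta
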