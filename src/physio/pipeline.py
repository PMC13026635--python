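"""End-to-end cohort analysis: bundle on disk → per-cell feature table →
group statistics report.

Analysis settings live in :class:`AnalysisConfig`; the defaults are tuned
to the synthetic cohort (slightly more permissive event criteria than the
single-cell defaults because group medians near the event-detection
boundary occur by design).  Per-cell failures are recorded as NaN features
rather than aborting the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import passive as passive_mod
from . import stats as stats_mod
from .errors import PhysioError
from .spikes import RampFamily, analyze_first_ap
from .timing import (
    find_min_sustain_current,
    jitter_ratio_last5,
    normalize_latency_series,
    rheobase_latency,
    train_latencies,
)
from .traceio import read_stack, read_sweeps, write_json
from .vacuoles import score_vacuolization

logger = logging.getLogger(__name__)

#: features reported per cell, in table order
FEATURES = [
    "capacitance_pf", "input_resistance_mohm", "tau_mem_ms", "resting_mv",
    "ramp_current_pa", "v_thres_mv", "ap_amplitude_mv", "halfwidth_ms",
    "dvdt_max_vpms", "dvdt_min_vpms", "ahp_halftime_ms",
    "rheobase_pa", "latency_ms", "jitter_ms",
    "min_sustain_pa", "norm_latency_last5", "jitter_ratio_last5",
    "bw_ratio",
]


@dataclass
class AnalysisConfig:
    peak_criterion_mv: float = -30.0
    dvdt_criterion_vpms: float = 0.02
    step_voltage_mv: float = -5.0
    step_current_pa: float = -5.0


def analyze_cell(cell_dir: str | Path, nucleus_plane: int | None = None,
                 config: AnalysisConfig | None = None) -> dict:
    """Run every analysis battery on one cell directory; missing protocols
    or per-protocol failures yield NaN features."""
    cfg = config or AnalysisConfig()
    cell_dir = Path(cell_dir)
    out: dict = {c: np.nan for c in FEATURES}

    e_rest = np.nan
    try:
        vc = read_sweeps(cell_dir / "vc.tsv")
        cc = read_sweeps(cell_dir / "cc.tsv")
        props = passive_mod.analyze_passive(
            vc, cc, step_voltage=cfg.step_voltage_mv,
            step_current=cfg.step_current_pa)
        out.update(capacitance_pf=props.capacitance,
                   input_resistance_mohm=props.input_resistance,
                   tau_mem_ms=props.tau_mem, resting_mv=props.resting)
        e_rest = props.resting
    except (PhysioError, FileNotFoundError) as exc:
        logger.warning("%s: passive battery failed: %s", cell_dir.name, exc)

    try:
        ramp = read_sweeps(cell_dir / "ramp.tsv")
        currents = ramp.sweeps[0].stimulus["amplitudes_pa"]
        family = RampFamily(ramp, np.asarray(currents))
        rest_ref = e_rest if np.isfinite(e_rest) else \
            float(ramp.sweeps[0].samples[:10].mean())
        feats = analyze_first_ap(family, rest_ref,
                                 peak_criterion=cfg.peak_criterion_mv,
                                 dvdt_criterion=cfg.dvdt_criterion_vpms)
        out.update(ramp_current_pa=feats.ramp_current_at_first_ap,
                   v_thres_mv=feats.v_thres,
                   ap_amplitude_mv=feats.amplitude,
                   halfwidth_ms=feats.halfwidth,
                   dvdt_max_vpms=feats.dvdt_max,
                   dvdt_min_vpms=feats.dvdt_min,
                   ahp_halftime_ms=feats.ahp_halftime
                   if feats.ahp_halftime is not None else np.nan)
    except (PhysioError, FileNotFoundError, KeyError) as exc:
        logger.warning("%s: AP battery failed: %s", cell_dir.name, exc)

    try:
        square = read_sweeps(cell_dir / "square.tsv")
        lat = rheobase_latency(square,
                               peak_criterion=cfg.peak_criterion_mv,
                               dvdt_criterion=cfg.dvdt_criterion_vpms)
        out.update(rheobase_pa=lat.rheobase_current,
                   latency_ms=lat.mean_latency, jitter_ms=lat.jitter)
    except (PhysioError, FileNotFoundError) as exc:
        logger.warning("%s: latency battery failed: %s", cell_dir.name, exc)

    try:
        train_files = sorted(cell_dir.glob("train_*.tsv"))
        if train_files:
            results = [train_latencies(
                read_sweeps(f), peak_criterion=cfg.peak_criterion_mv,
                dvdt_criterion=cfg.dvdt_criterion_vpms)
                for f in train_files]
            ms = find_min_sustain_current(results)
            at_ms = next(r for r in results if r.amplitude == ms)
            norm = normalize_latency_series(at_ms)
            out.update(min_sustain_pa=ms,
                       norm_latency_last5=float(np.nanmean(norm[-5:])),
                       jitter_ratio_last5=jitter_ratio_last5(at_ms))
    except (PhysioError, FileNotFoundError) as exc:
        logger.warning("%s: train battery failed: %s", cell_dir.name, exc)

    if nucleus_plane is not None:
        try:
            stack = read_stack(cell_dir / "stack.tif")
            res = score_vacuolization(stack, nucleus_plane)
            out["bw_ratio"] = res.bw_ratio
        except (PhysioError, FileNotFoundError) as exc:
            logger.warning("%s: vacuole battery failed: %s",
                           cell_dir.name, exc)
    return out


def analyze_cohort(bundle_dir: str | Path,
                   config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-cell feature table for a cohort bundle (see
    :func:`physio.cohort.gen_cohort` for the layout)."""
    bundle_dir = Path(bundle_dir)
    meta = pd.read_csv(bundle_dir / "metadata.tsv", sep="\t")
    rows = []
    for _, rec in meta.iterrows():
        feats = analyze_cell(bundle_dir / rec["path"],
                             nucleus_plane=int(rec["nucleus_plane"]),
                             config=config)
        feats["cell_id"] = rec["cell_id"]
        feats["group"] = rec["group"]
        rows.append(feats)
    return pd.DataFrame(rows)[["cell_id", "group"] + FEATURES]


def run_pipeline(bundle_dir: str | Path, report_dir: str | Path,
                 config: AnalysisConfig | None = None) -> dict:
    """Analyze a bundle and write the feature table plus the statistics
    report (TSV + JSON).  Returns the comparisons keyed by feature."""
    report_dir = Path(report_dir)
    report_dir.mkdir(parents=True, exist_ok=True)
    table = analyze_cohort(bundle_dir, config)
    table.to_csv(report_dir / "features.tsv", sep="\t", index=False)
    order = list(dict.fromkeys(table["group"]))
    comparisons = stats_mod.summarize_cohort(table, group_order=order)
    report = stats_mod.comparison_report(comparisons)
    report.to_csv(report_dir / "comparisons.tsv", sep="\t", index=False)
    write_json(
        {f: {"kruskal_H": c.kruskal_h, "kruskal_p": c.kruskal_p,
             "groups": c.group_summary.to_dict(orient="records"),
             "pairwise": c.pairwise.to_dict(orient="records")}
         for f, c in comparisons.items()},
        report_dir / "comparisons.json")
    return comparisons
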