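"""Group-comparison statistics over per-cell feature tables.

The testing scheme: per group Shapiro–Wilk normality (reported, not
gating), omnibus Kruskal–Wallis over all groups (mid-ranks with tie
correction, χ² reference with k−1 df), and Dunn post hoc z tests on the
pooled ranks with Bonferroni adjustment over all k(k−1)/2 pairs
(adjusted p = min(1, raw p × m)).  Significance at α = 0.05, starred at
the 0.05 / 0.01 / 0.001 tiers.  Summaries are medians with first and
third quartiles (linear-interpolation quantiles).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatisticsError

ALPHA = 0.05


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro–Wilk W and p for one sample (3 ≤ n ≤ 5000, non-constant)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise StatisticsError("Shapiro–Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise StatisticsError("constant sample")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected mid-ranks) and χ²(k−1) p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise StatisticsError("need at least two groups")
    if any(g.size < 1 for g in groups):
        raise StatisticsError("empty group")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise StatisticsError("total N must be >= 3")
    if np.ptp(pooled) == 0:
        raise StatisticsError("all values identical")
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def dunn_bonferroni(groups, labels=None) -> pd.DataFrame:
    """Dunn post hoc z tests on the pooled mid-ranks with Bonferroni
    adjustment over all pairs.

    z_ij = (R̄_i − R̄_j) / sqrt[(N(N+1)/12 − T/(12(N−1))) (1/n_i + 1/n_j)]
    with tie term T = Σ(t³ − t); two-sided normal p, adjusted
    p = min(1, p × k(k−1)/2).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise StatisticsError("need at least two groups")
    if any(g.size < 1 for g in groups):
        raise StatisticsError("empty group")
    if labels is None:
        labels = [str(i) for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [g.size for g in groups]
    idx = np.cumsum([0] + sizes)
    mean_ranks = [ranks[idx[i]:idx[i + 1]].mean()
                  for i in range(len(groups))]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    m = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        rows.append({
            "group_a": labels[i], "group_b": labels[j], "z": float(z),
            "p_raw": float(p_raw), "p_adj": float(min(1.0, p_raw * m)),
        })
    return pd.DataFrame(rows)


def significance_stars(p: float, alpha: float = ALPHA) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < alpha:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    """Full test battery for one feature."""

    feature: str
    group_summary: pd.DataFrame    # n, median, q1, q3, shapiro p per group
    kruskal_h: float
    kruskal_p: float
    pairwise: pd.DataFrame         # Dunn z, raw and adjusted p per pair
    alpha: float = ALPHA
    error: str | None = None

    @property
    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.pairwise[self.pairwise["p_adj"] < self.alpha]
        return list(zip(sig["group_a"], sig["group_b"]))


def summarize_feature(table: pd.DataFrame, feature: str,
                      group_col: str = "group",
                      group_order: list[str] | None = None
                      ) -> GroupComparison:
    """Medians/quartiles, Shapiro–Wilk, Kruskal–Wallis and Dunn–Bonferroni
    for one feature column of a per-cell table."""
    sub = table[[group_col, feature]].dropna()
    if group_order is None:
        group_order = list(dict.fromkeys(sub[group_col]))
    groups, labels = [], []
    rows = []
    for g in group_order:
        vals = sub.loc[sub[group_col] == g, feature].to_numpy(dtype=float)
        if vals.size == 0:
            raise StatisticsError(f"empty group {g!r} for feature {feature!r}")
        groups.append(vals)
        labels.append(g)
        try:
            _, sw_p = shapiro_wilk(vals)
        except StatisticsError:
            sw_p = np.nan
        rows.append({
            "group": g, "n": vals.size,
            "median": float(np.median(vals)),
            "q1": float(np.quantile(vals, 0.25)),
            "q3": float(np.quantile(vals, 0.75)),
            "shapiro_p": sw_p,
        })
    summary = pd.DataFrame(rows)
    try:
        h, p = kruskal_wallis(groups)
        pairwise = dunn_bonferroni(groups, labels)
        err = None
    except StatisticsError as exc:
        h, p = np.nan, np.nan
        pairwise = pd.DataFrame(
            columns=["group_a", "group_b", "z", "p_raw", "p_adj"])
        err = str(exc)
    return GroupComparison(feature=feature, group_summary=summary,
                           kruskal_h=h, kruskal_p=p, pairwise=pairwise,
                           error=err)


def summarize_cohort(table: pd.DataFrame, features: list[str] | None = None,
                     group_col: str = "group",
                     group_order: list[str] | None = None
                     ) -> dict[str, GroupComparison]:
    """Run the full battery for every (or the listed) numeric feature
    column of a per-cell table."""
    if features is None:
        features = [c for c in table.columns
                    if c not in (group_col, "cell_id")
                    and pd.api.types.is_numeric_dtype(table[c])]
    return {f: summarize_feature(table, f, group_col, group_order)
            for f in features}


def comparison_report(comparisons: dict[str, GroupComparison]
                      ) -> pd.DataFrame:
    """Flat per-feature report table (one row per feature × pair)."""
    rows = []
    for feature, comp in comparisons.items():
        if comp.pairwise.empty:
            rows.append({"feature": feature, "kruskal_H": comp.kruskal_h,
                         "kruskal_p": comp.kruskal_p, "pair": None,
                         "dunn_z": None, "p_adj": None, "stars": None})
        for _, r in comp.pairwise.iterrows():
            rows.append({
                "feature": feature, "kruskal_H": comp.kruskal_h,
                "kruskal_p": comp.kruskal_p,
                "pair": f"{r['group_a']} vs {r['group_b']}",
                "dunn_z": r["z"], "p_adj": r["p_adj"],
                "stars": significance_stars(r["p_adj"]),
            })
    return pd.DataFrame(rows)
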