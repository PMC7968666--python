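"""Drug-effect endpoint statistics: survival, fecundity, fertility.

Group comparisons follow a normality-gated branch: Shapiro-Wilk on the
pooled within-arm residuals at alpha = 0.05 selects either one-way ANOVA
with Tukey's HSD post-hoc, or Kruskal-Wallis with pairwise Wilcoxon
rank-sum tests adjusted by Holm's method.  Mortality is analysed as the
four-day percent survival per replicate cup.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import EffectsRecord

__all__ = ["ENDPOINTS", "ComparisonResult", "endpoint_values",
           "endpoint_summaries", "compare_groups"]

ENDPOINTS = ("survival", "fecundity", "fertility")
ALPHA = 0.05


@dataclass
class ComparisonResult:
    endpoint: str
    branch: str                    # 'anova_tukey' | 'kruskal_wilcoxon' | 'skipped'
    shapiro_p: Optional[float]
    omnibus_p: Optional[float]
    pairwise: pd.DataFrame
    note: str = ""


def endpoint_values(records: Sequence[EffectsRecord], endpoint: str) -> pd.DataFrame:
    """Per-replicate endpoint values in long format (ARM, REPLICATE, VALUE)."""
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    rows = []
    for rec in records:
        if endpoint == "survival":
            value = rec.survival_pct
        elif endpoint == "fecundity":
            value = rec.eggs
        else:
            value = rec.fertility_pct
        rows.append({"ARM": rec.arm, "REPLICATE": rec.replicate, "VALUE": value})
    return pd.DataFrame(rows)


def endpoint_summaries(records: Sequence[EffectsRecord]) -> pd.DataFrame:
    """Median and range per arm for each endpoint."""
    if not records:
        raise ValueError("no records")
    rows = []
    for endpoint in ENDPOINTS:
        df = endpoint_values(records, endpoint)
        for arm, grp in df.groupby("ARM", sort=True):
            vals = grp["VALUE"].to_numpy(dtype=float)
            rows.append({"endpoint": endpoint, "arm": arm, "n": len(vals),
                         "median": float(np.median(vals)),
                         "min": float(vals.min()), "max": float(vals.max())})
    return pd.DataFrame(rows)


def compare_groups(records: Sequence[EffectsRecord], endpoint: str,
                   alpha: float = ALPHA) -> ComparisonResult:
    """Omnibus and pairwise group comparisons for one endpoint.

    The branch selection is a pure function of the data: Shapiro-Wilk on
    pooled residuals decides parametric vs rank-based testing.
    """
    df = endpoint_values(records, endpoint)
    arms = sorted(df["ARM"].unique())
    if len(arms) < 2:
        raise ValueError("need at least 2 arms")
    groups = [df.loc[df["ARM"] == a, "VALUE"].to_numpy(dtype=float) for a in arms]
    if any(len(g) < 2 for g in groups):
        raise ValueError("need at least 2 replicates per arm")
    empty = pd.DataFrame(columns=["arm_a", "arm_b", "p_unadjusted",
                                  "p_adjusted", "significant"])
    if np.ptp(df["VALUE"].to_numpy()) == 0:
        return ComparisonResult(endpoint, "skipped", None, None, empty,
                                note="endpoint constant across all arms; "
                                     "comparison skipped")
    residuals = np.concatenate([g - g.mean() for g in groups])
    if np.ptp(residuals) == 0:
        shapiro_p, normal = 1.0, True
        note = "zero within-arm variance; parametric branch by default"
    else:
        shapiro_p = float(stats.shapiro(residuals).pvalue)
        normal = shapiro_p >= alpha
        note = ""
    pairs = list(combinations(range(len(arms)), 2))
    if normal:
        branch = "anova_tukey"
        omnibus_p = float(stats.f_oneway(*groups).pvalue)
        hsd = stats.tukey_hsd(*groups)
        p_adj = [float(hsd.pvalue[i, j]) for i, j in pairs]
        p_raw = [float(stats.ttest_ind(groups[i], groups[j]).pvalue)
                 for i, j in pairs]
        # Tukey controls the family-wise rate; never report below the raw p
        p_adj = [max(a, r) for a, r in zip(p_adj, p_raw)]
    else:
        branch = "kruskal_wilcoxon"
        omnibus_p = float(stats.kruskal(*groups).pvalue)
        p_raw = [float(stats.mannwhitneyu(groups[i], groups[j],
                                          alternative="two-sided").pvalue)
                 for i, j in pairs]
        p_adj = list(multipletests(p_raw, method="holm")[1])
    pairwise = pd.DataFrame({
        "arm_a": [arms[i] for i, _ in pairs],
        "arm_b": [arms[j] for _, j in pairs],
        "p_unadjusted": p_raw, "p_adjusted": p_adj,
        "significant": [p < alpha for p in p_adj]})
    return ComparisonResult(endpoint, branch, shapiro_p, omnibus_p, pairwise,
                            note=note)
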