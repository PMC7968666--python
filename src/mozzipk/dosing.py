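"""Dosing precision and linearity QC for feeding experiments.

Precision is the per-concentration coefficient of variation
CV% = 100 * SD / mean (sample SD, n-1 denominator), computed on raw amounts
or weight-normalised amounts (ng/mg); the weight-normalised CV is the
headline dosing-precision metric.  Linearity is an ordinary least-squares
regression of the per-mosquito amount on the blood concentration, with R^2
the squared Pearson correlation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import LinearityRecord

__all__ = ["DosingSummary", "dosing_precision", "dosing_linearity",
           "implied_meal_volume_ul"]


@dataclass
class DosingSummary:
    per_concentration: pd.DataFrame
    slope: float
    intercept: float
    r_squared: float
    normalized: bool


def _frame(records: Sequence[LinearityRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([{"CONC": r.blood_conc_ug_ml, "AMOUNT": r.amount_ng,
                          "WT": r.weight_mg} for r in records])


def _cv_table(df: pd.DataFrame, value_col: str) -> pd.DataFrame:
    rows = []
    for conc, grp in df.groupby("CONC", sort=True):
        if len(grp) < 2:
            warnings.warn(f"concentration {conc} has fewer than 2 records; excluded")
            continue
        vals = grp[value_col].to_numpy(dtype=float)
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        rows.append({"conc_ug_ml": conc, "n": len(grp), "mean": mean,
                     "sd": sd, "cv_percent": 100.0 * sd / mean})
    if not rows:
        raise ValueError("no concentration has at least 2 records")
    return pd.DataFrame(rows)


def dosing_precision(records, normalize_by_weight: bool = True) -> DosingSummary:
    """Per-concentration dosing CV% plus the overall amount-concentration
    regression (on the same scale as the CVs)."""
    df = _frame(records).copy()
    df["VALUE"] = df["AMOUNT"] / df["WT"] if normalize_by_weight else df["AMOUNT"]
    table = _cv_table(df, "VALUE")
    if df["CONC"].nunique() >= 2:
        reg = stats.linregress(df["CONC"], df["VALUE"])
        slope, intercept, r2 = reg.slope, reg.intercept, reg.rvalue ** 2
    else:
        slope = intercept = r2 = float("nan")
    return DosingSummary(per_concentration=table, slope=float(slope),
                         intercept=float(intercept), r_squared=float(r2),
                         normalized=normalize_by_weight)


def dosing_linearity(records, normalize_by_weight: bool = False):
    """OLS of per-mosquito amount on blood concentration.

    Returns (slope, intercept, r_squared).  With raw amounts the slope is
    the mean imbibed blood volume in ul (ng per ng/ul).
    """
    df = _frame(records)
    if df["CONC"].nunique() < 2:
        raise ValueError("linearity requires at least 2 distinct concentrations")
    y = df["AMOUNT"] / df["WT"] if normalize_by_weight else df["AMOUNT"]
    reg = stats.linregress(df["CONC"], y)
    return float(reg.slope), float(reg.intercept), float(reg.rvalue ** 2)


def implied_meal_volume_ul(mean_amount_ng: float, blood_conc_ug_ml: float) -> float:
    """Blood volume implied by a mean imbibed amount at a given blood
    concentration (1 ug/ml == 1 ng/ul, so volume = amount / concentration)."""
    if blood_conc_ug_ml <= 0:
        raise ValueError("blood_conc_ug_ml must be > 0")
    return mean_amount_ng / blood_conc_ug_ml
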