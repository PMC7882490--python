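"""Calibration of beliefs: internal consistency and comparison to benchmarks.

Four instruments: paired t tests between belief items (e.g., the believed
infection fatality ratio against the believed prevalence, which objective
evidence says should be much larger); per-respondent classification of item
pairs as higher / equal / lower; a no-intercept regression measuring the
believed contagiousness of one disease as a multiple of another's; and the
gap between the mean believed own risk and the objective prevalence within
demographic strata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .survey_io import SurveyTable

__all__ = [
    "PairedComparison",
    "PairClassification",
    "paired_test",
    "classify_pairs",
    "proportional_slope",
    "stratified_gap",
    "fold_difference",
]

_ALTERNATIVES = {
    "two_sided": "two-sided",
    "one_sided_a_lt_b": "less",
    "one_sided_a_gt_b": "greater",
}


@dataclass(frozen=True)
class PairedComparison:
    item_a: str
    item_b: str
    n_pairs: int
    mean_difference: float  # a - b on the item scale
    t_statistic: float
    p_value: float
    sidedness: str


@dataclass(frozen=True)
class PairClassification:
    n_higher: int
    n_equal: int
    n_lower: int

    @property
    def n_pairs(self) -> int:
        return self.n_higher + self.n_equal + self.n_lower


def _complete_pairs(df: pd.DataFrame, item_a: str, item_b: str) -> pd.DataFrame:
    return df[[item_a, item_b]].dropna()


def paired_test(
    table: SurveyTable | pd.DataFrame,
    item_a: str,
    item_b: str,
    sidedness: str = "two_sided",
    wave: int | None = None,
) -> PairedComparison:
    """Classical paired t test of item_a against item_b, listwise complete.

    ``sidedness`` is ``two_sided``, ``one_sided_a_lt_b`` (alternative: a < b)
    or ``one_sided_a_gt_b``.
    """
    if sidedness not in _ALTERNATIVES:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    df = table.data if isinstance(table, SurveyTable) else table
    if wave is not None:
        df = df[df["wave"] == wave]
    pairs = _complete_pairs(df, item_a, item_b)
    if len(pairs) < 2:
        raise ValueError(f"need >= 2 complete pairs, got {len(pairs)}")
    a = pairs[item_a].to_numpy(float)
    b = pairs[item_b].to_numpy(float)
    d = a - b
    if np.std(d, ddof=1) == 0.0:
        # degenerate case scipy leaves as NaN: constant differences
        t = 0.0 if d[0] == 0 else float(np.sign(d[0]) * np.inf)
        if sidedness == "two_sided":
            p = 1.0 if t == 0 else 0.0
        elif sidedness == "one_sided_a_lt_b":
            p = 0.5 if t == 0 else (0.0 if t < 0 else 1.0)
        else:
            p = 0.5 if t == 0 else (0.0 if t > 0 else 1.0)
    else:
        res = stats.ttest_rel(a, b, alternative=_ALTERNATIVES[sidedness])
        t, p = float(res.statistic), float(res.pvalue)
    return PairedComparison(
        item_a=item_a,
        item_b=item_b,
        n_pairs=len(pairs),
        mean_difference=float(np.mean(d)),
        t_statistic=t,
        p_value=p,
        sidedness=sidedness,
    )


def classify_pairs(
    table: SurveyTable | pd.DataFrame,
    item_a: str,
    item_b: str,
    tolerance: float = 0.0,
    wave: int | None = None,
) -> PairClassification:
    """Count respondents with item_a higher / equal / lower than item_b.

    A pair with |a - b| <= tolerance counts as equal; the default tolerance
    of 0 reads "equal" as exact equality on integer-valued items.
    """
    df = table.data if isinstance(table, SurveyTable) else table
    if wave is not None:
        df = df[df["wave"] == wave]
    pairs = _complete_pairs(df, item_a, item_b)
    d = pairs[item_a].to_numpy(float) - pairs[item_b].to_numpy(float)
    equal = np.abs(d) <= tolerance
    return PairClassification(
        n_higher=int(np.sum(d > tolerance)),
        n_equal=int(np.sum(equal)),
        n_lower=int(np.sum(d < -tolerance)),
    )


def proportional_slope(
    table: SurveyTable | pd.DataFrame,
    item_y: str,
    item_x: str,
    wave: int | None = None,
) -> tuple[float, float]:
    """No-intercept least-squares slope of item_y on item_x and its SE.

    slope = sum(xy)/sum(x^2); SE = sqrt(sum((y - b x)^2)/(n-1)) / sqrt(sum(x^2)).
    Reads as "y is `slope` times x" (e.g., believed contagiousness of one
    disease as a multiple of another's).
    """
    df = table.data if isinstance(table, SurveyTable) else table
    if wave is not None:
        df = df[df["wave"] == wave]
    pairs = _complete_pairs(df, item_y, item_x)
    if len(pairs) < 2:
        raise ValueError("need >= 2 complete pairs")
    x = pairs[item_x].to_numpy(float)
    y = pairs[item_y].to_numpy(float)
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all x are zero; slope undefined")
    slope = float(np.sum(x * y) / sxx)
    resid = y - slope * x
    se = float(np.sqrt(np.sum(resid**2) / (len(x) - 1)) / np.sqrt(sxx))
    return slope, se


def fold_difference(a: float, b: float) -> float:
    """How many times larger a is than b (e.g., two reproduction numbers)."""
    if b == 0:
        raise ZeroDivisionError("reference value is zero")
    return a / b


def stratified_gap(
    table: SurveyTable | pd.DataFrame,
    item: str,
    bench: pd.DataFrame,
    strata: list[str] | str,
    wave: int | None = None,
) -> pd.DataFrame:
    """Mean belief minus objective benchmark prevalence within strata.

    ``strata`` are column names present in both the survey table and the
    benchmark table (e.g., gender, or region tier).  The gap is
    mean item (0-100 scale) minus benchmark ``prevalence`` (per 100), so a
    positive gap means beliefs exceed the recorded prevalence.  Strata
    missing from the benchmark are returned with ``comparable = False``.
    """
    if isinstance(strata, str):
        strata = [strata]
    df = table.data if isinstance(table, SurveyTable) else table
    if wave is not None:
        df = df[df["wave"] == wave]
    if "prevalence" not in bench.columns:
        raise ValueError("benchmark table lacks a 'prevalence' column; run compute_rates")
    beliefs = (
        df[strata + [item]].dropna().groupby(strata, observed=True)[item].agg(["mean", "size"])
    )
    bench_idx = bench.set_index(strata if len(strata) > 1 else strata[0])["prevalence"]
    rows = []
    for key, row in beliefs.iterrows():
        comparable = key in bench_idx.index
        prev = float(bench_idx.loc[key]) if comparable else np.nan
        rows.append(
            {
                **dict(zip(strata, key if isinstance(key, tuple) else (key,))),
                "mean_belief": float(row["mean"]),
                "n": int(row["size"]),
                "benchmark_prevalence": prev,
                "gap": float(row["mean"]) - prev if comparable else np.nan,
                "comparable": comparable,
            }
        )
    return pd.DataFrame(rows)
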