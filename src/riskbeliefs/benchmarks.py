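"""Objective risk benchmarks from stratum-level hospital count tables.

Per demographic stratum (gender, age band, region or incidence tier) the
inputs are deaths, diagnosed cases and population.  The module computes the
infection fatality ratio (deaths per 100 diagnosed), the prevalence
(diagnosed per 100 population), odds ratios against a reference stratum,
and pooled-count aggregation of strata (e.g., 13 regions into 3 incidence
tiers).  Because the counts are hospital counts of severe cases, the IFR is
an upper bound and the prevalence a lower bound of the population rates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "COUNT_COLUMNS",
    "validate_counts",
    "compute_rates",
    "odds_ratio_table",
    "aggregate_strata",
    "read_counts",
    "write_counts",
]

COUNT_COLUMNS = ("deaths", "diagnosed", "population")


_DERIVED_COLUMNS = ("date_label", "ifr", "ifr_defined", "prevalence")


def _stratum_keys(counts: pd.DataFrame) -> list[str]:
    return [c for c in counts.columns if c not in COUNT_COLUMNS + _DERIVED_COLUMNS]


def validate_counts(counts: pd.DataFrame) -> None:
    """Enforce 0 <= deaths <= diagnosed <= population on every stratum."""
    for col in COUNT_COLUMNS:
        if col not in counts.columns:
            raise ValueError(f"count table lacks column {col!r}")
        if (counts[col] < 0).any():
            raise ValueError(f"negative {col} count")
    if (counts["deaths"] > counts["diagnosed"]).any():
        raise ValueError("deaths exceed diagnosed in some stratum")
    if (counts["diagnosed"] > counts["population"]).any():
        raise ValueError("diagnosed exceed population in some stratum")


def compute_rates(counts: pd.DataFrame) -> pd.DataFrame:
    """IFR (per 100 diagnosed) and prevalence (per 100 population) by stratum.

    A stratum with zero diagnosed cases has an undefined IFR: the value is
    NaN and ``ifr_defined`` is False, never a silent zero.
    """
    validate_counts(counts)
    out = counts.copy()
    diagnosed = counts["diagnosed"].to_numpy(float)
    defined = diagnosed > 0
    ifr = np.full(len(counts), np.nan)
    ifr[defined] = 100.0 * counts["deaths"].to_numpy(float)[defined] / diagnosed[defined]
    out["ifr"] = ifr
    out["ifr_defined"] = defined
    out["prevalence"] = 100.0 * diagnosed / counts["population"].to_numpy(float)
    return out


def odds_ratio_table(
    bench: pd.DataFrame, reference, measure: str = "prevalence"
) -> pd.Series:
    """Odds ratio of each stratum against a reference stratum.

    ``measure`` is ``prevalence`` or ``ifr`` (per-100 columns from
    :func:`compute_rates`); with p the rate on the proportion scale,
    OR(s) = [p_s/(1-p_s)] / [p_ref/(1-p_ref)].  The reference maps to
    exactly 1.  A stratum whose rate is 100 (odds infinite) or undefined
    is returned as NaN.  ``reference`` is a stratum-key tuple (or scalar
    for a single-key table).
    """
    if measure not in ("prevalence", "ifr"):
        raise ValueError("measure must be 'prevalence' or 'ifr'")
    keys = _stratum_keys(bench)
    indexed = bench.set_index(keys if len(keys) > 1 else keys[0])
    p = indexed[measure] / 100.0
    if reference not in indexed.index:
        raise KeyError(f"reference stratum {reference!r} not in table")
    p_ref = p.loc[reference]
    if not (0 < p_ref < 1) or np.isnan(p_ref):
        raise ValueError(f"reference stratum rate {p_ref} must lie in (0, 1)")
    ref_odds = p_ref / (1 - p_ref)
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.where(p < 1, p / (1 - p), np.nan)
    out = pd.Series(odds / ref_odds, index=indexed.index, name=f"odds_ratio_{measure}")
    out.loc[reference] = 1.0
    return out


def aggregate_strata(counts: pd.DataFrame, mapping: dict, key: str | None = None) -> pd.DataFrame:
    """Sum counts of strata into groups (e.g., regions into incidence tiers).

    ``mapping`` sends each observed value of ``key`` (default: the single
    stratum-key column) to its group label; an unmapped stratum is an error.
    Rates on the result equal pooled-count rates, never averages of rates.
    """
    validate_counts(counts)
    keys = _stratum_keys(counts)
    key = key or (keys[0] if len(keys) == 1 else None)
    if key is None or key not in keys:
        raise ValueError(f"aggregation key must be one of {keys}")
    unmapped = set(counts[key].unique()) - set(mapping)
    if unmapped:
        raise ValueError(f"unmapped stratum value(s): {sorted(unmapped)}")
    out = counts.copy()
    out[key] = out[key].map(mapping)
    group_cols = [key] + [k for k in keys if k != key]
    agg = {c: "sum" for c in COUNT_COLUMNS}
    if "date_label" in counts.columns:
        agg["date_label"] = "first"
    return out.groupby(group_cols, as_index=False, sort=False).agg(agg)


def read_counts(path) -> pd.DataFrame:
    """Read a stratum count table from comma-separated text and validate it."""
    counts = pd.read_csv(path)
    validate_counts(counts)
    return counts


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, index=False)
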