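"""Respondent-level survey data model, validated I/O, and descriptive summaries.

The data model covers a two-wave belief-elicitation survey: demographics with
post-stratification weights, bounded 0-100 belief items (infection fatality
ratio, own risk, others' risk, expected prevalence), 0-10 opinion scores, and
auxiliary health items.  Files are plain comma-separated text with a header;
an empty cell is the one and only encoding of a missing response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ItemDef",
    "Codebook",
    "SurveyTable",
    "SchemaError",
    "ValidationError",
    "default_codebook",
    "read_survey",
    "write_survey",
    "summarize_items",
    "REGION_TIERS",
]


class SchemaError(ValueError):
    """The file's columns do not match the codebook."""


class ValidationError(ValueError):
    """One or more cell values violate the codebook's constraints."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            f"{len(self.problems)} validation problem(s):\n  " + "\n  ".join(self.problems)
        )


#: Assignment of the 13 metropolitan regions to incidence tiers.
REGION_TIERS: dict[str, str] = {
    "Normandie": "lowest",
    "Bretagne": "lowest",
    "Pays de la Loire": "lowest",
    "Nouvelle-Aquitaine": "lowest",
    "Occitanie": "lowest",
    "Hauts-de-France": "medium",
    "Bourgogne-Franche-Comté": "medium",
    "Auvergne-Rhône-Alpes": "medium",
    "Corse": "medium",
    "Provence-Alpes-Côte d'Azur": "medium",
    "Centre-Val de Loire": "medium",
    "Île-de-France": "highest",
    "Grand-Est": "highest",
}


@dataclass(frozen=True)
class ItemDef:
    """Definition of one survey column.

    kind is one of ``id``, ``int``, ``categorical``, ``numeric``; numeric
    definitions carry a closed valid range, categorical ones the ordered list
    of admissible codes (order fixes the reference level downstream).
    ``waves`` lists the waves in which the item was collected; a value present
    in any other wave is a validation error, not a quiet missing.
    """

    name: str
    kind: str
    categories: tuple[str, ...] | None = None
    vmin: float | None = None
    vmax: float | None = None
    waves: tuple[int, ...] = (1, 2)
    required: bool = False  # must be non-missing in its waves


def _belief(name: str, waves=(1, 2)) -> ItemDef:
    return ItemDef(name, "numeric", vmin=0.0, vmax=100.0, waves=waves)


def _score(name: str, waves=(1, 2)) -> ItemDef:
    return ItemDef(name, "numeric", vmin=0.0, vmax=10.0, waves=waves)


@dataclass
class Codebook:
    """Ordered mapping of column names to item definitions."""

    items: dict[str, ItemDef]

    def __post_init__(self):
        for name, item in self.items.items():
            if name != item.name:
                raise ValueError(f"codebook key {name!r} != item name {item.name!r}")

    @property
    def columns(self) -> list[str]:
        return list(self.items)

    def numeric_items(self) -> list[str]:
        return [n for n, d in self.items.items() if d.kind == "numeric"]

    def wave1_only(self) -> list[str]:
        return [n for n, d in self.items.items() if d.waves == (1,)]

    @classmethod
    def from_yaml(cls, path) -> "Codebook":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        items = {}
        for name, spec in raw.items():
            items[name] = ItemDef(
                name=name,
                kind=spec["kind"],
                categories=tuple(spec["categories"]) if spec.get("categories") else None,
                vmin=spec.get("vmin"),
                vmax=spec.get("vmax"),
                waves=tuple(spec.get("waves", (1, 2))),
                required=bool(spec.get("required", False)),
            )
        return cls(items)

    def to_yaml(self, path) -> None:
        raw = {}
        for name, d in self.items.items():
            spec: dict = {"kind": d.kind, "waves": list(d.waves)}
            if d.categories:
                spec["categories"] = list(d.categories)
            if d.vmin is not None:
                spec["vmin"] = d.vmin
            if d.vmax is not None:
                spec["vmax"] = d.vmax
            if d.required:
                spec["required"] = True
            raw[name] = spec
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False, allow_unicode=True)


def default_codebook() -> Codebook:
    """The codebook of the two-wave lockdown belief survey."""
    items = [
        ItemDef("respondent_id", "id", required=True),
        ItemDef("wave", "int", vmin=1, vmax=2, required=True),
        ItemDef("gender", "categorical", ("female", "male"), required=True),
        ItemDef(
            "age_category",
            "categorical",
            ("<=19", "20-29", "30-39", "40-49", "50-59", "60-69", "70+"),
            required=True,
        ),
        ItemDef("marital", "categorical", ("single", "couple")),
        ItemDef(
            "education",
            "categorical",
            ("below_high_school", "bachelor_or_higher", "high_school_no_bachelor"),
        ),
        ItemDef(
            "labor_status",
            "categorical",
            ("inactive", "private_employee", "public_employee", "self_employed", "unemployed"),
        ),
        ItemDef("income", "categorical", ("low", "high", "middle")),
        ItemDef("region_tier", "categorical", ("lowest", "medium", "highest"), required=True),
        ItemDef("weight", "numeric", vmin=float(np.nextafter(0, 1)), vmax=float("inf"), required=True),
        _belief("q1_ifr"),
        _belief("q1bis_flu_ifr", waves=(1,)),
        _belief("q2_own_risk"),
        _belief("q3_others_risk"),
        _belief("q4_prevalence"),
        _score("q5_relative_risk"),
        _score("q6_worry"),
        _score("q7_contagious"),
        _score("q7bis_contagious_flu", waves=(1,)),
        _score("q8_serious"),
        _score("q8bis_serious_flu", waves=(1,)),
        ItemDef(
            "confidence_q2",
            "categorical",
            ("very_high", "high", "moderate", "low", "very_low"),
            waves=(1,),
        ),
        ItemDef(
            "confidence_q3",
            "categorical",
            ("very_high", "high", "moderate", "low", "very_low"),
            waves=(1,),
        ),
        ItemDef("expected_duration_weeks", "numeric", vmin=0.0, vmax=52.0),
        ItemDef(
            "health_status", "categorical", ("very_good", "good", "bad_or_very_bad"), waves=(1,)
        ),
        ItemDef("chronic_illness", "categorical", ("no", "yes"), waves=(1,)),
        ItemDef("diagnosed_covid", "categorical", ("no", "yes")),
        ItemDef("relative_ill", "categorical", ("no", "yes")),
    ]
    return Codebook({d.name: d for d in items})


@dataclass
class SurveyTable:
    """Validated respondent-level table for one or both waves.

    ``data`` holds one row per respondent; numeric items are floats with NaN
    for missing, categorical items are strings with NaN for missing.
    """

    data: pd.DataFrame
    codebook: Codebook = field(default_factory=default_codebook)

    def __post_init__(self):
        problems = validate(self.data, self.codebook)
        if problems:
            raise ValidationError(problems)

    def wave(self, w: int) -> pd.DataFrame:
        return self.data[self.data["wave"] == w]

    @property
    def waves(self) -> list[int]:
        return sorted(self.data["wave"].unique())

    def __len__(self) -> int:
        return len(self.data)


def validate(df: pd.DataFrame, codebook: Codebook) -> list[str]:
    """Return a list of human-readable problems; empty means valid.

    Row numbers in messages are 1-based data rows (header excluded).
    """
    problems: list[str] = []
    if df.empty:
        return problems
    if not df["respondent_id"].notna().all():
        problems.append("missing respondent_id")
    for w, grp in df.groupby("wave"):
        dup = grp["respondent_id"][grp["respondent_id"].duplicated()]
        for rid in dup.unique():
            problems.append(f"duplicate respondent_id {rid!r} in wave {w}")
    wave_ok = df["wave"].isin([1, 2])
    for idx in df.index[~wave_ok]:
        problems.append(f"row {idx + 1}: wave must be 1 or 2, got {df.at[idx, 'wave']!r}")
    for name, item in codebook.items.items():
        col = df[name]
        if item.required:
            for idx in df.index[col.isna() & wave_ok]:
                problems.append(f"row {idx + 1}: column {name} is required but missing")
        if item.kind == "categorical":
            bad = col.notna() & ~col.isin(item.categories)
            for idx in df.index[bad]:
                problems.append(
                    f"row {idx + 1}: column {name} has unknown code {col[idx]!r}"
                )
        elif item.kind in ("numeric", "int"):
            vals = pd.to_numeric(col, errors="coerce")
            bad = col.notna() & (
                vals.isna() | (vals < item.vmin) | (vals > item.vmax)
            )
            for idx in df.index[bad]:
                problems.append(
                    f"row {idx + 1}: column {name} value {col[idx]!r} outside "
                    f"[{item.vmin}, {item.vmax}]"
                )
        # an item never fielded in a wave must not carry answers there
        off_wave = wave_ok & ~df["wave"].isin(item.waves) & col.notna()
        for idx in df.index[off_wave]:
            problems.append(
                f"row {idx + 1}: column {name} answered in wave {df.at[idx, 'wave']} "
                f"but the item was only fielded in wave(s) {item.waves}"
            )
    return problems


def _parse_float(value):
    # Python's float() is correctly rounded; pandas' fast parser is not,
    # which would break bit-identical round-trips
    try:
        return float(value)
    except (TypeError, ValueError):
        return np.nan


def _coerce(df: pd.DataFrame, codebook: Codebook) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    for name, item in codebook.items.items():
        col = df[name].replace("", np.nan)
        if item.kind in ("numeric", "int"):
            # keep raw strings where unparseable so validation can report them
            num = col.map(_parse_float, na_action="ignore").astype(float)
            out[name] = num.where(num.notna() | col.isna(), col)
            if item.kind == "int" and num.notna().all():
                out[name] = num.astype(int)
        else:
            out[name] = col
    return out


def read_survey(path, codebook: Codebook | None = None) -> SurveyTable:
    """Read and validate a comma-separated survey file.

    Unknown or absent columns raise :class:`SchemaError`; out-of-range or
    miscoded values raise :class:`ValidationError` naming every offending row
    and column.  Values are never silently coerced into range.
    """
    codebook = codebook or default_codebook()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = set(codebook.columns)
    got = set(df.columns)
    # a raw-region column is accepted in place of the tier and mapped
    if "region" in got and "region_tier" not in got:
        unknown = set(df["region"].unique()) - set(REGION_TIERS) - {""}
        if unknown:
            raise SchemaError(f"unknown region name(s): {sorted(unknown)}")
        df["region_tier"] = df["region"].map(REGION_TIERS).fillna("")
        df = df.drop(columns=["region"])
        got = set(df.columns)
    if got - expected:
        raise SchemaError(f"unknown column(s): {sorted(got - expected)}")
    if expected - got:
        raise SchemaError(f"missing column(s): {sorted(expected - got)}")
    coerced = _coerce(df[codebook.columns], codebook)
    coerced["wave"] = pd.to_numeric(coerced["wave"], errors="coerce").astype("Int64")
    problems = validate(coerced, codebook)
    if problems:
        raise ValidationError(problems)
    coerced["wave"] = coerced["wave"].astype(int)
    for name in codebook.numeric_items():
        coerced[name] = pd.to_numeric(coerced[name])
    return SurveyTable(coerced, codebook)


def write_survey(table: SurveyTable, path) -> None:
    """Write a survey table as comma-separated text; missing cells are empty.

    Floats use Python's shortest round-trip representation, so a write/read
    cycle reproduces every value bit-identically.
    """
    table.data.to_csv(path, index=False, na_rep="")


def _weighted_mean_sd(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    # weights renormalized to mean 1 over present respondents, so that equal
    # weights reduce the formulas exactly to the unweighted n-1 versions
    w = w * (len(w) / w.sum())
    m = float(np.sum(w * x) / np.sum(w))
    if len(x) < 2:
        return m, float("nan")
    sd = float(np.sqrt(np.sum(w * (x - m) ** 2) / (np.sum(w) - 1.0)))
    return m, sd


def summarize_items(
    table: SurveyTable,
    use_weights: bool = False,
    items: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per item x wave missingness counts, means and standard deviations.

    Statistics are computed over present responses only; when ``use_weights``
    the post-stratification weights are renormalized over the non-missing
    respondents of each item.  An item with zero present responses in a wave
    gets ``defined = False`` and NaN statistics rather than an exception.
    """
    if len(table) == 0:
        raise ValueError("empty survey table")
    cb = table.codebook
    items = list(items) if items is not None else [
        n for n in cb.numeric_items() if n != "weight"
    ]
    rows = []
    for w in table.waves:
        sub = table.wave(w)
        for name in items:
            fielded = w in cb.items[name].waves
            x = sub[name].dropna()
            n_missing = (len(sub) - len(x)) if fielded else 0
            if not fielded or len(x) == 0:
                rows.append((name, w, n_missing, np.nan, np.nan, False))
                continue
            if use_weights:
                mean, sd = _weighted_mean_sd(
                    x.to_numpy(float), sub.loc[x.index, "weight"].to_numpy(float)
                )
            else:
                mean = float(x.mean())
                sd = float(x.std(ddof=1)) if len(x) > 1 else float("nan")
            rows.append((name, w, n_missing, mean, sd, True))
    return pd.DataFrame(
        rows, columns=["item", "wave", "n_missing", "mean", "sd", "defined"]
    ).set_index(["item", "wave"])
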