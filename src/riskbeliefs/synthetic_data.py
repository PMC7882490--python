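"""Synthetic two-wave belief-survey generator and stratum-count generator.

Emulates the statistical structure the analysis modules assume: demographics
drawn from fixed margins, bounded belief items drawn as ``100 * Beta(a, b)``
with covariate effects on the logit of the beta mean, an extra point mass of
"fifty-fifty" answers at exactly 50, per-item missingness, between-wave mean
shifts for own-risk and expected-prevalence items, and post-stratification
weights on gender x age.  Defaults reproduce the margins, item means and
standard deviations, heap masses and missingness rates of the two French
lockdown surveys (n = 1005 and 1004) the package was built around.

Objective benchmark inputs are generated separately: per-stratum diagnosed
counts are binomial in the population with a true prevalence, and deaths are
binomial among the diagnosed with a true infection fatality ratio.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .survey_io import Codebook, SurveyTable, default_codebook

__all__ = [
    "ItemSpec",
    "GeneratorConfig",
    "TrueParams",
    "default_config",
    "generate_survey",
    "generate_stratum_counts",
]

_AGE_BANDS = ("<=19", "20-29", "30-39", "40-49", "50-59", "60-69", "70+")


@dataclass(frozen=True)
class ItemSpec:
    """Generating law of one bounded item.

    ``mean`` is the latent beta mean per wave on (0,1); ``precision`` is
    alpha + beta.  ``pi50`` is the probability, per wave, that the response is
    replaced by the heap ``anchor`` (on the item's raw scale).  ``missing``
    is the per-wave probability that the response is blanked.  Responses are
    ``round(scale * X)`` so that "answered exactly 50" is well defined.
    """

    mean: tuple[float, ...]
    precision: float
    scale: int = 100
    pi50: tuple[float, ...] = (0.0, 0.0)
    missing: tuple[float, ...] = (0.0, 0.0)
    waves: tuple[int, ...] = (1, 2)
    effects: dict = field(default_factory=dict)
    anchor: int = 50

    def validate(self, name: str) -> None:
        if self.precision <= 0:
            raise ValueError(f"item {name}: beta precision must be > 0")
        for m in self.mean:
            if not 0 < m < 1:
                raise ValueError(f"item {name}: beta mean must lie in (0,1)")
        for p in self.pi50:
            if not 0 <= p < 1:
                raise ValueError(f"item {name}: pi50 must lie in [0,1)")
        for r in self.missing:
            if not 0 <= r <= 1:
                raise ValueError(f"item {name}: missingness rate must lie in [0,1]")

    def wave_value(self, values: tuple[float, ...], wave: int) -> float:
        return values[min(wave - 1, len(values) - 1)]


def _normalized(counts: dict[str, float]) -> dict[str, float]:
    tot = float(sum(counts.values()))
    return {k: v / tot for k, v in counts.items()}


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of the synthetic survey's generating process."""

    n_per_wave: tuple[int, int] = (1005, 1004)
    gender_margins: tuple[dict, dict] = (
        _normalized({"female": 527, "male": 478}),
        _normalized({"female": 526, "male": 478}),
    )
    age_margins: tuple[dict, dict] = (
        _normalized(dict(zip(_AGE_BANDS, (23, 122, 190, 174, 185, 140, 171)))),
        _normalized(dict(zip(_AGE_BANDS, (27, 144, 155, 182, 188, 135, 172)))),
    )
    marital_margins: tuple[dict, dict] = (
        _normalized({"single": 319, "couple": 686}),
        _normalized({"single": 335, "couple": 669}),
    )
    education_margins: tuple[dict, dict] = (
        _normalized(
            {"below_high_school": 513, "bachelor_or_higher": 155, "high_school_no_bachelor": 337}
        ),
        _normalized(
            {"below_high_school": 509, "bachelor_or_higher": 159, "high_school_no_bachelor": 337}
        ),
    )
    labor_margins: tuple[dict, dict] = (
        _normalized(
            {
                "inactive": 419,
                "private_employee": 353,
                "public_employee": 103,
                "self_employed": 55,
                "unemployed": 75,
            }
        ),
        _normalized(
            {
                "inactive": 407,
                "private_employee": 360,
                "public_employee": 92,
                "self_employed": 47,
                "unemployed": 97,
            }
        ),
    )
    income_margins: tuple[dict, dict] = (
        _normalized({"low": 341, "high": 130, "middle": 412}),
        _normalized({"low": 365, "high": 141, "middle": 383}),
    )
    income_missing: tuple[float, float] = (122 / 1005, 115 / 1004)
    # regional tiers by share of metropolitan population (west / centre-east / Paris+north-east)
    tier_margins: dict = field(
        default_factory=lambda: {"lowest": 0.333, "medium": 0.402, "highest": 0.265}
    )
    items: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if not self.items:
            object.__setattr__(self, "items", default_item_specs())
        for pair in (
            self.gender_margins,
            self.age_margins,
            self.marital_margins,
            self.education_margins,
            self.labor_margins,
            self.income_margins,
        ):
            for margins in pair:
                if abs(sum(margins.values()) - 1.0) > 1e-9:
                    raise ValueError(f"margins must sum to 1: {margins}")
        if abs(sum(self.tier_margins.values()) - 1.0) > 1e-9:
            raise ValueError("tier margins must sum to 1")
        for name, spec in self.items.items():
            spec.validate(name)


def default_item_specs() -> dict[str, ItemSpec]:
    """Per-item generating laws matching the published wave-level moments.

    Latent beta means are the observed wave means on the unit scale; the
    precision alpha+beta is solved from the observed standard deviation via
    var = m(1-m)/(1+precision).  The own-risk item shifts up 11.5 points and
    the expected-prevalence item down 11.1 points between waves.  Heap masses
    mirror the measured excess-50 percentages; missingness rates are the
    published per-item missing counts over the wave sizes.
    """
    n1, n2 = 1005, 1004
    common = {"male": -0.15, "age_trend": -0.06}
    return {
        "q1_ifr": ItemSpec(
            mean=(0.165, 0.161), precision=1.8,
            missing=(280 / n1, 263 / n2), effects=dict(common),
        ),
        "q1bis_flu_ifr": ItemSpec(
            mean=(0.127,), precision=1.6, waves=(1,),
            missing=(347 / n1,), effects=dict(common),
        ),
        "q2_own_risk": ItemSpec(
            mean=(0.345, 0.460), precision=2.2,
            pi50=(0.12, 0.175), missing=(291 / n1, 274 / n2),
            effects={**common, "tier_medium": 0.08, "tier_highest": 0.15},
        ),
        "q3_others_risk": ItemSpec(
            mean=(0.479, 0.462), precision=3.4,
            pi50=(0.14, 0.16), missing=(373 / n1, 381 / n2),
        ),
        "q4_prevalence": ItemSpec(
            mean=(0.450, 0.339), precision=2.9,
            pi50=(0.02, 0.0), missing=(276 / n1, 308 / n2), effects=dict(common),
        ),
        "q5_relative_risk": ItemSpec(
            mean=(0.560, 0.566), precision=3.4, scale=10,
            missing=(175 / n1, 69 / n2),
        ),
        "q6_worry": ItemSpec(
            mean=(0.606, 0.635), precision=2.4, scale=10,
            missing=(58 / n1, 39 / n2),
        ),
        "q7_contagious": ItemSpec(
            mean=(0.817, 0.790), precision=3.3, scale=10,
            missing=(59 / n1, 44 / n2),
        ),
        "q7bis_contagious_flu": ItemSpec(
            mean=(0.674,), precision=4.6, scale=10, waves=(1,), missing=(96 / n1,),
        ),
        "q8_serious": ItemSpec(
            mean=(0.815, 0.786), precision=3.5, scale=10,
            missing=(39 / n1, 51 / n2),
        ),
        "q8bis_serious_flu": ItemSpec(
            mean=(0.648,), precision=4.5, scale=10, waves=(1,), missing=(75 / n1,),
        ),
        "expected_duration_weeks": ItemSpec(
            mean=(0.251, 0.597), precision=5.2, scale=52,
        ),
    }


@dataclass(frozen=True)
class TrueParams:
    """The realized generating values attached to a generated table."""

    items: dict
    seed: int
    n_per_wave: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_per_wave": list(self.n_per_wave),
            "items": {
                name: {
                    "mean": list(spec.mean),
                    "precision": spec.precision,
                    "scale": spec.scale,
                    "pi50": list(spec.pi50),
                    "missing": list(spec.missing),
                    "waves": list(spec.waves),
                    "effects": dict(spec.effects),
                    "anchor": spec.anchor,
                }
                for name, spec in self.items.items()
            },
        }


def _draw_cat(rng: np.random.Generator, margins: dict[str, float], n: int) -> np.ndarray:
    cats = list(margins)
    p = np.array([margins[c] for c in cats], float)
    return rng.choice(cats, size=n, p=p / p.sum())


def _linear_predictor(spec: ItemSpec, wave: int, demo: pd.DataFrame) -> np.ndarray:
    lp = np.full(len(demo), logit(spec.wave_value(spec.mean, wave)))
    eff = spec.effects
    if "male" in eff:
        lp = lp + eff["male"] * (demo["gender"] == "male").to_numpy(float)
    if "age_trend" in eff:
        age_idx = demo["age_category"].map({b: i for i, b in enumerate(_AGE_BANDS)})
        lp = lp + eff["age_trend"] * (age_idx.to_numpy(float) - 3.0)
    for tier in ("medium", "highest"):
        key = f"tier_{tier}"
        if key in eff:
            lp = lp + eff[key] * (demo["region_tier"] == tier).to_numpy(float)
    return lp


def _draw_item(
    rng: np.random.Generator, spec: ItemSpec, wave: int, demo: pd.DataFrame
) -> np.ndarray:
    n = len(demo)
    mu = expit(_linear_predictor(spec, wave, demo))
    a = mu * spec.precision
    b = (1.0 - mu) * spec.precision
    x = np.round(spec.scale * rng.beta(a, b, size=n)).astype(float)
    p_heap = spec.wave_value(spec.pi50, wave)
    if p_heap > 0:
        x[rng.random(n) < p_heap] = float(spec.anchor)
    p_miss = spec.wave_value(spec.missing, wave) if spec.missing else 0.0
    if p_miss > 0:
        x[rng.random(n) < p_miss] = np.nan
    return x


def _post_stratification_weights(
    demo: pd.DataFrame, gender_margins: dict, age_margins: dict
) -> np.ndarray:
    """Cell weights aligning the gender x age sample margins with the targets.

    Weight of a cell = target probability / observed share, renormalized to
    mean one.  Cells with no observations simply contribute no weight.
    """
    target = {
        (g, a): gender_margins[g] * age_margins[a]
        for g in gender_margins
        for a in age_margins
    }
    obs = demo.groupby(["gender", "age_category"], observed=True).size() / len(demo)
    w = np.empty(len(demo))
    cells = list(zip(demo["gender"], demo["age_category"]))
    # renormalize targets over occupied cells so weighted margins are exact
    occ_tot = sum(target[c] for c in obs.index)
    for i, c in enumerate(cells):
        w[i] = (target[c] / occ_tot) / obs[c]
    return w / w.mean()


_CONFIDENCE_DIST = {
    "confidence_q2": _normalized(
        {"very_high": 45, "high": 215, "moderate": 385, "low": 45, "very_low": 24}
    ),
    "confidence_q3": _normalized(
        {"very_high": 32, "high": 176, "moderate": 351, "low": 65, "very_low": 9}
    ),
}
_HEALTH_DIST = _normalized({"very_good": 209, "good": 659, "bad_or_very_bad": 137})


def generate_survey(
    config: GeneratorConfig | None = None, codebook: Codebook | None = None
) -> tuple[SurveyTable, TrueParams]:
    """Draw a two-wave survey table; identical seed gives an identical table."""
    config = config or GeneratorConfig()
    codebook = codebook or default_codebook()
    rng = np.random.default_rng(config.seed)
    frames = []
    for wave in (1, 2):
        n = config.n_per_wave[wave - 1]
        wi = wave - 1
        demo = pd.DataFrame(
            {
                "respondent_id": [f"w{wave}-{i:05d}" for i in range(n)],
                "wave": wave,
                "gender": _draw_cat(rng, config.gender_margins[wi], n),
                "age_category": _draw_cat(rng, config.age_margins[wi], n),
                "marital": _draw_cat(rng, config.marital_margins[wi], n),
                "education": _draw_cat(rng, config.education_margins[wi], n),
                "labor_status": _draw_cat(rng, config.labor_margins[wi], n),
                "income": _draw_cat(rng, config.income_margins[wi], n),
                "region_tier": _draw_cat(rng, config.tier_margins, n),
            }
        )
        if n == 0:
            frames.append(pd.DataFrame(columns=codebook.columns))
            continue
        demo.loc[rng.random(n) < config.income_missing[wi], "income"] = np.nan
        demo["weight"] = _post_stratification_weights(
            demo, config.gender_margins[wi], config.age_margins[wi]
        )
        for name, spec in config.items.items():
            if wave in spec.waves:
                demo[name] = _draw_item(rng, spec, wave, demo)
            else:
                demo[name] = np.nan
        # confidence answered exactly when the underlying belief item is
        for conf, item in (("confidence_q2", "q2_own_risk"), ("confidence_q3", "q3_others_risk")):
            col = np.full(n, np.nan, dtype=object)
            if wave == 1:
                present = demo[item].notna().to_numpy()
                col[present] = _draw_cat(rng, _CONFIDENCE_DIST[conf], int(present.sum()))
            demo[conf] = col
        if wave == 1:
            demo["health_status"] = _draw_cat(rng, _HEALTH_DIST, n)
            chronic = _draw_cat(rng, _normalized({"no": 685, "yes": 289}), n).astype(object)
            chronic[rng.random(n) < 30 / 1005] = np.nan
            demo["chronic_illness"] = chronic
            demo["diagnosed_covid"] = _draw_cat(rng, {"no": 1 - 0.011, "yes": 0.011}, n)
            demo["relative_ill"] = _draw_cat(rng, {"no": 1 - 0.243, "yes": 0.243}, n)
        else:
            demo["health_status"] = np.nan
            demo["chronic_illness"] = np.nan
            demo["diagnosed_covid"] = _draw_cat(rng, {"no": 1 - 0.028, "yes": 0.028}, n)
            demo["relative_ill"] = _draw_cat(rng, {"no": 1 - 0.257, "yes": 0.257}, n)
        frames.append(demo[codebook.columns])
    data = pd.concat(frames, ignore_index=True)
    truth = TrueParams(
        items=dict(config.items), seed=config.seed, n_per_wave=tuple(config.n_per_wave)
    )
    return SurveyTable(data, codebook), truth


def simple_survey_config(
    n: int = 1000,
    mean: float = 0.35,
    precision: float = 2.2,
    pi50: float = 0.0,
    missing: float = 0.0,
    item: str = "q2_own_risk",
    seed: int = 0,
    **kwargs,
) -> GeneratorConfig:
    """One-item configuration with no covariate effects, for focused tests."""
    spec = ItemSpec(
        mean=(mean, mean), precision=precision, pi50=(pi50, pi50),
        missing=(missing, missing), **kwargs,
    )
    items = {
        name: dataclasses.replace(s, missing=tuple(1.0 for _ in s.missing) or (1.0, 1.0))
        for name, s in default_item_specs().items()
    }
    items[item] = spec
    return GeneratorConfig(n_per_wave=(n, 0), items=items, seed=seed, income_missing=(0.0, 0.0))


def generate_stratum_counts(
    truth: pd.DataFrame, seed: int = 0, date_label: str = "synthetic"
) -> pd.DataFrame:
    """Draw a stratum-level count table from true prevalence and IFR.

    ``truth`` needs columns ``population``, ``true_prevalence`` and
    ``true_ifr`` (both rates on [0,1]) plus any stratum-key columns; the
    result carries the keys with ``deaths``, ``diagnosed``, ``population``
    and ``date_label``, satisfying deaths <= diagnosed <= population.
    """
    for col in ("population", "true_prevalence", "true_ifr"):
        if col not in truth.columns:
            raise ValueError(f"truth table lacks column {col}")
    prev = truth["true_prevalence"].to_numpy(float)
    ifr = truth["true_ifr"].to_numpy(float)
    pop = truth["population"].to_numpy()
    if ((prev < 0) | (prev > 1)).any() or ((ifr < 0) | (ifr > 1)).any():
        raise ValueError("true_prevalence and true_ifr must lie in [0,1]")
    if (pop <= 0).any() or not np.issubdtype(np.asarray(pop).dtype, np.integer):
        raise ValueError("populations must be positive integers")
    rng = np.random.default_rng(seed)
    diagnosed = rng.binomial(pop, prev)
    deaths = rng.binomial(diagnosed, ifr)
    out = truth.drop(columns=["true_prevalence", "true_ifr"]).copy()
    out["diagnosed"] = diagnosed
    out["deaths"] = deaths
    out["date_label"] = date_label
    keys = [c for c in out.columns if c not in ("population", "diagnosed", "deaths", "date_label")]
    return out[keys + ["deaths", "diagnosed", "population", "date_label"]]
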