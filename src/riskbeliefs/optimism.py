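"""Comparative optimism: own risk against expected population prevalence.

A respondent who judges their own risk of catching the disease (0-100) below
the prevalence they expect in the population is comparatively optimistic.
The index rescales the difference to [0,1]:

    index = (prevalence_belief - own_risk + 100) / 200

so 0.5 means no comparative optimism, values above 0.5 comparative optimism,
below 0.5 comparative pessimism.  The module reports per-wave mean
differences with paired t tests and the between-wave contrast from a
quasibinomial logit GLM of the index on a wave indicator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import paired_test
from .regression import GlmFit, fit_quasibinomial
from .survey_io import SurveyTable

__all__ = ["WaveOptimism", "OptimismResult", "optimism_index", "optimism_dynamics"]

OWN_RISK = "q2_own_risk"
PREVALENCE = "q4_prevalence"


@dataclass(frozen=True)
class WaveOptimism:
    wave: int
    n_pairs: int
    mean_own_minus_prev: float  # mean (own risk - expected prevalence), points
    p_value: float  # two-sided paired t
    index_mean: float


@dataclass(frozen=True)
class OptimismResult:
    per_wave: tuple[WaveOptimism, ...]
    wave_contrast_p: float  # GLM p for the wave indicator, NaN if < 2 waves
    glm: GlmFit | None


def optimism_index(own_risk, prevalence):
    """Comparative-optimism index on [0,1]; NaN where either item is missing.

    The unique affine map sending a difference (prevalence - own risk) of
    -100 to 0, 0 to 0.5 and +100 to 1.
    """
    own = np.asarray(own_risk, float)
    prev = np.asarray(prevalence, float)
    return (prev - own + 100.0) / 200.0


def optimism_dynamics(
    table: SurveyTable, use_weights: bool = False
) -> OptimismResult:
    """Per-wave comparative optimism and its between-wave contrast.

    Waves with fewer than 2 complete own-risk/prevalence pairs are skipped
    with a warning.  The wave contrast is the p-value of the wave indicator
    in a quasibinomial logit GLM of the index (weighted by default weights
    when ``use_weights``).
    """
    per_wave = []
    usable = []
    for w in table.waves:
        pairs = table.wave(w)[[OWN_RISK, PREVALENCE]].dropna()
        if len(pairs) < 2:
            import warnings

            warnings.warn(f"wave {w}: fewer than 2 complete pairs, skipped", stacklevel=2)
            continue
        cmp = paired_test(table, OWN_RISK, PREVALENCE, "two_sided", wave=w)
        idx = optimism_index(pairs[OWN_RISK], pairs[PREVALENCE])
        per_wave.append(
            WaveOptimism(
                wave=w,
                n_pairs=cmp.n_pairs,
                mean_own_minus_prev=cmp.mean_difference,
                p_value=cmp.p_value,
                index_mean=float(np.mean(idx)),
            )
        )
        usable.append(w)
    glm = None
    contrast_p = float("nan")
    if len(usable) >= 2:
        df = table.data[table.data["wave"].isin(usable)][
            [OWN_RISK, PREVALENCE, "wave", "weight"]
        ].dropna()
        df = df.assign(
            optimism=optimism_index(df[OWN_RISK], df[PREVALENCE]),
            wave2=(df["wave"] == usable[1]).astype(float),
        )
        glm = fit_quasibinomial(
            df, "optimism", ["wave2"], use_weights=use_weights, outcome_scale=1.0
        )
        ame_idx = list(glm.params.index).index("wave2")
        beta = glm.params.iloc[ame_idx]
        se = float(np.sqrt(glm.cov.iloc[ame_idx, ame_idx]))
        from scipy import stats as _st

        contrast_p = float(2 * _st.norm.sf(abs(beta / se)))
    return OptimismResult(per_wave=tuple(per_wave), wave_contrast_p=contrast_p, glm=glm)


def optimism_report(result: OptimismResult) -> pd.DataFrame:
    """Flat per-wave table plus the wave-contrast p-value."""
    rows = [
        {
            "wave": w.wave,
            "n_pairs": w.n_pairs,
            "mean_own_minus_prev": w.mean_own_minus_prev,
            "index_mean": w.index_mean,
            "p_value": w.p_value,
        }
        for w in result.per_wave
    ]
    out = pd.DataFrame(rows)
    out["wave_contrast_p"] = result.wave_contrast_p
    return out
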