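"""Detection of "fifty-fifty" response heaping on 0-100 belief items.

A common artefact of numeric belief elicitation is a spike of answers at
exactly 50, read as epistemic uncertainty rather than a numeric judgment.
The procedure here: fit a beta law to the item's distribution, compare the
observed share of answers in the 45-55 window with the share the fitted beta
predicts there (the *excess-50* percentage), report means with and without
the exact-50 answers, and test the difference by regressing the demeaned
answers on an indicator of the "50" answer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .survey_io import SurveyTable

__all__ = [
    "BetaFit",
    "HeapingResult",
    "fit_beta",
    "excess_fifty",
    "heaping_adjusted_means",
    "analyze_heaping",
    "DEFAULT_ITEMS",
]

DEFAULT_ITEMS = ("q1_ifr", "q2_own_risk", "q3_others_risk", "q4_prevalence")

#: window of answers attributed to the heap, inclusive on both ends
WINDOW = (45.0, 55.0)


class DegenerateFitError(ValueError):
    """All responses identical; a beta law cannot be fitted."""


@dataclass(frozen=True)
class BetaFit:
    alpha: float
    beta: float
    n_used: int
    log_likelihood: float

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class HeapingResult:
    item: str
    wave: int
    observed_window_mass: float
    expected_window_mass: float
    excess_pct: float
    mean_proportion: float
    mean_without_50s: float
    p_value_indicator_test: float  # NaN when no exact-50 answers
    fit: BetaFit


def _clean(responses) -> np.ndarray:
    x = np.asarray(pd.Series(responses).dropna(), dtype=float)
    if ((x < 0) | (x > 100)).any():
        raise ValueError("responses must lie in [0, 100]")
    return x


def _shrink_to_open_unit(x: np.ndarray) -> np.ndarray:
    # Smithson-Verkuilen boundary shrinkage keeps exact 0/100 answers in the
    # sample while bounding the log-likelihood
    n = len(x)
    return (x / 100.0 * (n - 1) + 0.5) / n


def fit_beta(responses, include_fifties: bool = True, method: str = "mle") -> BetaFit:
    """Maximum-likelihood beta fit to responses on the 0-100 scale.

    Responses are mapped to (0,1) by x/100 followed by boundary shrinkage
    x' = (x(n-1) + 0.5)/n.  ``include_fifties=False`` drops the exact-50
    answers before fitting; ``method='moments'`` uses the method of moments
    instead of maximum likelihood.
    """
    x = _clean(responses)
    if not include_fifties:
        x = x[x != 50.0]
    if len(x) < 2 or np.unique(x).size < 2:
        raise DegenerateFitError("need at least 2 distinct responses to fit a beta law")
    y = _shrink_to_open_unit(x)
    if method == "moments":
        m, v = y.mean(), y.var(ddof=1)
        phi = m * (1 - m) / v - 1.0
        if phi <= 0:
            raise DegenerateFitError("sample variance too large for a beta law")
        a, b = m * phi, (1 - m) * phi
    elif method == "mle":
        a, b, _, _ = stats.beta.fit(y, floc=0, fscale=1)
    else:
        raise ValueError(f"unknown method {method!r}")
    ll = float(np.sum(stats.beta.logpdf(y, a, b)))
    return BetaFit(alpha=float(a), beta=float(b), n_used=len(x), log_likelihood=ll)


def excess_window_mass(
    responses, fit: BetaFit | None = None, include_fifties: bool = True
) -> tuple[float, float, float]:
    """(observed, expected, excess%) mass in the 45-55 answer window.

    Observed mass is the share of answers in [45, 55] inclusive.  Expected
    mass is the fitted beta's probability of producing an integer answer in
    that window: answers are whole numbers, so the window corresponds to
    latent values rounding into it, I(0.555; a, b) - I(0.445; a, b) with I
    the regularized incomplete beta function.  (Evaluating the continuous
    window [0.45, 0.55] instead would understate the expectation by the two
    half-cells and bias the excess upward by about a tenth of the window
    mass.)
    """
    x = _clean(responses)
    fit = fit or fit_beta(x, include_fifties=include_fifties)
    observed = float(np.mean((x >= WINDOW[0]) & (x <= WINDOW[1])))
    expected = float(
        stats.beta.cdf((WINDOW[1] + 0.5) / 100.0, fit.alpha, fit.beta)
        - stats.beta.cdf((WINDOW[0] - 0.5) / 100.0, fit.alpha, fit.beta)
    )
    return observed, expected, 100.0 * (observed - expected)


def heaping_adjusted_means(responses) -> tuple[float, float, float]:
    """Means on the proportion scale with and without the exact-50 answers.

    The significance of the 50s' pull on the mean comes from an ordinary
    least-squares regression of the demeaned answers on an indicator of the
    "50" answer (two-sided t test on the indicator coefficient) — which is
    algebraically the pooled-variance two-sample t test of the 50 group
    against the rest.  With no exact-50 answers the p-value is NaN.
    """
    x = _clean(responses)
    if len(x) < 2:
        raise ValueError("need at least 2 responses")
    is50 = x == 50.0
    if is50.all():
        raise ValueError("all responses are exactly 50")
    p = x / 100.0
    mean_all = float(p.mean())
    mean_wo = float(p[~is50].mean())
    if not is50.any():
        return mean_all, mean_wo, float("nan")
    d = p - mean_all
    z = is50.astype(float)
    zc = z - z.mean()
    beta1 = float(np.sum(zc * d) / np.sum(zc**2))
    resid = d - d.mean() - beta1 * zc
    dof = len(x) - 2
    if dof <= 0 or np.allclose(resid, 0):
        return mean_all, mean_wo, float("nan") if dof <= 0 else 0.0
    se = float(np.sqrt(np.sum(resid**2) / dof / np.sum(zc**2)))
    t = beta1 / se
    pval = float(2 * stats.t.sf(abs(t), dof))
    return mean_all, mean_wo, pval


def excess_fifty(
    responses, item: str = "", wave: int = 0, include_fifties: bool = True
) -> HeapingResult:
    """Full heaping analysis of one item's responses."""
    x = _clean(responses)
    fit = fit_beta(x, include_fifties=include_fifties)
    observed, expected, excess = excess_window_mass(x, fit=fit)
    mean_all, mean_wo, pval = heaping_adjusted_means(x)
    return HeapingResult(
        item=item,
        wave=wave,
        observed_window_mass=observed,
        expected_window_mass=expected,
        excess_pct=excess,
        mean_proportion=mean_all,
        mean_without_50s=mean_wo,
        p_value_indicator_test=pval,
        fit=fit,
    )


def analyze_heaping(
    table: SurveyTable,
    items=DEFAULT_ITEMS,
    include_fifties: bool = True,
) -> pd.DataFrame:
    """Heaping summary per item x wave, unweighted by design.

    Returns one row per item and wave with the excess-50 percentage, the
    means with and without 50s (proportion scale) and the indicator-test
    p-value.
    """
    rows = []
    for item in items:
        for w in table.waves:
            if w not in table.codebook.items[item].waves:
                continue
            res = excess_fifty(
                table.wave(w)[item], item=item, wave=w, include_fifties=include_fifties
            )
            rows.append(
                {
                    "item": item,
                    "wave": w,
                    "excess_pct": res.excess_pct,
                    "mean_proportion": res.mean_proportion,
                    "mean_without_50s": res.mean_without_50s,
                    "p_value": res.p_value_indicator_test,
                    "alpha": res.fit.alpha,
                    "beta": res.fit.beta,
                    "n_used": res.fit.n_used,
                }
            )
    return pd.DataFrame(rows)
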