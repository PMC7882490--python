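"""Survey-weighted quasibinomial logit regression with average marginal effects.

Belief items live on bounded scales (0-100 sliders, 0-10 scores); rescaled to
[0,1] they are continuous proportions, so the mean model is a logit link with
quasi-likelihood variance phi * mu * (1 - mu).  Post-stratification weights
enter as variance weights (multiplying the IRLS working weights), the
dispersion phi is estimated from Pearson residuals, and the coefficient
covariance is a design-robust (sandwich) estimator by default.  Effects are
reported as average marginal effects (AME): for a categorical level, the
average over respondents of the fitted-probability contrast against the
reference level; standard errors follow by the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .survey_io import SurveyTable

__all__ = ["GlmFit", "fit_quasibinomial", "average_marginal_effects"]


@dataclass
class GlmFit:
    """A fitted weighted quasibinomial logit model."""

    params: pd.Series
    cov: pd.DataFrame
    dispersion: float
    n_used: int
    converged: bool
    iterations: int
    outcome: str
    terms: list[str]
    weighted: bool
    separation_suspected: bool
    #: categorical term -> ordered category list (first = reference)
    categories: dict = field(default_factory=dict)
    #: complete-case analysis frame (terms + outcome + weight)
    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    def design_matrix(self, df: pd.DataFrame) -> pd.DataFrame:
        return _design_matrix(df, self.terms, self.categories)

    def predict(self, df: pd.DataFrame | None = None) -> np.ndarray:
        X = self.design_matrix(self.frame if df is None else df)
        return expit(X.to_numpy(float) @ self.params.to_numpy(float))


def _term_categories(
    df: pd.DataFrame, terms: list[str], table: SurveyTable | None
) -> dict[str, list[str]]:
    cats: dict[str, list[str]] = {}
    for t in terms:
        if pd.api.types.is_numeric_dtype(df[t]):
            continue
        if table is not None and table.codebook.items.get(t) is not None and (
            table.codebook.items[t].categories
        ):
            declared = list(table.codebook.items[t].categories)
            cats[t] = [c for c in declared if c in set(df[t].dropna())]
        else:
            cats[t] = sorted(df[t].dropna().unique())
    return cats


def _design_matrix(
    df: pd.DataFrame, terms: list[str], categories: dict[str, list[str]]
) -> pd.DataFrame:
    cols = {"Intercept": np.ones(len(df))}
    for t in terms:
        if t in categories:
            for level in categories[t][1:]:
                cols[f"{t}[{level}]"] = (df[t] == level).to_numpy(float)
        else:
            cols[t] = df[t].to_numpy(float)
    return pd.DataFrame(cols, index=df.index)


def fit_quasibinomial(
    table: SurveyTable | pd.DataFrame,
    outcome: str,
    terms: list[str],
    use_weights: bool = True,
    outcome_scale: float = 100.0,
    cov_type: str = "HC1",
    wave: int | None = None,
) -> GlmFit:
    """Fit a weighted quasibinomial logit GLM of ``outcome`` on ``terms``.

    The outcome is divided by ``outcome_scale`` to land on [0,1] (pass 1.0
    for an already-proportion outcome).  Complete-case (listwise) deletion is
    applied over the outcome and all terms.  Categorical reference levels are
    the first codebook-declared category of each term.  ``cov_type`` is a
    statsmodels sandwich type (``HC1`` default) or ``nonrobust`` for the
    model-based covariance scaled by the Pearson dispersion.
    """
    df = table.data if isinstance(table, SurveyTable) else table
    if wave is not None:
        df = df[df["wave"] == wave]
    needed = [outcome] + list(terms) + (["weight"] if use_weights else [])
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise ValueError(f"column(s) not in table: {missing_cols}")
    frame = df[list(dict.fromkeys(needed))].dropna().copy()
    categories = _term_categories(
        frame, list(terms), table if isinstance(table, SurveyTable) else None
    )
    X = _design_matrix(frame, list(terms), categories)
    p = X.shape[1]
    if len(frame) < p + 2:
        raise ValueError(f"need >= {p + 2} complete records, got {len(frame)}")
    y = frame[outcome].to_numpy(float) / outcome_scale
    if (y < 0).any() or (y > 1).any():
        raise ValueError("outcome outside [0,1] after rescaling")
    w = frame["weight"].to_numpy(float) if use_weights else np.ones(len(frame))
    model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w)
    if cov_type == "nonrobust":
        res = model.fit(maxiter=100, tol=1e-8, scale="X2")
    else:
        res = model.fit(maxiter=100, tol=1e-8, cov_type=cov_type)
    dispersion = float(res.pearson_chi2 / res.df_resid)
    eta = X.to_numpy(float) @ np.asarray(res.params)
    fit = GlmFit(
        params=pd.Series(np.asarray(res.params), index=X.columns),
        cov=pd.DataFrame(np.asarray(res.cov_params()), index=X.columns, columns=X.columns),
        dispersion=dispersion,
        n_used=len(frame),
        converged=bool(res.converged),
        iterations=int(res.fit_history.get("iteration", 0)) if res.fit_history else 0,
        outcome=outcome,
        terms=list(terms),
        weighted=use_weights,
        separation_suspected=bool(np.abs(eta).max() > 30),
        categories=categories,
        frame=frame,
    )
    if not fit.converged:
        import warnings

        warnings.warn(f"GLM for {outcome} did not converge", stacklevel=2)
    return fit


def _ame_value(fit: GlmFit, params: np.ndarray, term: str, level: str | None) -> float:
    """AME for one contrast at given coefficient values (weighted when fitted)."""
    frame = fit.frame
    w = frame["weight"].to_numpy(float) if fit.weighted else np.ones(len(frame))
    w = w / w.sum()
    if level is not None:  # categorical: level vs reference
        hi = frame.copy()
        hi[term] = level
        lo = frame.copy()
        lo[term] = fit.categories[term][0]
        Xh = _design_matrix(hi, fit.terms, fit.categories).to_numpy(float)
        Xl = _design_matrix(lo, fit.terms, fit.categories).to_numpy(float)
        return float(np.sum(w * (expit(Xh @ params) - expit(Xl @ params))))
    # numeric: average derivative d mu / d x = beta * mu (1 - mu)
    X = fit.design_matrix(frame).to_numpy(float)
    mu = expit(X @ params)
    beta = params[list(fit.params.index).index(term)]
    return float(np.sum(w * beta * mu * (1.0 - mu)))


def average_marginal_effects(fit: GlmFit, step: float = 1e-6) -> pd.DataFrame:
    """Average marginal effects with delta-method standard errors.

    One row per non-reference level of each categorical term (contrast
    against the reference, other covariates held at observed values) and per
    numeric term (average derivative).  The Jacobian of each AME with respect
    to the coefficients is computed by central differences with the given
    step; SE^2 = J' V J with V the fit's covariance; p-values are two-sided
    normal.
    """
    if not fit.converged:
        raise ValueError("cannot compute marginal effects from a non-converged fit")
    theta = fit.params.to_numpy(float)
    V = fit.cov.to_numpy(float)
    contrasts: list[tuple[str, str | None]] = []
    for t in fit.terms:
        if t in fit.categories:
            contrasts.extend((t, level) for level in fit.categories[t][1:])
        else:
            contrasts.append((t, None))
    rows = []
    for term, level in contrasts:
        ame = _ame_value(fit, theta, term, level)
        J = np.empty(len(theta))
        for k in range(len(theta)):
            up = theta.copy()
            dn = theta.copy()
            up[k] += step
            dn[k] -= step
            J[k] = (_ame_value(fit, up, term, level) - _ame_value(fit, dn, term, level)) / (
                2 * step
            )
        se = float(np.sqrt(J @ V @ J))
        z = ame / se if se > 0 else np.nan
        rows.append(
            {
                "term": term,
                "level": level if level is not None else "(per unit)",
                "ame": ame,
                "se": se,
                "p_value": float(2 * stats.norm.sf(abs(z))) if se > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
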