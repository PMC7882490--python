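"""Independent iteratively-reweighted-least-squares oracle for test use.

Deliberately minimal and self-contained (numpy only) so it shares no code
path with the package's statsmodels-backed GLM fit.
"""

import numpy as np


def irls_quasibinomial_logit(X, y, w=None, tol=1e-12, maxiter=200):
    """Coefficients of a logit-link quasibinomial GLM by plain IRLS.

    ``w`` are record-level variance weights multiplying the working weights.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    w = np.ones(n) if w is None else np.asarray(w, float)
    beta = np.zeros(p)
    for _ in range(maxiter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        working_w = w * mu * (1.0 - mu)  # logit link: W = w * mu(1-mu)
        z = eta + (y - mu) / (mu * (1.0 - mu))
        WX = X * working_w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (working_w * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    return beta
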