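"""Compact Newton/IRLS logistic solver for permutation inner loops.

Reported odds ratios, confidence intervals and Wald tests elsewhere in the
package come from statsmodels; this solver exists only where thousands of
small refits are needed (binary-trait genome-scan permutations, GWAS
permutation p-values).  It is validated against statsmodels in the tests.
"""

from __future__ import annotations

import numpy as np

MAX_ABS_ETA = 30.0  # cap on the linear predictor; flags (quasi-)separation


def logit_fit(
    X: np.ndarray,
    y: np.ndarray,
    maxiter: int = 50,
    tol: float = 1e-10,
):
    """Maximum-likelihood logistic fit of y (0/1) on the design X.

    Returns ``(beta, cov, llf, converged)``.  ``converged`` is False when the
    iteration cap is hit or the linear predictor escapes to +-MAX_ABS_ETA
    (complete separation); the capped fit is still returned so callers can
    flag the record rather than fail.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    XtX_ridge = 1e-10 * np.eye(p)
    for _ in range(maxiter):
        eta = np.clip(X @ beta, -MAX_ABS_ETA, MAX_ABS_ETA)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X + XtX_ridge
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -MAX_ABS_ETA, MAX_ABS_ETA)
    if np.any(np.abs(X @ beta) >= MAX_ABS_ETA):
        converged = False
    mu = 1.0 / (1.0 + np.exp(-eta))
    llf = float(np.sum(y * np.log(mu + 1e-300) + (1 - y) * np.log(1 - mu + 1e-300)))
    w = mu * (1.0 - mu)
    hess = (X * w[:, None]).T @ X + 1e-10 * np.eye(p)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, cov, llf, converged


def logit_llf_null(y: np.ndarray) -> float:
    """Log-likelihood of the intercept-only logistic model (closed form)."""
    y = np.asarray(y, dtype=float)
    n, k = len(y), float(y.sum())
    if k == 0 or k == n:
        return 0.0
    p = k / n
    return float(k * np.log(p) + (n - k) * np.log(1 - p))
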