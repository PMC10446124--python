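"""Fast regression kernels shared by all estimation routines.

Ordinary least squares and maximum-likelihood logistic regression are
implemented directly on numpy arrays.  The Monte Carlo engines (SIMEX
simulation step, bootstrap-inside-simulation, scenario grids) refit the
same small design matrix tens of thousands of times per run, so per-fit
model-object overhead dominates total cost; these kernels keep a full
simulation study at desk scale.  Coefficients, standard errors and
log-likelihoods are validated against statsmodels in the test suite.
"""

from __future__ import annotations

import numpy as np


class FitError(RuntimeError):
    """A regression fit failed (collinearity, separation, non-convergence)."""


def ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS fit. Returns (coefficients, covariance matrix of coefficients).

    Covariance uses the unbiased residual variance (denominator n - p).
    """
    n, p = X.shape
    if n <= p:
        raise FitError(f"need more than {p} observations, got {n}")
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:
        raise FitError("collinear (rank-deficient) design matrix") from exc
    # guard near-singular designs that inv() silently accepts
    if np.linalg.cond(xtx) > 1e12:
        raise FitError("collinear (rank-deficient) design matrix")
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    s2 = float(resid @ resid) / (n - p)
    return beta, s2 * xtx_inv


def batched_ols_coef(Xs: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS coefficients for a stack of designs (m, n, p) sharing one outcome.

    Returns an (m, p) array. Used by the vectorised SIMEX simulation step.
    """
    xt = Xs.transpose(0, 2, 1)
    xtx = xt @ Xs
    xty = xt @ y
    try:
        return np.linalg.solve(xtx, xty[..., None])[..., 0]
    except np.linalg.LinAlgError as exc:
        raise FitError("collinear design in batched refit") from exc


def logit(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood logistic regression via Newton-Raphson (IRLS).

    Returns (coefficients, covariance = inverse observed information).
    Raises FitError on one-class outcomes, divergence (a symptom of
    perfect separation) or non-convergence.
    """
    n, p = X.shape
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise FitError("outcome has a single class; logistic fit impossible")
    beta = np.zeros(p)
    pbar = y.mean()
    beta[0] = np.log(pbar / (1.0 - pbar))  # intercept warm start
    ll_old = _logit_loglik(X, y, beta)
    for _ in range(max_iter):
        eta = X @ beta
        mu = _expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular information matrix") from exc
        # step-halving keeps Newton monotone on awkward resamples
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new = _logit_loglik(X, y, cand)
            if ll_new >= ll_old - 1e-12:
                break
            factor *= 0.5
        beta = beta + factor * step
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e4:
            raise FitError("diverging coefficients (possible perfect separation)")
        if np.max(np.abs(factor * step)) < tol:
            mu = _expit(X @ beta)
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            hess = (X * w[:, None]).T @ X
            return beta, np.linalg.inv(hess)
        ll_old = ll_new
    raise FitError("logistic fit did not converge")


def _expit(eta: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-eta))


def _logit_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(1+exp(eta)) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def nagelkerke_r2(y: np.ndarray, X: np.ndarray) -> float:
    """Nagelkerke pseudo R-squared of a logistic model.

    Cox-Snell R2 = 1 - exp(2(ll0 - ll1)/n), rescaled by its maximum
    1 - exp(2 ll0 / n); ll0 is the intercept-only log-likelihood, which
    has the closed form n*(pbar log pbar + (1-pbar) log(1-pbar)).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    beta, _ = logit(X, y)
    ll1 = _logit_loglik(X, y, beta)
    pbar = y.mean()
    ll0 = n * (pbar * np.log(pbar) + (1.0 - pbar) * np.log(1.0 - pbar))
    cox_snell = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
    return float(cox_snell / (1.0 - np.exp(2.0 * ll0 / n)))
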