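"""Elastic-net penalized logistic regression with a glmnet-style solver.

Implements the regularized-regression primitive used by the encoding and
readout models: coordinate descent on an IRLS quadratic approximation,
solved along a decreasing penalty path with warm starts, and penalty
selection by grouped (leave-one-video-out) cross-validated binomial
deviance.

The objective minimized is::

    -(1/n) * loglik(b0, beta) + lam * (alpha*||beta||_1 + (1-alpha)/2*||beta||_2^2)

with an unpenalized intercept.  This matches the parameterization of the
reference implementations of elastic-net logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "LogisticNetPath",
    "CVResult",
    "lambda_grid",
    "logistic_net_path",
    "fit_logistic_net",
    "cv_lambda_min",
    "binomial_deviance",
]

_PMIN = 1e-9
_WMIN = 1e-5


@njit(cache=True)
def _cd_update(X, beta, b0, w, r, sw, x2w, l1, l2, active):  # pragma: no cover
    """One coordinate-descent sweep.

    Returns the maximum curvature-weighted squared coefficient change
    (the glmnet convergence metric).
    """
    n, p = X.shape
    maxd = 0.0
    num = 0.0
    for i in range(n):
        num += r[i]
    d0 = num / sw
    b0_new = b0 + d0
    if d0 != 0.0:
        for i in range(n):
            r[i] -= w[i] * d0
        ad = (sw / n) * d0 * d0
        if ad > maxd:
            maxd = ad
    for j in range(p):
        if not active[j]:
            continue
        bj = beta[j]
        num = 0.0
        for i in range(n):
            num += X[i, j] * r[i]
        num = num / n + x2w[j] * bj
        if num > l1:
            bn = (num - l1) / (x2w[j] + l2)
        elif num < -l1:
            bn = (num + l1) / (x2w[j] + l2)
        else:
            bn = 0.0
        d = bn - bj
        if d != 0.0:
            beta[j] = bn
            for i in range(n):
                r[i] -= w[i] * X[i, j] * d
            ad = x2w[j] * d * d
            if ad > maxd:
                maxd = ad
    return b0_new, maxd


@njit(cache=True)
def _deviance_nat(y, eta):  # pragma: no cover
    n = y.shape[0]
    dev = 0.0
    for i in range(n):
        e = eta[i]
        if e > 30.0:
            ll = (y[i] - 1.0) * e
        elif e < -30.0:
            ll = y[i] * e
        else:
            ll = y[i] * e - np.log(1.0 + np.exp(e))
        dev -= 2.0 * ll
    return dev / n


@njit(cache=True)
def _cd_path(X, y, alpha, lambdas, beta0, b0_init, max_outer, tol, dev_stop):  # pragma: no cover
    n, p = X.shape
    nlam = lambdas.shape[0]
    B = np.zeros((nlam, p))
    b0s = np.zeros(nlam)
    beta = beta0.copy()
    b0 = b0_init
    xb = X @ beta
    ybar = y.mean()
    if ybar < _PMIN:
        ybar = _PMIN
    if ybar > 1.0 - _PMIN:
        ybar = 1.0 - _PMIN
    null_dev = -2.0 * (ybar * np.log(ybar) + (1.0 - ybar) * np.log(1.0 - ybar))
    active = np.ones(p, dtype=np.bool_)
    w = np.empty(n)
    r = np.empty(n)
    x2w = np.empty(p)
    stopped = -1
    for il in range(nlam):
        lam = lambdas[il]
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        for _outer in range(max_outer):
            # IRLS quadratic approximation at the current solution
            eta = b0 + xb
            for i in range(n):
                e = eta[i]
                if e > 30.0:
                    pr = 1.0
                elif e < -30.0:
                    pr = 0.0
                else:
                    pr = 1.0 / (1.0 + np.exp(-e))
                wi = pr * (1.0 - pr)
                if wi < _WMIN:
                    wi = _WMIN
                w[i] = wi
                r[i] = y[i] - pr
            sw = w.sum()
            for j in range(p):
                s = 0.0
                for i in range(n):
                    s += w[i] * X[i, j] * X[i, j]
                x2w[j] = s / n
            # first sweep over all coordinates, then iterate the active set
            for j in range(p):
                active[j] = True
            b0, maxd_outer = _cd_update(X, beta, b0, w, r, sw, x2w, l1, l2, active)
            for j in range(p):
                active[j] = beta[j] != 0.0
            for _sweep in range(1000):
                b0, maxd = _cd_update(X, beta, b0, w, r, sw, x2w, l1, l2, active)
                if maxd < tol:
                    break
            # KKT check: one more full sweep; re-enter if anything moved
            for j in range(p):
                active[j] = True
            b0, maxd = _cd_update(X, beta, b0, w, r, sw, x2w, l1, l2, active)
            xb = X @ beta
            if maxd_outer < tol and maxd < tol:
                break
        B[il] = beta
        b0s[il] = b0
        if dev_stop and null_dev > 0.0:
            dev = _deviance_nat(y, b0 + xb)
            if dev < 0.01 * null_dev:
                stopped = il
                break
    if stopped >= 0:
        for il in range(stopped + 1, nlam):
            B[il] = B[stopped]
            b0s[il] = b0s[stopped]
    return B, b0s


@dataclass
class LogisticNetPath:
    """Solution path of an elastic-net logistic regression."""

    lambdas: np.ndarray
    coefs: np.ndarray  # (n_lambda, p)
    intercepts: np.ndarray  # (n_lambda,)
    alpha: float

    def at(self, lam: float) -> tuple[np.ndarray, float]:
        """Coefficients and intercept at the grid value closest to ``lam``."""
        i = int(np.argmin(np.abs(self.lambdas - lam)))
        return self.coefs[i].copy(), float(self.intercepts[i])


@dataclass
class CVResult:
    lambda_min: float
    lambdas: np.ndarray
    mean_deviance: np.ndarray
    alpha: float
    n_folds: int = 0
    extras: dict = field(default_factory=dict)


def _as01(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    u = np.unique(y)
    if not np.all(np.isin(u, (0.0, 1.0))):
        raise ValueError("labels must be coded 0/1")
    return y


def lambda_grid(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.95,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-2,
) -> np.ndarray:
    """Log-spaced penalty grid from the data-dependent ``lambda_max`` down.

    ``lambda_max`` is the smallest penalty at which all coefficients are
    zero under the null (intercept-only) model.
    """
    y = _as01(y)
    n = X.shape[0]
    ybar = y.mean()
    g = X.T @ (y - ybar) / n
    amax = max(alpha, 1e-3)
    lam_max = float(np.max(np.abs(g))) / amax
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def logistic_net_path(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.95,
    lambdas: np.ndarray | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-2,
    max_outer: int = 25,
    tol: float = 1e-9,
    dev_stop: bool = True,
) -> LogisticNetPath:
    """Fit the whole penalty path with warm starts (decreasing penalty)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    y = _as01(y)
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    if lambdas is None:
        lambdas = lambda_grid(X, y, alpha, n_lambda, lambda_min_ratio)
    lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1].copy()
    ybar = float(np.clip(y.mean(), _PMIN, 1 - _PMIN))
    b0 = float(np.log(ybar / (1 - ybar)))
    B, b0s = _cd_path(
        X, y, float(alpha), lambdas, np.zeros(X.shape[1]), b0, max_outer, tol, dev_stop
    )
    return LogisticNetPath(lambdas=lambdas, coefs=B, intercepts=b0s, alpha=float(alpha))


def fit_logistic_net(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    warm: tuple[np.ndarray, float] | None = None,
    max_outer: int = 50,
    tol: float = 1e-12,
) -> tuple[np.ndarray, float]:
    # fixed-penalty fit: no deviance-based path stopping
    """Single fixed-penalty fit; optional warm start ``(beta, b0)``."""
    y = _as01(y)
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    if warm is None:
        beta0 = np.zeros(X.shape[1])
        ybar = float(np.clip(y.mean(), _PMIN, 1 - _PMIN))
        b0 = float(np.log(ybar / (1 - ybar)))
    else:
        beta0, b0 = np.asarray(warm[0], dtype=float).copy(), float(warm[1])
    B, b0s = _cd_path(
        X, y, float(alpha), np.array([float(lam)]), beta0, b0, max_outer, tol, False
    )
    return B[0], float(b0s[0])


def predict_proba(X: np.ndarray, beta: np.ndarray, b0: float) -> np.ndarray:
    eta = X @ beta + b0
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))


def binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    """Mean binomial deviance (-2 * mean log-likelihood)."""
    y = np.asarray(y, dtype=float)
    p = np.clip(p, _PMIN, 1 - _PMIN)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def cv_lambda_min(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    alpha: float = 0.95,
    lambdas: np.ndarray | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-2,
) -> CVResult:
    """Grouped cross-validation of the penalty: one fold per group.

    All trials sharing a group id (all repetitions of one video) are held
    out together.  Returns the penalty minimizing the mean held-out
    binomial deviance across folds.
    """
    y = _as01(y)
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    groups = np.asarray(groups)
    if lambdas is None:
        lambdas = lambda_grid(X, y, alpha, n_lambda, lambda_min_ratio)
    lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1].copy()
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("grouped CV needs at least 2 groups")
    dev = np.zeros((uniq.size, lambdas.size))
    for k, g in enumerate(uniq):
        test = groups == g
        train = ~test
        yt = y[train]
        if np.unique(yt).size < 2:
            # degenerate fold: held-out deviance from the base-rate model
            pb = float(np.clip(yt.mean(), _PMIN, 1 - _PMIN))
            dev[k] = binomial_deviance(y[test], np.full(test.sum(), pb))
            continue
        path = logistic_net_path(X[train], yt, alpha, lambdas=lambdas)
        for il in range(lambdas.size):
            p = predict_proba(X[test], path.coefs[il], path.intercepts[il])
            dev[k, il] = binomial_deviance(y[test], p)
    mean_dev = dev.mean(axis=0)
    lam_min = float(lambdas[int(np.argmin(mean_dev))])
    return CVResult(
        lambda_min=lam_min,
        lambdas=lambdas,
        mean_deviance=mean_dev,
        alpha=float(alpha),
        n_folds=int(uniq.size),
    )
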