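"""L1-penalized least squares by cyclic coordinate descent.

Solves, on a standardized design (columns mean 0 / SD 1, response
centered),

    min_beta  (1/(2n)) * ||y - X beta||^2  +  lambda * ||beta||_1

which is the convention under which the smallest penalty producing the
all-zero solution is ``lambda_max = max_j |x_j' y| / n``. Coefficients
are back-transformed to the original measurement units after fitting, so
reported coefficients are unstandardized.

The inner loop runs in covariance-update (Gram) form — each coordinate
update costs O(p) after a one-off O(n p^2) Gram computation — and is
JIT-compiled with numba. A pure-Python reference sweep that asserts the
objective is non-increasing after every pass is available via
``fit_lasso(..., debug=True)``.

Penalty selection uses k-fold cross-validation on a log-spaced path and
returns ``lambda_min``, the grid value minimizing mean validation MSE
(largest such value on ties, i.e. the sparser model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "soft_threshold",
    "StandardizedDesign",
    "standardize",
    "LassoFit",
    "fit_lasso",
    "lambda_max",
    "lambda_path",
    "fit_path",
    "CvResult",
    "cv_lasso",
    "complete_cases",
    "PathError",
]

logger = logging.getLogger("screenlasso")


class PathError(ValueError):
    """Raised when a regularization path cannot be constructed."""


def soft_threshold(z: float, gamma: float) -> float:
    """Soft-thresholding operator ``sign(z) * max(|z| - gamma, 0)``."""
    if gamma < 0:
        raise ValueError("soft-threshold parameter must be non-negative")
    return float(np.sign(z) * max(abs(z) - gamma, 0.0))


@dataclass
class StandardizedDesign:
    """Design matrix standardized column-wise, with back-transform info.

    Zero-variance columns are dropped before standardization and listed
    in ``dropped``; ``names`` covers the retained columns only.
    """

    X_std: np.ndarray
    y_centered: np.ndarray
    col_means: np.ndarray
    col_sds: np.ndarray
    y_mean: float
    names: list[str]
    dropped: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.X_std.shape[0]

    @property
    def p(self) -> int:
        return self.X_std.shape[1]


def standardize(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    names: Optional[Sequence[str]] = None,
) -> StandardizedDesign:
    """Center/scale columns to mean 0, SD 1 (population SD) and center y."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per element of y")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("standardize requires complete data; filter rows first")
    means = X.mean(axis=0)
    sds = X.std(axis=0)  # population SD; ddof=0
    keep = sds > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        logger.debug("standardize: dropping zero-variance column(s) %s", dropped)
    X_std = (X[:, keep] - means[keep]) / sds[keep]
    y_mean = float(y.mean())
    return StandardizedDesign(
        X_std=X_std,
        y_centered=y - y_mean,
        col_means=means[keep],
        col_sds=sds[keep],
        y_mean=y_mean,
        names=[n for n, k in zip(names, keep) if k],
        dropped=dropped,
    )


@dataclass
class LassoFit:
    """A LASSO solution at one penalty, on both coefficient scales."""

    lam: float
    beta_std: np.ndarray
    beta_raw: np.ndarray
    intercept_raw: float
    n_iter: int
    converged: bool
    names: list[str]

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.names].to_numpy(dtype=float)
        return self.intercept_raw + np.asarray(X, dtype=float) @ self.beta_raw

    def active_set(self) -> list[str]:
        return [n for n, b in zip(self.names, self.beta_raw) if b != 0.0]


@njit(cache=True)
def _cd_gram(G, c, beta, lam, tol, max_iter):  # pragma: no cover - jitted
    """Cyclic coordinate descent on (1/2) b'Gb - c'b + lam*||b||_1."""
    p = c.shape[0]
    it = 0
    for it in range(1, max_iter + 1):
        max_delta = 0.0
        for j in range(p):
            old = beta[j]
            rho = c[j] + G[j, j] * old
            for k in range(p):
                rho -= G[j, k] * beta[k]
            if rho > lam:
                new = (rho - lam) / G[j, j]
            elif rho < -lam:
                new = (rho + lam) / G[j, j]
            else:
                new = 0.0
            beta[j] = new
            d = abs(new - old)
            if d > max_delta:
                max_delta = d
        if max_delta < tol:
            return it, True
    return it, False


@njit(cache=True)
def _cd_path(G, c, lambdas, tol, max_iter):  # pragma: no cover - jitted
    """Warm-started coordinate descent along a decreasing lambda grid."""
    n_lam = lambdas.shape[0]
    p = c.shape[0]
    coefs = np.zeros((n_lam, p))
    beta = np.zeros(p)
    ok = True
    for i in range(n_lam):
        _, conv = _cd_gram(G, c, beta, lambdas[i], tol, max_iter)
        ok = ok and conv
        coefs[i] = beta
    return coefs, ok


def _objective(design: StandardizedDesign, beta: np.ndarray, lam: float) -> float:
    r = design.y_centered - design.X_std @ beta
    n = design.n
    return float(r @ r / (2 * n) + lam * np.abs(beta).sum())


def _cd_python(design: StandardizedDesign, beta: np.ndarray, lam: float,
               tol: float, max_iter: int) -> tuple[int, bool]:
    """Reference residual-update sweep; asserts objective monotonicity."""
    X, y = design.X_std, design.y_centered
    n, p = X.shape
    r = y - X @ beta
    obj = _objective(design, beta, lam)
    for it in range(1, max_iter + 1):
        max_delta = 0.0
        for j in range(p):
            old = beta[j]
            rho = X[:, j] @ r / n + old  # column SD is 1 so G_jj = 1
            new = soft_threshold(rho, lam)
            if new != old:
                r -= X[:, j] * (new - old)
                beta[j] = new
            max_delta = max(max_delta, abs(new - old))
        new_obj = _objective(design, beta, lam)
        assert new_obj <= obj + 1e-12, "coordinate descent objective increased"
        obj = new_obj
        if max_delta < tol:
            return it, True
    return max_iter, False


def _back_transform(design: StandardizedDesign, beta_std: np.ndarray):
    beta_raw = beta_std / design.col_sds
    intercept = design.y_mean - float(design.col_means @ beta_raw)
    return beta_raw, intercept


def fit_lasso(
    design: StandardizedDesign,
    lam: float,
    tol: float = 1e-7,
    max_iter: int = 10_000,
    warm_start: Optional[np.ndarray] = None,
    debug: bool = False,
) -> LassoFit:
    """Fit the LASSO at one penalty value on a standardized design.

    Convergence is declared when the largest coefficient update in a
    sweep falls below ``tol``. Non-convergence returns the current
    iterate with ``converged=False`` and a logged warning.
    """
    if lam < 0:
        raise ValueError("penalty must be non-negative")
    beta = np.zeros(design.p) if warm_start is None else np.array(warm_start, dtype=float)
    if debug:
        n_iter, converged = _cd_python(design, beta, lam, tol, max_iter)
    else:
        n = design.n
        G = design.X_std.T @ design.X_std / n
        c = design.X_std.T @ design.y_centered / n
        n_iter, converged = _cd_gram(G, c, beta, lam, tol, max_iter)
    if not converged:
        logger.warning("fit_lasso: not converged after %d sweeps (lambda=%g)", n_iter, lam)
    beta_raw, intercept = _back_transform(design, beta)
    return LassoFit(
        lam=float(lam),
        beta_std=beta,
        beta_raw=beta_raw,
        intercept_raw=intercept,
        n_iter=n_iter,
        converged=converged,
        names=list(design.names),
    )


def lambda_max(design: StandardizedDesign) -> float:
    """Smallest penalty at which the solution is identically zero."""
    return float(np.abs(design.X_std.T @ design.y_centered).max() / design.n)


def lambda_path(
    design: StandardizedDesign, n_lambda: int = 100, ratio: float = 1e-3
) -> np.ndarray:
    """Log-spaced decreasing grid from lambda_max to ratio*lambda_max."""
    if n_lambda < 2:
        raise ValueError("n_lambda must be at least 2")
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    lmax = lambda_max(design)
    if lmax <= 0:
        raise PathError("degenerate response: constant y gives lambda_max = 0")
    return np.logspace(np.log10(lmax), np.log10(ratio * lmax), n_lambda)


def fit_path(
    design: StandardizedDesign,
    lambdas: np.ndarray,
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Standardized coefficients along a decreasing grid (warm-started).

    Returns an (n_lambda, p) array of standardized-scale coefficients.
    """
    n = design.n
    G = design.X_std.T @ design.X_std / n
    c = design.X_std.T @ design.y_centered / n
    coefs, ok = _cd_path(G, c, np.asarray(lambdas, dtype=float), tol, max_iter)
    if not ok:
        logger.warning("fit_path: at least one grid point did not converge")
    return coefs


@dataclass
class CvResult:
    """k-fold cross-validation curve over a lambda grid."""

    lambda_grid: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    fold_assignment: np.ndarray
    k: int


def complete_cases(data: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    """Rows of ``data`` with no missing value among ``cols``."""
    return data.loc[data[list(cols)].notna().all(axis=1), list(cols)]


def cv_lasso(
    data: pd.DataFrame,
    outcome: str,
    predictors: Optional[Sequence[str]] = None,
    k: int = 10,
    n_lambda: int = 100,
    ratio: float = 1e-3,
    seed: int | np.random.SeedSequence = 0,
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> CvResult:
    """Select the LASSO penalty by k-fold cross-validation.

    Complete cases on ``outcome`` + ``predictors`` are used. Folds are
    assigned by a seeded shuffle with sizes differing by at most one;
    within each fold the training split is standardized on its own and
    the warm-started path is fitted on the shared grid (computed from
    the full sample). ``lambda_min`` minimizes mean validation MSE;
    ties go to the largest lambda (sparser model). Deterministic for a
    fixed seed.
    """
    if predictors is None:
        predictors = [c for c in data.columns if c != outcome]
    sub = complete_cases(data, [outcome, *predictors])
    n = len(sub)
    if n < k:
        raise ValueError(f"need at least k={k} complete cases, got {n}")
    y = sub[outcome].to_numpy(dtype=float)
    X = sub[list(predictors)].to_numpy(dtype=float)

    full = standardize(X, y, names=predictors)
    grid = lambda_path(full, n_lambda=n_lambda, ratio=ratio)

    rng = np.random.default_rng(seed)
    folds = np.resize(np.arange(k), n)
    rng.shuffle(folds)

    fold_mse = np.empty((k, len(grid)))
    for f in range(k):
        train, val = folds != f, folds == f
        des = standardize(X[train], y[train], names=predictors)
        coefs = fit_path(des, grid, tol=tol, max_iter=max_iter)
        # back-transform whole path, predict on raw validation block
        beta_raw = coefs / des.col_sds  # (n_lambda, p_kept)
        inter = y[train].mean() - beta_raw @ des.col_means
        kept = [list(predictors).index(nm) for nm in des.names]
        pred = X[np.ix_(val, kept)] @ beta_raw.T + inter  # (n_val, n_lambda)
        if y[val].std() == 0:
            logger.warning("cv_lasso: fold %d has zero-variance outcome", f)
        fold_mse[f] = ((y[val][:, None] - pred) ** 2).mean(axis=0)

    cv_mean = fold_mse.mean(axis=0)
    cv_se = fold_mse.std(axis=0, ddof=1) / np.sqrt(k)
    best = int(np.argmin(cv_mean))  # grid decreasing -> first min = largest lambda
    return CvResult(
        lambda_grid=grid,
        cv_mean=cv_mean,
        cv_se=cv_se,
        lambda_min=float(grid[best]),
        fold_assignment=folds,
        k=k,
    )
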