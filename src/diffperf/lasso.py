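"""Least-squares lasso: single fits, regularization path, CV lambda choice.

This is the feature-selection engine: the L1-penalized linear
regression of the 0/1 diagnosis label on the imaging features.
Predictors are standardized internally using only the rows of the fit
at hand (no leakage across CV folds); coefficients are reported back on
the input scale. The penalized objective, on the standardized scale, is

    (1/2n) * ||y - b0 - X b||^2 + lambda * ||b||_1,

minimized by cyclic coordinate descent with warm starts along a
geometric lambda grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from ._solvers import lasso_cd_gram, lasso_path_gram

__all__ = [
    "LassoConfig",
    "LassoFit",
    "LassoError",
    "lambda_max",
    "lasso_fit",
    "lambda_grid",
    "cv_select_lambda",
]

#: coefficients with |b| below this (input scale, after back-transform)
#: are treated as exact zeros for support purposes
SUPPORT_EPS = 1e-12


class LassoError(RuntimeError):
    """Numerical failure inside the lasso solver."""


@dataclass
class LassoConfig:
    """Knobs for the lasso path and its cross-validated lambda choice."""

    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    tol: float = 1e-7
    max_iter: int = 100_000
    cv_folds: int = 10
    #: '1se' (default): largest lambda within one SE of the CV minimum;
    #: 'min': the CV minimizer (saturates the support at n < p)
    selection_rule: Literal["min", "1se"] = "1se"
    #: stop the path once training R^2 reaches this (saturated fit);
    #: smaller lambdas inherit the saturated solution
    path_dev_stop: float = 0.999
    #: tolerance for the CV path fits only -- these are used to rank
    #: lambdas by prediction MSE, where coefficient precision far below
    #: the CV noise floor buys nothing; final fits use ``tol``
    cv_tol: float = 1e-4

    def __post_init__(self) -> None:
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class LassoFit:
    """One lasso solution: input-scale coefficients and support."""

    lam: float
    coefficients: np.ndarray
    intercept: float
    selected_support: frozenset[int] = field(init=False)

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        coef[np.abs(coef) < SUPPORT_EPS] = 0.0
        self.coefficients = coef
        self.selected_support = frozenset(np.flatnonzero(coef).tolist())

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, float) @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "lambda": self.lam,
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "support": sorted(self.selected_support),
        }


def _standardize(X: np.ndarray):
    """Column means/SDs (population) and the standardized matrix.

    Zero-variance columns get SD = inf so their standardized values are
    0: they can never enter the model, which realizes the 'drop
    constant columns' contract without reindexing.
    """
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    safe = np.where(sd > 0, sd, np.inf)
    return mean, sd, (X - mean) / safe


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest lambda with an all-zero solution: max_j |<x_j, y>| / n.

    Expects standardized columns and centered y; raises on a
    zero-variance column (drop those upstream).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = X.shape[0]
    if np.any(X.std(axis=0) == 0):
        raise LassoError("zero-variance column passed to lambda_max")
    return float(np.abs(X.T @ y).max() / n)


def lambda_grid(lam_max: float, config: LassoConfig) -> np.ndarray:
    """Descending geometric grid from lam_max to lam_max*lambda_min_ratio."""
    if config.n_lambda == 1:
        return np.array([lam_max])
    return lam_max * np.logspace(
        0.0, np.log10(config.lambda_min_ratio), config.n_lambda
    )


def lasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    config: LassoConfig | None = None,
) -> LassoFit:
    """Solve one lasso problem at penalty ``lam``.

    X is raw (unstandardized); standardization happens inside on these
    rows only and coefficients come back on the input scale. y is the
    0/1 label treated as a real response.
    """
    config = config or LassoConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if n < 2:
        raise LassoError("need at least 2 rows")
    mean, sd, Xs = _standardize(X)
    if np.all(sd == 0):
        raise LassoError("all columns constant")
    ybar = y.mean()
    yc = y - ybar
    G = (Xs.T @ Xs) / n
    c = (Xs.T @ yc) / n
    beta = np.zeros(p)
    status = lasso_cd_gram(G, c, lam, beta, config.tol, config.max_iter)
    if status < 0:
        raise LassoError(
            f"lasso did not converge at lambda={lam:g} "
            f"within {config.max_iter} iterations"
        )
    coef = np.where(sd > 0, beta / np.where(sd > 0, sd, 1.0), 0.0)
    intercept = float(ybar - mean @ coef)
    return LassoFit(lam=lam, coefficients=coef, intercept=intercept)


def _kfold_indices(n: int, k: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    return np.array_split(perm, k)


def cv_select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    config: LassoConfig | None = None,
    seed: int = 0,
) -> tuple[float, dict]:
    """Choose lambda on a geometric path by k-fold CV of prediction MSE.

    The grid runs from the full-data lambda_max down by
    ``lambda_min_ratio``; each fold refits the whole path (warm starts)
    with fold-internal standardization. Rule 'min' takes the MSE
    minimizer, ties broken toward the larger (sparser) lambda; '1se'
    takes the largest lambda within one standard error of the minimum.
    Returns (lambda_star, path summary dict).
    """
    config = config or LassoConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    k = config.cv_folds
    if n < 2 * k:
        raise LassoError(f"need n >= 2*cv_folds ({2 * k}), got {n}")
    if np.all(y == y[0]):
        raise LassoError("constant response")

    mean, sd, Xs = _standardize(X)
    keep = sd > 0
    lam_max = float(np.abs(Xs[:, keep].T @ (y - y.mean())).max() / n)
    if lam_max == 0:
        raise LassoError("response orthogonal to all predictors")
    lams = lambda_grid(lam_max, config)

    rng = np.random.default_rng(seed)
    folds = _kfold_indices(n, k, rng)
    sq_err = np.zeros((n, len(lams)))  # per-subject squared error per lambda
    fold_mse = np.zeros((k, len(lams)))
    for fi, val_idx in enumerate(folds):
        tr_mask = np.ones(n, dtype=bool)
        tr_mask[val_idx] = False
        Xtr, ytr = X[tr_mask], y[tr_mask]
        m_tr, s_tr, Xtr_s = _standardize(Xtr)
        safe = np.where(s_tr > 0, s_tr, np.inf)
        ntr = Xtr.shape[0]
        G = (Xtr_s.T @ Xtr_s) / ntr
        c = (Xtr_s.T @ (ytr - ytr.mean())) / ntr
        ymss = float(((ytr - ytr.mean()) ** 2).mean())
        betas, status = lasso_path_gram(
            G, c, lams, config.cv_tol, config.max_iter,
            ymss, config.path_dev_stop, ntr,
        )
        if (status < 0).any():
            bad = lams[np.flatnonzero(status < 0)[0]]
            raise LassoError(f"CV path did not converge at lambda={bad:g}")
        Xv_s = (X[val_idx] - m_tr) / safe
        preds = ytr.mean() + Xv_s @ betas.T  # (n_val, n_lambda)
        sq_err[val_idx] = (y[val_idx, None] - preds) ** 2
        fold_mse[fi] = sq_err[val_idx].mean(axis=0)

    mse = sq_err.mean(axis=0)
    # SE of the CV curve: SD of the fold-mean errors across folds
    se = fold_mse.std(axis=0, ddof=1) / np.sqrt(k)
    if config.selection_rule == "min":
        best = int(np.argmin(mse))  # first index = largest lambda on ties
    else:
        i_min = int(np.argmin(mse))
        within = np.flatnonzero(mse <= mse[i_min] + se[i_min])
        best = int(within[0])
    summary = {
        "lambdas": lams.tolist(),
        "cv_mse": mse.tolist(),
        "cv_se": se.tolist(),
        "lambda_star": float(lams[best]),
        "rule": config.selection_rule,
        "seed": seed,
    }
    return float(lams[best]), summary
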