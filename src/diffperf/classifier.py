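"""Sparse logistic regression, LOOCV orchestration, consensus features.

The classifier is an L1-penalized logistic regression on a reduced
feature set: probability of the case class is 1 / (1 + exp(-w'z^)) with
z^ the standardized feature vector augmented by a constant 1 and w the
weight vector (its last entry the unpenalized intercept).  Leave-one-
out cross-validation trains one model per subject on all others,
restricted to the reduced feature set of that subject's testing pool;
features carrying nonzero weight in at least 75% of the LOOCV models
form the consensus (discriminative) set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._solvers import logistic_l1_irls
from .schema import Cohort
from .selection import ReducedFeatureSets, stratified_kfold

__all__ = [
    "ClassifierModel",
    "LoocvResult",
    "ConsensusSet",
    "ClassifierError",
    "SparseLogisticConfig",
    "fit_sparse_logistic",
    "predict_prob",
    "cv_select_lambda_logit",
    "loocv_run",
    "consensus_features",
]

WEIGHT_EPS = 1e-12


class ClassifierError(RuntimeError):
    pass


@dataclass
class SparseLogisticConfig:
    """Penalty path and CV settings for the logistic stage."""

    n_lambda: int = 25
    lambda_min_ratio: float = 0.01
    tol: float = 1e-8
    max_iter: int = 200
    cv_folds: int = 10
    selection_rule: str = "1se"  # or "min"


@dataclass
class ClassifierModel:
    """Trained sparse logistic model over a named feature subset.

    ``weights`` has length k+1: one weight per feature (on the
    standardized scale) followed by the intercept; ``mean``/``sd`` are
    the training standardization parameters.
    """

    features: tuple[str, ...]
    weights: np.ndarray
    lambda_logit: float
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.features) + 1:
            raise ClassifierError("weight vector must have length k+1")

    @property
    def nonzero_features(self) -> frozenset[str]:
        w = np.asarray(self.weights[:-1])
        return frozenset(
            f for f, wi in zip(self.features, w) if abs(wi) > WEIGHT_EPS
        )

    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "weights": np.asarray(self.weights).tolist(),
            "lambda_logit": self.lambda_logit,
            "mean": np.asarray(self.mean).tolist(),
            "sd": np.asarray(self.sd).tolist(),
        }


def predict_prob(model: ClassifierModel, features: np.ndarray) -> np.ndarray:
    """P(case | features) = 1 / (1 + exp(-w' z^)).

    ``features`` is one vector of length k or a matrix (n, k) on the
    raw scale; the model's training standardization is applied first.
    """
    x = np.asarray(features, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != len(model.features):
        raise ClassifierError(
            f"expected {len(model.features)} features, got {x.shape[1]}"
        )
    safe = np.where(model.sd > 0, model.sd, 1.0)
    z = (x - model.mean) / safe
    eta = z @ model.weights[:-1] + model.weights[-1]
    prob = 1.0 / (1.0 + np.exp(-eta))
    return float(prob[0]) if single else prob


def fit_sparse_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lambda_logit: float,
    features: Sequence[str] | None = None,
    config: SparseLogisticConfig | None = None,
) -> ClassifierModel:
    """Fit the L1-penalized logistic regression (intercept unpenalized).

    Minimizes -(1/n) loglik + lambda_logit * ||w_features||_1 by
    coordinate descent inside IRLS, on internally standardized
    features. Raises on non-convergence; at lambda_logit = 0 that
    typically signals perfect separation.
    """
    config = config or SparseLogisticConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ClassifierError("X/y shape mismatch")
    if y.min() == y.max():
        raise ClassifierError("both classes must be present")
    if X.shape[1] == 0:
        raise ClassifierError("reduced feature set is empty")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / safe
    Z[:, sd == 0] = 0.0
    b0, beta, ok = logistic_l1_irls(
        Z, y, lambda_logit, config.tol, config.max_iter
    )
    if not ok:
        raise ClassifierError(
            f"IRLS did not converge at lambda_logit={lambda_logit:g}; "
            "data may be separable -- use lambda_logit > 0"
        )
    names = tuple(features) if features is not None else tuple(
        f"x{j}" for j in range(X.shape[1])
    )
    return ClassifierModel(
        features=names,
        weights=np.r_[beta, b0],
        lambda_logit=lambda_logit,
        mean=mean,
        sd=sd,
    )


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def cv_select_lambda_logit(
    cohort: Cohort,
    feature_cols: Sequence[str],
    config: SparseLogisticConfig | None = None,
    seed: int = 0,
) -> float:
    """Choose the logistic penalty by stratified k-fold CV deviance.

    The grid descends geometrically from the smallest penalty that
    zeroes every feature weight; ties break toward the larger (sparser)
    penalty.
    """
    config = config or SparseLogisticConfig()
    X = cohort.table[list(feature_cols)].to_numpy(dtype=float)
    y = cohort.diagnosis.astype(float)
    sd = X.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    Z = (X - X.mean(axis=0)) / safe
    Z[:, sd == 0] = 0.0
    n = len(y)
    lam_max = float(np.abs(Z.T @ (y - y.mean())).max() / n)
    if lam_max == 0:
        return 1.0
    lams = lam_max * np.logspace(
        0, np.log10(config.lambda_min_ratio), config.n_lambda
    )
    folds = stratified_kfold(cohort.subjects, config.cv_folds, seed)
    ids = cohort.subject_ids
    # per-fold mean deviance per lambda (rows: folds)
    dev = np.full((config.cv_folds, len(lams)), np.nan)
    for fold in range(config.cv_folds):
        held = set(folds.members(fold))
        mask = np.array([sid in held for sid in ids])
        ytr = y[~mask]
        if ytr.min() == ytr.max():  # degenerate fold: skip
            continue
        for i, lam in enumerate(lams):
            try:
                model = fit_sparse_logistic(
                    X[~mask], ytr, lam, feature_cols, config
                )
            except ClassifierError:
                dev[fold, i] = np.inf
                continue
            dev[fold, i] = _deviance(
                y[mask], predict_prob(model, X[mask])
            ) / mask.sum()
    used = ~np.isnan(dev).all(axis=1)
    mean = np.nanmean(dev[used], axis=0)
    best = int(np.argmin(mean))  # first index = largest lambda on ties
    if config.selection_rule == "1se":
        se = np.nanstd(dev[used], axis=0, ddof=1) / np.sqrt(used.sum())
        within = np.flatnonzero(mean <= mean[best] + se[best])
        best = int(within[0])
    return float(lams[best])


@dataclass
class LoocvResult:
    """Per-subject LOOCV predictions plus provenance."""

    subject_ids: list[str]
    true_labels: np.ndarray
    probabilities: np.ndarray
    predicted_labels: np.ndarray
    fold_features: list[frozenset[str]]  # nonzero-weight set per model
    reduced: ReducedFeatureSets
    pool_lambdas: dict[int, float]
    seed: int

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "pool_lambdas": {str(k): v for k, v in self.pool_lambdas.items()},
            "subjects": [
                {
                    "subject_id": sid,
                    "true": int(t),
                    "probability": float(p),
                    "predicted": int(l),
                    "nonzero_features": sorted(fs),
                }
                for sid, t, p, l, fs in zip(
                    self.subject_ids,
                    self.true_labels,
                    self.probabilities,
                    self.predicted_labels,
                    self.fold_features,
                )
            ],
        }


def loocv_run(
    cohort: Cohort,
    reduced: ReducedFeatureSets,
    config: SparseLogisticConfig | None = None,
    seed: int = 0,
) -> LoocvResult:
    """Leave-one-out CV with pool-shared reduced features.

    For each subject: the reduced feature set of its testing pool is
    used, the penalty is the one chosen once per pool by CV on the
    subjects outside the pool, and the model is trained on all other
    subjects. A pool with an empty reduced set predicts the training
    base rate for its members (with a warning).
    """
    config = config or SparseLogisticConfig()
    ids = cohort.subject_ids
    covered = set().union(*(p.pool for p in reduced.pools))
    if set(ids) - covered:
        raise ClassifierError("reduced sets do not cover the cohort")
    y = cohort.diagnosis.astype(float)
    probs = np.full(len(ids), np.nan)
    fold_feats: list[frozenset[str]] = [frozenset()] * len(ids)
    pool_lambdas: dict[int, float] = {}

    for pi, pool in enumerate(reduced.pools):
        members = [sid for sid in ids if sid in pool.pool]
        if not members:
            continue
        cols = sorted(pool.features)
        outside_ids = [sid for sid in ids if sid not in pool.pool]
        if not cols:
            warnings.warn(
                f"pool {pi}: empty reduced feature set; predicting the "
                "training base rate for its members"
            )
            pool_lambdas[pi] = np.nan
            for sid in members:
                i = ids.index(sid)
                others = [s for s in ids if s != sid]
                base = y[[ids.index(s) for s in others]].mean()
                probs[i] = base
                fold_feats[i] = frozenset()
            continue
        pool_seed = int(
            np.random.SeedSequence([seed, 11, pi]).generate_state(1)[0]
            % 2**31
        )
        lam = cv_select_lambda_logit(
            cohort.subset(outside_ids), cols, config, seed=pool_seed
        )
        pool_lambdas[pi] = lam
        for sid in members:
            i = ids.index(sid)
            train_ids = [s for s in ids if s != sid]
            sub = cohort.subset(train_ids)
            model = fit_sparse_logistic(
                sub.table[cols].to_numpy(dtype=float),
                sub.diagnosis.astype(float),
                lam,
                cols,
                config,
            )
            probs[i] = predict_prob(
                model, cohort.table.loc[sid, cols].to_numpy(dtype=float)
            )
            fold_feats[i] = model.nonzero_features

    return LoocvResult(
        subject_ids=list(ids),
        true_labels=cohort.diagnosis,
        probabilities=probs,
        predicted_labels=(probs >= 0.5).astype(int),
        fold_features=fold_feats,
        reduced=reduced,
        pool_lambdas=pool_lambdas,
        seed=seed,
    )


@dataclass
class ConsensusSet:
    """Per-feature LOOCV selection frequencies and the threshold verdict."""

    frequencies: dict[str, float]
    threshold: float
    features: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ClassifierError("threshold must be in (0, 1]")
        self.features = frozenset(
            f for f, q in self.frequencies.items() if q >= self.threshold
        )


def consensus_features(
    result: LoocvResult,
    threshold: float = 0.75,
    count: str = "model_weights",
) -> ConsensusSet:
    """Features selected in at least ``threshold`` of the LOOCV folds.

    ``count='model_weights'`` (default) counts a feature in a fold when
    the fold's classifier gives it nonzero weight; ``'reduced_sets'``
    counts membership in the fold's pool-shared reduced set instead.
    The threshold comparison is inclusive.
    """
    n = len(result.subject_ids)
    freq: dict[str, float] = {}
    if count == "model_weights":
        for fs in result.fold_features:
            for f in fs:
                freq[f] = freq.get(f, 0.0) + 1.0
    elif count == "reduced_sets":
        for sid in result.subject_ids:
            for f in result.reduced.pool_of(sid).features:
                freq[f] = freq.get(f, 0.0) + 1.0
    else:
        raise ClassifierError(f"unknown counting rule {count!r}")
    freq = {f: c / n for f, c in freq.items()}
    cs = ConsensusSet(frequencies=freq, threshold=threshold)
    if not cs.features:
        warnings.warn("no feature reaches the consensus threshold")
    return cs
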