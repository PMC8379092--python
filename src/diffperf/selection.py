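"""Nested 10 x 10 lasso feature selection.

The cohort is split into 10 outer folds, stratified on (diagnosis,
sex).  Each outer fold becomes a *testing pool*: its reduced feature
set is computed from the other nine folds only, by splitting those
subjects into 10 stratified inner folds, fitting a cross-validated
lasso on each inner fold's training portion, and taking the union of
the ten supports.  Leave-one-out classification later reuses one
reduced set for every subject of its pool, so no subject ever
influences the feature set it is evaluated with.

All randomness is keyed to sorted subject ids plus an integer seed, so
file row order cannot change any output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .lasso import LassoConfig, cv_select_lambda, lasso_fit
from .schema import Cohort, SubjectRecord

__all__ = [
    "FoldAssignment",
    "ReducedFeatureSets",
    "SelectionError",
    "stratified_kfold",
    "inner_union_selection",
    "nested_fs",
]


class SelectionError(ValueError):
    pass


@dataclass
class FoldAssignment:
    """Map subject_id -> fold index for a stratified k-fold split."""

    n_folds: int
    assignment: dict[str, int]

    def members(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignment.items() if f == fold)

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.n_folds
        for f in self.assignment.values():
            sizes[f] += 1
        return sizes


@dataclass
class PoolSelection:
    """One outer fold: its testing pool and the shared reduced set."""

    pool: frozenset[str]
    features: frozenset[str]  # feature column names
    inner_lambdas: tuple[float, ...]
    inner_support_sizes: tuple[int, ...]


@dataclass
class ReducedFeatureSets:
    """Per-outer-fold reduced feature sets; pools partition the cohort."""

    pools: list[PoolSelection]
    seed: int

    def pool_of(self, subject_id: str) -> PoolSelection:
        for p in self.pools:
            if subject_id in p.pool:
                return p
        raise KeyError(subject_id)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "pools": [
                    {
                        "pool": sorted(p.pool),
                        "features": sorted(p.features),
                        "inner_lambdas": list(p.inner_lambdas),
                        "inner_support_sizes": list(p.inner_support_sizes),
                    }
                    for p in self.pools
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ReducedFeatureSets":
        d = json.loads(text)
        pools = [
            PoolSelection(
                pool=frozenset(p["pool"]),
                features=frozenset(p["features"]),
                inner_lambdas=tuple(p["inner_lambdas"]),
                inner_support_sizes=tuple(p["inner_support_sizes"]),
            )
            for p in d["pools"]
        ]
        return cls(pools=pools, seed=d["seed"])


def stratified_kfold(
    subjects: Sequence[SubjectRecord], k: int, seed: int
) -> FoldAssignment:
    """Deterministic stratified k-fold split on (diagnosis, sex).

    Fold sizes differ by at most one overall and within every stratum.
    Members of each stratum are shuffled (seeded per stratum) and dealt
    to the currently smallest folds, so strata smaller than k land in
    distinct folds.
    """
    if k < 2:
        raise SelectionError("k must be >= 2")
    if k > len(subjects):
        raise SelectionError(f"k={k} exceeds cohort size {len(subjects)}")
    strata: dict[tuple[int, int], list[str]] = {}
    for s in sorted(subjects, key=lambda s: s.subject_id):
        strata.setdefault((s.diagnosis, s.sex), []).append(s.subject_id)

    sizes = np.zeros(k, dtype=int)
    assignment: dict[str, int] = {}
    for key in sorted(strata):
        members = list(strata[key])
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, key[0], key[1]])
        )
        rng.shuffle(members)
        # deal to the smallest folds first (stable order on ties)
        order = np.argsort(sizes, kind="stable")
        for i, sid in enumerate(members):
            fold = int(order[i % k])
            assignment[sid] = fold
            sizes[fold] += 1
            if (i + 1) % k == 0:
                order = np.argsort(sizes, kind="stable")
    return FoldAssignment(n_folds=k, assignment=assignment)


def _design(cohort: Cohort):
    X = cohort.values()
    y = cohort.diagnosis.astype(float)
    return X, y


def inner_union_selection(
    cohort: Cohort,
    config: LassoConfig | None = None,
    seed: int = 0,
    n_inner: int = 10,
) -> tuple[frozenset[str], list[float], list[int]]:
    """Union of the supports of ``n_inner`` cross-validated lasso fits.

    The subset is split into ``n_inner`` stratified folds; for each
    fold, a lasso with internally CV-chosen lambda is fit on the other
    folds and its support recorded. Returns (union of supports as
    feature column names, per-fold lambda, per-fold support size). An
    inner fit that selects nothing contributes the empty set.
    """
    config = config or LassoConfig()
    y = cohort.diagnosis
    if y.min() == y.max():
        raise SelectionError("subset must contain both classes")
    folds = stratified_kfold(cohort.subjects, n_inner, seed)
    columns = [f.column for f in cohort.feature_index]
    union: set[str] = set()
    lambdas: list[float] = []
    sizes: list[int] = []
    for fold in range(n_inner):
        held = set(folds.members(fold))
        train_ids = [s for s in cohort.subject_ids if s not in held]
        sub = cohort.subset(train_ids)
        ytr = sub.diagnosis
        if ytr.min() == ytr.max():
            raise SelectionError(
                f"inner fold {fold}: training portion has a single class"
            )
        Xtr, ytr = _design(sub)
        lam, _ = cv_select_lambda(
            Xtr, ytr, config, seed=int(np.random.SeedSequence([seed, fold, 1])
                                       .generate_state(1)[0] % 2**31)
        )
        fit = lasso_fit(Xtr, ytr, lam, config)
        union.update(columns[j] for j in fit.selected_support)
        lambdas.append(lam)
        sizes.append(len(fit.selected_support))
    return frozenset(union), lambdas, sizes


def nested_fs(
    cohort: Cohort,
    config: LassoConfig | None = None,
    seed: int = 0,
    n_outer: int = 10,
    n_inner: int = 10,
) -> ReducedFeatureSets:
    """The 10 x 10 nested selection: one reduced set per outer pool.

    Each pool's reduced set is the inner-union selection computed on
    the subjects *outside* the pool, so the leak-free property holds by
    construction.
    """
    y = cohort.diagnosis
    if y.min() == y.max():
        raise SelectionError("cohort must contain both classes")
    outer = stratified_kfold(cohort.subjects, n_outer, seed)
    pools: list[PoolSelection] = []
    for fold in range(n_outer):
        pool_ids = set(outer.members(fold))
        train_ids = [s for s in cohort.subject_ids if s not in pool_ids]
        sub = cohort.subset(train_ids)
        inner_seed = int(
            np.random.SeedSequence([seed, 7, fold]).generate_state(1)[0]
            % 2**31
        )
        features, lambdas, sizes = inner_union_selection(
            sub, config, seed=inner_seed, n_inner=n_inner
        )
        pools.append(
            PoolSelection(
                pool=frozenset(pool_ids),
                features=features,
                inner_lambdas=tuple(lambdas),
                inner_support_sizes=tuple(sizes),
            )
        )
    return ReducedFeatureSets(pools=pools, seed=seed)
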