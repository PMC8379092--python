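"""Covariate-adjusted association statistics and group-comparison tests.

Partial Pearson correlations between imaging features and cognitive
test scores, controlling sex/age/education, with Benjamini-Hochberg FDR
correction; plus the two-group comparisons used for demographic and
feature tables (normality-gated t-test / Wilcoxon rank-sum, chi-square
for sex).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .schema import Cohort
from .classifier import ConsensusSet

__all__ = [
    "AssociationRecord",
    "AssociationError",
    "partial_correlation",
    "bh_fdr",
    "group_compare",
    "chi_square_2x2",
    "association_table",
]

COVARIATE_NAMES = ("sex", "age", "education")


class AssociationError(ValueError):
    pass


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on the covariates plus an intercept
    by least squares; r is the Pearson correlation of the residuals and
    the two-sided p comes from t = r*sqrt(df/(1-r^2)) with
    df = n - 2 - n_covariates. With no covariates this is exactly the
    Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise AssociationError("length mismatch")
    if covariates is None:
        C = np.ones((n, 1))
        k = 0
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        if covariates.shape[0] != n:
            raise AssociationError("covariate shape mismatch")
        k = covariates.shape[1]
        C = np.c_[np.ones(n), covariates]
        if np.linalg.matrix_rank(C) < C.shape[1]:
            raise AssociationError("rank-deficient covariate matrix")
    df = n - 2 - k
    if df < 1:
        raise AssociationError(f"need n > covariates + 2, got n={n}, k={k}")
    rx = x - C @ np.linalg.lstsq(C, x, rcond=None)[0]
    ry = y - C @ np.linalg.lstsq(C, y, rcond=None)[0]
    sx, sy = np.sqrt(rx @ rx), np.sqrt(ry @ ry)
    if sx == 0 or sy == 0:
        raise AssociationError("zero residual variance")
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise AssociationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def group_compare(
    values: Sequence[float], labels: Sequence[int], alpha: float = 0.05
) -> tuple[str, float, float]:
    """Two-group comparison with a normality gate.

    Each group is checked with the Lilliefors variant of the
    Kolmogorov-Smirnov test (parameters estimated from the data) at
    ``alpha``; if both pass, Welch's t-test runs, otherwise the
    Wilcoxon rank-sum test (normal approximation, tie corrected).
    Returns (test name, statistic, p).
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=int)
    g1, g0 = v[lab == 1], v[lab == 0]
    if g1.size < 3 or g0.size < 3:
        raise AssociationError("both groups need >= 3 members")
    if np.ptp(g1) == 0 or np.ptp(g0) == 0:
        raise AssociationError("degenerate (constant) group")
    normal = True
    for g in (g1, g0):
        _, p_norm = lilliefors(g, dist="norm")
        if p_norm < alpha:
            normal = False
    if normal:
        stat, p = stats.ttest_ind(g1, g0, equal_var=False)
        return "welch-t", float(stat), float(p)
    res = stats.mannwhitneyu(g1, g0, alternative="two-sided",
                             method="asymptotic")
    return "wilcoxon-rank-sum", float(res.statistic), float(res.pvalue)


def chi_square_2x2(counts: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, 1 df, no Yates correction."""
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise AssociationError("need a non-negative 2x2 table")
    if t.sum() == 0:
        raise AssociationError("empty table")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise AssociationError("zero marginal")
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p)


@dataclass
class AssociationRecord:
    """One feature x cognitive-test partial correlation within a group."""

    feature: str
    test: str
    group: str  # "vMCI" or "control"
    r: float
    p_raw: float
    p_fdr: float
    n: int
    significant: bool

    def to_dict(self) -> dict:
        return {
            "feature": self.feature, "test": self.test, "group": self.group,
            "r": self.r, "p_raw": self.p_raw, "p_fdr": self.p_fdr,
            "n": self.n, "significant": self.significant,
        }


def association_table(
    cohort: Cohort,
    consensus: ConsensusSet | Sequence[str],
    tests: Sequence[str],
    group: str = "vMCI",
    fdr_family: str = "per_test",
    alpha: float = 0.05,
) -> list[AssociationRecord]:
    """Partial correlations of each consensus feature with each test.

    Computed within one diagnostic group, adjusting for sex, age, and
    education. BH correction is applied within each cognitive test
    across features (``fdr_family='per_test'``) or over the whole grid
    (``'table'``). Records with p_fdr < alpha are flagged significant.
    """
    features = sorted(
        consensus.features if isinstance(consensus, ConsensusSet)
        else consensus
    )
    if not features:
        raise AssociationError("empty consensus feature set")
    if group not in ("vMCI", "control"):
        raise AssociationError(f"unknown group {group!r}")
    want = 1 if group == "vMCI" else 0
    mask = cohort.diagnosis == want
    n = int(mask.sum())
    if n < 6:
        raise AssociationError(f"group {group} has too few subjects ({n})")
    cov = cohort.covariates()[mask]
    table = cohort.table[mask]
    records: list[AssociationRecord] = []
    for test in tests:
        scores = cohort.cognitive(test)[mask]
        for feat in features:
            x = table[feat].to_numpy(dtype=float)
            r, p = partial_correlation(x, scores, cov)
            records.append(AssociationRecord(
                feature=feat, test=test, group=group,
                r=r, p_raw=p, p_fdr=np.nan, n=n, significant=False,
            ))
    if fdr_family == "per_test":
        for test in tests:
            idx = [i for i, rec in enumerate(records) if rec.test == test]
            adj = bh_fdr([records[i].p_raw for i in idx])
            for i, q in zip(idx, adj):
                records[i].p_fdr = float(q)
    elif fdr_family == "table":
        adj = bh_fdr([rec.p_raw for rec in records])
        for rec, q in zip(records, adj):
            rec.p_fdr = float(q)
    else:
        raise AssociationError(f"unknown fdr_family {fdr_family!r}")
    for rec in records:
        rec.significant = bool(rec.p_fdr < alpha)
    return records


def records_to_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records])
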