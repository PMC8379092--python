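"""Classifier performance metrics: confusion counts, ROC/AUC, McNemar.

AUC is computed from the trapezoidal area under the empirical ROC
curve, which (with ties contributing 1/2) equals the probability that a
random case scores above a random control.  McNemar's test compares two
classifiers on their discordant correct/incorrect pairs -- the
chi-square form with continuity correction when discordance is ample,
the exact two-sided binomial test otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMetrics",
    "RocResult",
    "McNemarResult",
    "EvaluationError",
    "confusion_metrics",
    "roc_auc",
    "mcnemar_compare",
]


class EvaluationError(ValueError):
    pass


@dataclass
class ConfusionMetrics:
    """Counts plus percentage accuracy/sensitivity/specificity.

    Cases (label 1) are the positive class: sensitivity is the correct
    fraction among cases, specificity among controls. Percentages are
    reported to two decimals.
    """

    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: float = field(init=False)
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)

    def __post_init__(self) -> None:
        total = self.tp + self.fn + self.tn + self.fp
        if total == 0:
            raise EvaluationError("empty confusion table")
        self.accuracy = round(100.0 * (self.tp + self.tn) / total, 2)
        self.sensitivity = round(100.0 * self.tp / (self.tp + self.fn), 2)
        self.specificity = round(100.0 * self.tn / (self.tn + self.fp), 2)

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "FN": self.fn, "TN": self.tn, "FP": self.fp,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def _check_labels(true: np.ndarray) -> None:
    if true.size == 0:
        raise EvaluationError("empty input")
    if np.unique(true).size < 2:
        raise EvaluationError("both classes must be present in the truth")


def confusion_metrics(
    predicted: Sequence[int], true: Sequence[int]
) -> ConfusionMetrics:
    pred = np.asarray(predicted, dtype=int)
    truth = np.asarray(true, dtype=int)
    if pred.shape != truth.shape:
        raise EvaluationError("length mismatch")
    _check_labels(truth)
    return ConfusionMetrics(
        tp=int(np.sum((pred == 1) & (truth == 1))),
        fn=int(np.sum((pred == 0) & (truth == 1))),
        tn=int(np.sum((pred == 0) & (truth == 0))),
        fp=int(np.sum((pred == 1) & (truth == 0))),
    )


@dataclass
class RocResult:
    """ROC points (FPR, TPR) anchored at (0,0) and (1,1), plus AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def to_dict(self) -> dict:
        return {
            "fpr": self.fpr.tolist(),
            "tpr": self.tpr.tolist(),
            "thresholds": self.thresholds.tolist(),
            "auc": self.auc,
        }


def roc_auc(scores: Sequence[float], true: Sequence[int]) -> RocResult:
    """Empirical ROC over unique score thresholds; trapezoidal AUC.

    Tied case/control scores contribute 1/2, so the AUC equals the
    concordant-pair fraction (Mann-Whitney statistic).
    """
    s = np.asarray(scores, dtype=float)
    truth = np.asarray(true, dtype=int)
    if s.shape != truth.shape:
        raise EvaluationError("length mismatch")
    _check_labels(truth)
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    t_sorted = truth[order]
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    # cumulative counts at each unique descending threshold
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), s_sorted.size - 1]
    tps = np.cumsum(t_sorted)[distinct]
    fps = np.cumsum(1 - t_sorted)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


@dataclass
class McNemarResult:
    """Discordant counts, statistic, p, and which variant ran."""

    b: int  # A correct, B wrong
    c: int  # A wrong, B correct
    statistic: float
    p: float
    method: Literal["chi-square-corrected", "chi-square", "exact-binomial"]

    def to_dict(self) -> dict:
        return {
            "b": self.b, "c": self.c, "statistic": self.statistic,
            "p": self.p, "method": self.method,
        }


#: below this many discordant pairs the exact binomial test is used
EXACT_CUTOFF = 25


def mcnemar_compare(
    preds_a: Sequence[int],
    preds_b: Sequence[int],
    true: Sequence[int],
    continuity_correction: bool = True,
) -> McNemarResult:
    """McNemar's paired test on correct/incorrect classifications.

    b counts subjects classifier A gets right and B wrong, c the
    reverse. The reported statistic is always the chi-square form
    (continuity corrected by default); the p-value comes from its
    chi-square(1) tail when b + c >= 25 and from the exact two-sided
    binomial test on min(b, c) out of b + c fair-coin trials otherwise.
    """
    pa = np.asarray(preds_a, dtype=int)
    pb = np.asarray(preds_b, dtype=int)
    truth = np.asarray(true, dtype=int)
    if not (pa.shape == pb.shape == truth.shape):
        raise EvaluationError("length mismatch")
    correct_a = pa == truth
    correct_b = pb == truth
    b = int(np.sum(correct_a & ~correct_b))
    c = int(np.sum(~correct_a & correct_b))
    n_disc = b + c
    if n_disc == 0:
        return McNemarResult(b=b, c=c, statistic=0.0, p=1.0,
                             method="exact-binomial")
    num = (abs(b - c) - 1) if continuity_correction else abs(b - c)
    stat = max(num, 0) ** 2 / n_disc
    if n_disc >= EXACT_CUTOFF:
        p = float(stats.chi2.sf(stat, df=1))
        method = (
            "chi-square-corrected" if continuity_correction else "chi-square"
        )
    else:
        # two-sided: double the smaller tail, capped at 1
        p = float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), n_disc, 0.5)))
        method = "exact-binomial"
    return McNemarResult(b=b, c=c, statistic=float(stat), p=p, method=method)
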