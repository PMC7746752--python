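"""Evaluation statistics for the classification experiments.

AUC is the Mann-Whitney concordance probability (ties counted 1/2), with
its variance estimated from DeLong placement values; operating points come
from Youden's index J = sensitivity + specificity - 1; AUC comparisons use
the DeLong z-test (paired or independent); group comparisons use Student's
t (optionally from printed summary statistics), paired t, and the Pearson
chi-square without continuity correction.  All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "ROCResult",
    "OperatingPoint",
    "TestStatistic",
    "roc_auc",
    "youden_point",
    "delong_compare",
    "ttest_from_summary",
    "paired_ttest",
    "chi_square_2x2",
    "trial_summary",
    "auc_confidence_interval",
    "evaluate_scores",
]


@dataclass
class TestStatistic:
    statistic: float
    p_value: float
    df: float | None = None
    kind: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    auc_variance: float
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


# ---------------------------------------------------------------------------
# AUC and DeLong machinery
# ---------------------------------------------------------------------------

def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values (V10 for positives, V01 for negatives)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    # midranks over the pooled sample give ties weight 1/2
    pooled = np.concatenate([pos, neg])
    ranks = stats.rankdata(pooled, method="average")
    r_pos = stats.rankdata(pos, method="average")
    r_neg = stats.rankdata(neg, method="average")
    v10 = (ranks[:m] - r_pos) / n
    v01 = 1.0 - (ranks[m:] - r_neg) / m
    return v10, v01


def roc_auc(scores, labels) -> ROCResult:
    """ROC sweep, concordance AUC, and DeLong variance.

    ``labels`` are 1 for AD (positive) and 0 for CN; ``scores`` are predicted
    AD probabilities (any monotone score works).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1D arrays")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")

    v10, v01 = _placements(scores, labels)
    auc = float(v10.mean())
    m, n = v10.size, v01.size
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    var = s10 / m + s01 / n

    fpr, tpr, thr = roc_curve(labels, scores)
    return ROCResult(
        thresholds=thr,
        sensitivities=tpr,
        specificities=1.0 - fpr,
        auc=auc,
        auc_variance=var,
        scores=scores,
        labels=labels,
    )


def youden_point(roc: ROCResult) -> OperatingPoint:
    """Operating point maximizing J = sensitivity + specificity - 1.

    Candidate cut-offs are the unique observed scores (classify positive when
    score >= threshold) plus an all-negative cut above the maximum; ties in J
    are broken toward the lowest threshold.
    """
    scores, labels = roc.scores, roc.labels
    if scores is None:
        raise ValueError("ROCResult must carry its score/label source")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    candidates = np.concatenate([np.unique(scores), [np.inf]])
    best = None
    for thr in candidates:
        pred = scores >= thr
        tp = int(np.sum(pred & (labels == 1)))
        tn = int(np.sum(~pred & (labels == 0)))
        sens = tp / n_pos
        spec = tn / n_neg
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, thr, sens, spec, (tp + tn) / (n_pos + n_neg))
    _, thr, sens, spec, acc = best
    return OperatingPoint(threshold=float(thr), sensitivity=sens, specificity=spec, accuracy=acc)


def delong_compare(roc_1: ROCResult, roc_2: ROCResult, paired: bool) -> TestStatistic:
    """DeLong z-test comparing two AUCs (paired or independent samples)."""
    if paired:
        if roc_1.labels is None or roc_2.labels is None:
            raise ValueError("paired comparison needs the score/label sources")
        if roc_1.labels.shape != roc_2.labels.shape or np.any(roc_1.labels != roc_2.labels):
            raise ValueError("paired comparison requires identical subjects/labels")
        v10_1, v01_1 = _placements(roc_1.scores, roc_1.labels)
        v10_2, v01_2 = _placements(roc_2.scores, roc_2.labels)
        m, n = v10_1.size, v01_1.size
        s10 = np.cov(np.stack([v10_1, v10_2]), ddof=1) if m > 1 else np.zeros((2, 2))
        s01 = np.cov(np.stack([v01_1, v01_2]), ddof=1) if n > 1 else np.zeros((2, 2))
        var = (
            (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
            + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
        )
    else:
        var = roc_1.auc_variance + roc_2.auc_variance

    diff = roc_1.auc - roc_2.auc
    if var <= 0:
        z = 0.0
    else:
        z = diff / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return TestStatistic(statistic=float(z), p_value=p, kind="delong_paired" if paired else "delong")


def auc_confidence_interval(roc: ROCResult, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation CI from the DeLong variance, truncated to [0, 1]."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(roc.auc_variance, 0.0))
    return (max(0.0, roc.auc - half), min(1.0, roc.auc + half))


# ---------------------------------------------------------------------------
# group comparison tests
# ---------------------------------------------------------------------------

def ttest_from_summary(mean_1, sd_1, n_1, mean_2, sd_2, n_2) -> TestStatistic:
    """Pooled-variance two-sample Student's t from printed summary statistics."""
    if n_1 < 2 or n_2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd_1 < 0 or sd_2 < 0 or (sd_1 == 0 and sd_2 == 0):
        raise ValueError("SDs must be >= 0 and not both zero")
    t, p = stats.ttest_ind_from_stats(
        mean_1, sd_1, n_1, mean_2, sd_2, n_2, equal_var=True
    )
    return TestStatistic(statistic=float(t), p_value=float(p), df=n_1 + n_2 - 2, kind="student_t")


def paired_ttest(values_a, values_b) -> TestStatistic:
    """Paired Student's t on elementwise differences (df = n - 1)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1D samples with n >= 2")
    if np.var(a - b, ddof=1) == 0.0:
        raise ValueError("zero-variance differences: paired t undefined")
    t, p = stats.ttest_rel(a, b)
    return TestStatistic(statistic=float(t), p_value=float(p), df=a.size - 1, kind="paired_t")


def chi_square_2x2(table) -> TestStatistic:
    """Pearson chi-square (no continuity correction) on a 2x2 count table."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table entries must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("all table margins must be positive")
    res = stats.chi2_contingency(t, correction=False)
    return TestStatistic(statistic=float(res.statistic), p_value=float(res.pvalue), df=1, kind="chi2")


def trial_summary(values) -> tuple[float, float]:
    """(mean, sample SD) across repeated trials, n-1 denominator."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two trial values")
    return float(v.mean()), float(v.std(ddof=1))


# ---------------------------------------------------------------------------
# convenience bundle used by the pipeline
# ---------------------------------------------------------------------------

def evaluate_scores(scores, labels, ci_level: float = 0.95) -> dict:
    """AUC with CI plus the Youden-point sensitivity/specificity/accuracy."""
    roc = roc_auc(scores, labels)
    op = youden_point(roc)
    lo, hi = auc_confidence_interval(roc, ci_level)
    return {
        "auc": roc.auc,
        "auc_ci": [lo, hi],
        "auc_variance": roc.auc_variance,
        "accuracy": op.accuracy,
        "sensitivity": op.sensitivity,
        "specificity": op.specificity,
        "threshold": op.threshold,
    }
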