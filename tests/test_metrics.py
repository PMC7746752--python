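"""ROC/AUC, Youden operating points, DeLong, t-tests, chi-square, aggregation."""

import numpy as np
import pytest
from scipy import stats

from adslice.metrics import (
    auc_confidence_interval,
    chi_square_2x2,
    delong_compare,
    paired_ttest,
    roc_auc,
    trial_summary,
    ttest_from_summary,
    youden_point,
)


def _pair_counting_auc(scores, labels):
    """O(n^2) concordance oracle with ties counted one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def test_auc_perfect_separation():
    roc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
    assert roc.auc == 1.0


def test_auc_all_tied_scores_is_half():
    roc = roc_auc([0.5] * 8, [0, 1] * 4)
    assert roc.auc == 0.5


def test_auc_matches_pair_counting_oracle_exactly(rng):
    for _ in range(50):
        n = int(rng.integers(4, 31))
        scores = np.round(rng.random(n), 2)  # rounding provokes ties
        labels = np.zeros(n, dtype=int)
        labels[rng.choice(n, size=max(1, n // 2), replace=False)] = 1
        if labels.sum() in (0, n):
            continue
        roc = roc_auc(scores, labels)
        assert roc.auc == pytest.approx(_pair_counting_auc(scores, labels), abs=1e-12)


def test_auc_rejects_single_class():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], [1, 1])


def test_roc_sweep_monotone(rng):
    scores = rng.random(40)
    labels = rng.integers(0, 2, 40)
    labels[0], labels[1] = 0, 1
    roc = roc_auc(scores, labels)
    assert np.all(np.diff(roc.sensitivities) >= 0)
    assert np.all(np.diff(roc.specificities) <= 0)


# ---------------------------------------------------------------------------
# Youden point
# ---------------------------------------------------------------------------

def test_youden_perfect_separation():
    op = youden_point(roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]))
    assert op.youden_j == pytest.approx(1.0)
    assert op.accuracy == 1.0


def test_youden_matches_exhaustive_enumeration():
    scores = np.array([0.1, 0.4, 0.35, 0.8])
    labels = np.array([0, 0, 1, 1])
    op = youden_point(roc_auc(scores, labels))
    best_j = -2.0
    for thr in np.concatenate([np.unique(scores), [np.inf]]):
        pred = scores >= thr
        sens = np.sum(pred & (labels == 1)) / 2
        spec = np.sum(~pred & (labels == 0)) / 2
        best_j = max(best_j, sens + spec - 1)
    assert op.youden_j == pytest.approx(best_j)


def test_youden_is_argmax_over_sweep(rng):
    scores = rng.random(30)
    labels = rng.integers(0, 2, 30)
    labels[:2] = [0, 1]
    roc = roc_auc(scores, labels)
    op = youden_point(roc)
    n_pos, n_neg = (labels == 1).sum(), (labels == 0).sum()
    for thr in np.unique(scores):
        pred = scores >= thr
        j = (
            np.sum(pred & (labels == 1)) / n_pos
            + np.sum(~pred & (labels == 0)) / n_neg
            - 1.0
        )
        assert op.youden_j >= j - 1e-12


def test_youden_accuracy_identity(rng):
    """Accuracy equals the class-weighted mix of sensitivity and specificity."""
    scores = rng.random(25)
    labels = rng.integers(0, 2, 25)
    labels[:2] = [0, 1]
    op = youden_point(roc_auc(scores, labels))
    n_pos, n_neg = (labels == 1).sum(), (labels == 0).sum()
    expected = (op.sensitivity * n_pos + op.specificity * n_neg) / (n_pos + n_neg)
    assert op.accuracy == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# DeLong
# ---------------------------------------------------------------------------

def test_delong_self_comparison_is_null():
    rng = np.random.default_rng(0)
    scores = rng.random(30)
    labels = rng.integers(0, 2, 30)
    labels[:2] = [0, 1]
    roc = roc_auc(scores, labels)
    ts = delong_compare(roc, roc, paired=True)
    assert ts.statistic == 0.0
    assert ts.p_value == 1.0


def test_delong_paired_requires_same_subjects(rng):
    r1 = roc_auc(rng.random(20), np.array([0, 1] * 10))
    r2 = roc_auc(rng.random(22), np.array([0, 1] * 11))
    with pytest.raises(ValueError):
        delong_compare(r1, r2, paired=True)


def test_delong_variance_close_to_bootstrap(rng):
    """DeLong variance within 25% of a 1000-resample bootstrap at n = 100."""
    n = 100
    scores = np.concatenate([rng.normal(1.0, 1, n // 2), rng.normal(0, 1, n // 2)])
    labels = np.array([1] * (n // 2) + [0] * (n // 2))
    roc = roc_auc(scores, labels)
    boot = []
    for _ in range(1000):
        idx = rng.integers(0, n, n)
        if len(np.unique(labels[idx])) < 2:
            continue
        boot.append(roc_auc(scores[idx], labels[idx]).auc)
    boot_var = np.var(boot, ddof=1)
    assert abs(roc.auc_variance - boot_var) / boot_var < 0.25


def test_delong_detects_a_real_difference(rng):
    n = 200
    labels = np.array([1] * n + [0] * n)
    strong = np.concatenate([rng.normal(2, 1, n), rng.normal(0, 1, n)])
    weak = rng.normal(0, 1, 2 * n)
    ts = delong_compare(roc_auc(strong, labels), roc_auc(weak, labels), paired=True)
    assert ts.p_value < 1e-6


# ---------------------------------------------------------------------------
# t-tests and chi-square
# ---------------------------------------------------------------------------

def test_summary_ttest_identity_groups():
    ts = ttest_from_summary(10.0, 2.0, 50, 10.0, 2.0, 50)
    assert ts.statistic == 0.0
    assert ts.p_value == pytest.approx(1.0)


def test_summary_ttest_equals_welch_for_equal_n():
    t_pooled = ttest_from_summary(23.0, 2.3, 195, 18.4, 5.0, 195).statistic
    t_welch = stats.ttest_ind_from_stats(
        23.0, 2.3, 195, 18.4, 5.0, 195, equal_var=False
    ).statistic
    assert t_pooled == pytest.approx(t_welch, abs=1e-10)


def test_summary_ttest_validation():
    with pytest.raises(ValueError):
        ttest_from_summary(1.0, 0.0, 10, 1.0, 0.0, 10)
    with pytest.raises(ValueError):
        ttest_from_summary(1.0, 1.0, 1, 1.0, 1.0, 10)


def test_paired_ttest_hand_formula():
    diffs = np.array([1.0, 1.0, 1.0, 1.0, 2.0])
    b = np.zeros(5)
    ts = paired_ttest(diffs, b)
    expected = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(5))
    assert ts.statistic == pytest.approx(expected, abs=1e-12)
    assert ts.df == 4


def test_paired_ttest_antisymmetry(rng):
    a, b = rng.random(8), rng.random(8)
    assert paired_ttest(a, b).statistic == pytest.approx(
        -paired_ttest(b, a).statistic, abs=1e-12
    )


def test_paired_ttest_zero_variance_errors():
    with pytest.raises(ValueError):
        paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


def test_chi_square_closed_form_and_symmetry():
    assert chi_square_2x2(np.array([[10, 0], [0, 10]])).statistic == pytest.approx(20.0)
    t = np.array([[12, 5], [7, 9]])
    swapped = t[::-1, ::-1].copy()
    assert chi_square_2x2(t).statistic == pytest.approx(
        chi_square_2x2(swapped).statistic
    )


def test_chi_square_validation():
    with pytest.raises(ValueError):
        chi_square_2x2(np.array([[1, 0], [2, 0]]))
    with pytest.raises(ValueError):
        chi_square_2x2(np.array([[0.5, 1], [1, 1]]))


# ---------------------------------------------------------------------------
# aggregation and confidence intervals
# ---------------------------------------------------------------------------

def test_trial_summary_sample_sd():
    mean, sd = trial_summary([0.90, 0.97, 0.95, 0.95, 0.95])
    assert mean == pytest.approx(0.944)
    assert sd == pytest.approx(np.std([0.90, 0.97, 0.95, 0.95, 0.95], ddof=1))
    _, sd0 = trial_summary([0.5, 0.5, 0.5])
    assert sd0 == 0.0


def test_ci_contains_point_and_truncates():
    rng = np.random.default_rng(1)
    scores = rng.random(30)
    labels = rng.integers(0, 2, 30)
    labels[:2] = [0, 1]
    roc = roc_auc(scores, labels)
    lo, hi = auc_confidence_interval(roc)
    assert lo <= roc.auc <= hi
    perfect = roc_auc([0.1, 0.9], [0, 1])
    assert auc_confidence_interval(perfect) == (1.0, 1.0)


def test_ci_coverage_near_nominal():
    from adslice.validation import auc_ci_coverage

    coverage = auc_ci_coverage(n_sims=200, n_per_class=40, true_auc=0.8, seed=5)
    assert 0.90 <= coverage <= 0.99
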