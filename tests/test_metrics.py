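"""Macro metrics against hand computation and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import brute_force_macro

from awpfnet.metrics import (ConfusionMatrix, MetricsReport, accuracy,
                             aggregate_reports, confusion, macro_f1,
                             macro_precision, macro_recall, pr_auc, pr_curve)

WORKED = ConfusionMatrix(np.array([[2, 1], [0, 3]]))


def test_confusion_counts_direct_example():
    cm = confusion([0, 0, 1], [0, 1, 1], 2)
    assert np.array_equal(cm.counts, [[1, 1], [0, 1]])


def test_confusion_identical_sequences_are_diagonal(rng):
    y = rng.integers(0, 4, 30)
    cm = confusion(y, y, 4)
    assert np.array_equal(cm.counts, np.diag(np.bincount(y, minlength=4)))


def test_confusion_matches_pairwise_loop_oracle(rng):
    y_true = rng.integers(0, 5, 200)
    y_pred = rng.integers(0, 5, 200)
    cm = confusion(y_true, y_pred, 5)
    expected = np.zeros((5, 5), dtype=int)
    for t, p in zip(y_true, y_pred):
        expected[t, p] += 1
    assert np.array_equal(cm.counts, expected)


def test_confusion_rejects_out_of_range_labels():
    with pytest.raises(ValueError, match=r"y_pred\[1\]"):
        confusion([0, 1], [0, 5], 2)


def test_worked_matrix_values():
    assert accuracy(WORKED) == pytest.approx(5 / 6)
    assert macro_precision(WORKED) == pytest.approx(0.875)
    assert macro_recall(WORKED) == pytest.approx(5 / 6)
    assert macro_f1(WORKED) == pytest.approx((4 / 5 + 6 / 7) / 2)


def test_perfect_diagonal_scores_one(rng):
    cm = ConfusionMatrix(np.diag(rng.integers(1, 9, 5)))
    for metric in (accuracy, macro_precision, macro_recall, macro_f1):
        assert metric(cm) == 1.0


def test_zero_diagonal_accuracy_is_zero():
    assert accuracy(ConfusionMatrix(np.array([[0, 2], [3, 0]]))) == 0.0


def test_never_predicted_class_contributes_zero():
    cm = ConfusionMatrix(np.array([[0, 3], [0, 3]]))  # class 0 never predicted
    assert macro_precision(cm) == pytest.approx((0 + 0.5) / 2)


def test_macro_metrics_invariant_under_class_permutation(rng):
    counts = rng.integers(0, 20, (4, 4))
    counts[0, 0] += 1
    cm = ConfusionMatrix(counts)
    perm = rng.permutation(4)
    cmp_ = ConfusionMatrix(counts[np.ix_(perm, perm)])
    assert macro_recall(cm) == pytest.approx(macro_recall(cmp_))
    assert macro_precision(cm) == pytest.approx(macro_precision(cmp_))
    assert macro_f1(cm) == pytest.approx(macro_f1(cmp_))


def test_macro_metrics_match_brute_force_on_random_matrices(rng):
    for _ in range(100):
        k = int(rng.integers(2, 8))
        counts = rng.integers(0, 25, (k, k))
        counts[0, 0] += 1  # guarantee n > 0
        cm = ConfusionMatrix(counts)
        acc, mp, mr, mf = brute_force_macro(counts)
        assert abs(accuracy(cm) - acc) < 1e-12
        assert abs(macro_precision(cm) - mp) < 1e-12
        assert abs(macro_recall(cm) - mr) < 1e-12
        assert abs(macro_f1(cm) - mf) < 1e-12


def test_macro_agreement_with_sklearn(rng):
    """Cross-check against a reference implementation on predictions
    where every class appears (no zero-denominator convention needed)."""
    from sklearn.metrics import precision_recall_fscore_support
    for _ in range(25):
        y_true = np.concatenate([np.arange(4), rng.integers(0, 4, 80)])
        y_pred = np.concatenate([np.arange(4), rng.integers(0, 4, 80)])
        cm = confusion(y_true, y_pred, 4)
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, average="macro", zero_division=0)
        assert macro_precision(cm) == pytest.approx(p, abs=1e-9)
        assert macro_recall(cm) == pytest.approx(r, abs=1e-9)
        assert macro_f1(cm) == pytest.approx(f, abs=1e-9)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(seed=st.integers(0, 10**6), k=st.integers(2, 9))
def test_all_metrics_bounded_and_diagonal_perfect(seed, k):
    """Every metric lies in [0, 1]; Acc equals micro recall (trace / n)."""
    counts = np.random.default_rng(seed).integers(0, 40, (k, k))
    counts[0, 0] += 1
    cm = ConfusionMatrix(counts)
    for metric in (accuracy, macro_precision, macro_recall, macro_f1):
        assert 0.0 <= metric(cm) <= 1.0
    assert accuracy(cm) == pytest.approx(cm.tp.sum() / cm.n)


def test_empty_matrix_rejected():
    with pytest.raises(ValueError):
        accuracy(ConfusionMatrix(np.zeros((2, 2), dtype=int)))


# ---------------------------------------------------------------------------
# PR curves
# ---------------------------------------------------------------------------

def test_pr_curve_hand_enumerated_points():
    scores = np.array([[0.1, 0.9], [0.2, 0.8], [0.7, 0.3]])
    pts = pr_curve(scores, [1, 0, 1], 1)
    assert pts == [(0.5, 1.0), (0.5, 0.5), (1.0, pytest.approx(2 / 3))]
    recalls = [p[0] for p in pts]
    assert recalls == sorted(recalls)


def test_perfectly_separated_scores_have_auc_one():
    scores = np.array([[0.1, 0.9], [0.2, 0.8], [0.9, 0.1], [0.8, 0.2]])
    assert pr_auc(pr_curve(scores, [1, 1, 0, 0], 1)) == pytest.approx(1.0)


def test_inverted_scores_auc_at_most_prevalence(rng):
    y = np.array([1, 1, 0, 0, 0, 0, 0, 0])
    scores = np.zeros((8, 2))
    scores[:, 1] = np.where(y == 1, 0.1, 0.9)  # anti-correlated
    assert pr_auc(pr_curve(scores, y, 1)) <= 0.25 + 1e-9


def test_pr_curve_rejects_class_without_positives():
    with pytest.raises(ValueError, match="class 1"):
        pr_curve(np.zeros((3, 2)), [0, 0, 0], 1)


# ---------------------------------------------------------------------------
# reports and aggregation
# ---------------------------------------------------------------------------

def test_report_mf_is_mean_of_per_class_f1():
    report = MetricsReport.from_confusion(WORKED)
    assert report.mf == pytest.approx(np.mean([r["f1"] for r in report.per_class]))


def test_aggregate_identical_replicates_has_zero_sd():
    r = MetricsReport.from_confusion(WORKED)
    agg = aggregate_reports([r, r, r])
    assert agg["acc"]["sd"] == 0.0
    assert agg["acc"]["mean"] == pytest.approx(5 / 6)


def test_aggregate_two_values_hand_arithmetic():
    a = MetricsReport(acc=0.9, mp=0.9, mr=0.9, mf=0.9)
    b = MetricsReport(acc=0.95, mp=0.95, mr=0.95, mf=0.95)
    agg = aggregate_reports([a, b])
    assert agg["acc"]["mean"] == pytest.approx(0.925)
    assert agg["acc"]["sd"] == pytest.approx(np.std([0.9, 0.95], ddof=1))


def test_single_replicate_sd_zero():
    agg = aggregate_reports([MetricsReport.from_confusion(WORKED)])
    assert all(agg[k]["sd"] == 0.0 for k in ("acc", "mp", "mr", "mf"))
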