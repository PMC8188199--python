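"""Metric correctness against brute-force counting oracles."""

import numpy as np
import pytest

from imgtrain import (
    confusion_cell_examples,
    evaluate_probabilities,
    mean_sd,
    threshold_purity,
)


# ---------------------------------------------------------------------------
# Brute-force oracles: direct counting over all distinct thresholds.
# ---------------------------------------------------------------------------

def brute_prfs(labels, pred, k):
    precision, recall, f1, support = [], [], [], []
    for c in range(k):
        tp = int(((pred == c) & (labels == c)).sum())
        fp = int(((pred == c) & (labels != c)).sum())
        fn = int(((pred != c) & (labels == c)).sum())
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        precision.append(p)
        recall.append(r)
        f1.append(f)
        support.append(tp + fn)
    return (np.array(precision), np.array(recall), np.array(f1),
            np.array(support))


def brute_roc_auc(truth, score):
    """Trapezoidal ROC AUC from explicit (fpr, tpr) points at every
    distinct threshold (predict positive when score >= threshold)."""
    pos = int(truth.sum())
    neg = len(truth) - pos
    points = [(0.0, 0.0)]
    for t in sorted(set(score), reverse=True):
        pred = score >= t
        tpr = ((pred == 1) & (truth == 1)).sum() / pos
        fpr = ((pred == 1) & (truth == 0)).sum() / neg
        points.append((fpr, tpr))
    fprs, tprs = zip(*points)
    return float(np.trapezoid(tprs, fprs))


def brute_pr_auc(truth, score):
    """Trapezoidal area under the precision-recall curve, with points at
    every distinct threshold from full recall upward and the (0, 1)
    endpoint."""
    pos = int(truth.sum())
    points = []
    for t in sorted(set(score), reverse=True):
        pred = score >= t
        tp = int(((pred == 1) & (truth == 1)).sum())
        fp = int(((pred == 1) & (truth == 0)).sum())
        points.append((tp / pos, tp / (tp + fp)))
        if tp == pos:  # full recall reached; lower thresholds only add FPs
            break
    points = points[::-1]          # descending recall, 1 -> lowest
    points.append((0.0, 1.0))      # the conventional endpoint
    recalls, precisions = zip(*points)
    return float(-np.trapezoid(precisions, recalls))


def _random_probs(rng, n, k):
    p = rng.random((n, k))
    return p / p.sum(axis=1, keepdims=True)


class TestOracleEquivalence:
    def test_fifty_random_prediction_sets(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            k = int(rng.integers(2, 5))
            n = int(rng.integers(10, 40))
            labels = rng.integers(0, k, n)
            labels[:k] = np.arange(k)  # every class present
            probs = _random_probs(rng, n, k)
            report = evaluate_probabilities(probs, labels)
            pred = probs.argmax(axis=1)
            p, r, f, s = brute_prfs(labels, pred, k)
            np.testing.assert_allclose(report.precision, p, atol=1e-9)
            np.testing.assert_allclose(report.recall, r, atol=1e-9)
            np.testing.assert_allclose(report.f1, f, atol=1e-9)
            np.testing.assert_array_equal(report.support, s)
            for c in range(k):
                truth = (labels == c).astype(int)
                assert report.roc_auc[c] == pytest.approx(
                    brute_roc_auc(truth, probs[:, c]), abs=1e-9)
                assert report.pr_auc[c] == pytest.approx(
                    brute_pr_auc(truth, probs[:, c]), abs=1e-9)

    def test_accuracy_equals_direct_fraction(self, rng):
        labels = rng.integers(0, 3, 30)
        labels[:3] = [0, 1, 2]
        probs = _random_probs(rng, 30, 3)
        report = evaluate_probabilities(probs, labels)
        assert report.accuracy == pytest.approx(
            float((probs.argmax(axis=1) == labels).mean()))
        assert report.confusion.sum() == 30
        np.testing.assert_array_equal(report.confusion.sum(axis=1),
                                      report.support)


class TestReportCases:
    def test_perfect_predictor(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        probs = np.eye(3)[labels] * 0.94 + 0.02
        report = evaluate_probabilities(probs, labels)
        assert report.accuracy == 1.0
        assert np.array_equal(report.confusion, np.diag([2, 2, 2]))
        assert (report.f1 == 1.0).all()
        assert np.allclose(report.roc_auc, 1.0)

    def test_binary_counts_by_hand(self):
        # TP=8 FP=2 FN=1 TN=9 for the positive class (label 1)
        labels = np.array([1] * 9 + [0] * 11)
        pred = np.array([1] * 8 + [0] + [1] * 2 + [0] * 9)
        probs = np.stack([1.0 - pred * 0.8 - 0.1, pred * 0.8 + 0.1], axis=1)
        report = evaluate_probabilities(probs, labels)
        assert report.precision[1] == pytest.approx(0.800, abs=5e-4)
        assert report.recall[1] == pytest.approx(0.889, abs=5e-4)
        assert report.f1[1] == pytest.approx(0.842, abs=5e-4)

    def test_constant_predictor_chance_level(self):
        labels = np.tile(np.arange(4), 10)
        probs = np.tile([0.97, 0.01, 0.01, 0.01], (40, 1))
        report = evaluate_probabilities(probs, labels)
        assert report.accuracy == pytest.approx(0.25)
        assert "1" in report.zero_division_classes  # never predicted

    def test_random_ranker_auc_near_half(self):
        rng = np.random.default_rng(0)
        n = 4000
        labels = rng.integers(0, 2, n)
        probs = _random_probs(rng, n, 2)
        report = evaluate_probabilities(probs, labels)
        assert report.roc_auc[1] == pytest.approx(0.5, abs=0.03)

    def test_probability_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            evaluate_probabilities(np.array([[0.5, 0.2]]), np.array([0]))


class TestConfusionCellExamples:
    def test_partition_property(self, rng):
        n, k = 25, 3
        true = rng.integers(0, k, n)
        pred = rng.integers(0, k, n)
        ids = [f"img{i}" for i in range(n)]
        total = 0
        for i in range(k):
            for j in range(k):
                cell = confusion_cell_examples(true, pred, ids, (i, j))
                total += len(cell)
                for sid in cell:
                    idx = ids.index(sid)
                    assert true[idx] == i and pred[idx] == j
        assert total == n

    def test_constructed_single_error(self):
        true = np.array([0, 1, 1])
        pred = np.array([0, 1, 0])
        ids = ["a", "b", "c"]
        assert confusion_cell_examples(true, pred, ids, (1, 0)) == ["c"]
        assert confusion_cell_examples(true, pred, ids, (1, 1)) == ["b"]

    def test_out_of_range_cell(self):
        with pytest.raises(IndexError):
            confusion_cell_examples([0], [0], ["a"], (0, 5))


class TestThresholdPurity:
    def test_constructed_example(self):
        probs = np.array([0.95, 0.92, 0.97, 0.85])
        labels = np.array([1, 1, 0, 1])  # 1 = positive (T)
        res = threshold_purity(probs, labels, upper=0.9, lower=0.1)
        assert res.n_above == 3
        assert res.above_fraction == pytest.approx(2 / 3)
        assert res.below_fraction is None  # empty stratum, not 0
        assert res.n_unassigned == 1

    def test_all_certain_positive(self):
        res = threshold_purity(np.ones(5), np.ones(5, int), 0.9, 0.1)
        assert res.above_fraction == 1.0

    def test_strict_inequalities(self):
        probs = np.array([0.9, 0.1, 0.5])
        labels = np.array([1, 0, 1])
        res = threshold_purity(probs, labels, upper=0.9, lower=0.1)
        assert res.n_above == 0 and res.n_below == 0
        assert res.n_unassigned == 3

    def test_matches_direct_counting(self, rng):
        probs = rng.random(200)
        labels = rng.integers(0, 2, 200)
        res = threshold_purity(probs, labels, upper=0.8, lower=0.2)
        above = probs > 0.8
        below = probs < 0.2
        assert res.above_fraction == pytest.approx(
            (labels[above] == 1).mean())
        assert res.below_fraction == pytest.approx(
            (labels[below] == 0).mean())

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError, match="lower < upper"):
            threshold_purity(np.array([0.5]), np.array([1]), upper=0.1,
                             lower=0.9)


class TestMeanSD:
    def test_constant_vector(self):
        assert mean_sd([1, 1, 1]) == (1.0, 0.0)

    def test_two_values_sample_sd(self):
        mean, sd = mean_sd([0, 1])
        assert mean == 0.5
        assert sd == pytest.approx(0.7071, abs=1e-4)

    def test_single_value_sd_unavailable(self):
        mean, sd = mean_sd([3.5])
        assert mean == 3.5 and sd is None

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mean_sd([])
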