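"""Evaluation metrics: confusion arithmetic, averages, ROC/AUC oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from pharmrisk.metrics import (
    accuracy,
    class_metrics,
    confusion_matrix,
    evaluate,
    macro_average,
    roc_auc,
    weighted_average,
)
from pharmrisk.errors import ShapeError


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        y = [0, 1, 2, 2, 1]
        cm = confusion_matrix(y, y)
        assert np.array_equal(cm, np.diag([1, 2, 2]))

    def test_counting(self):
        cm = confusion_matrix([0, 0, 1], [0, 1, 1])
        assert cm[0, 0] == 1 and cm[0, 1] == 1 and cm[1, 1] == 1
        assert cm.sum() == 3

    def test_length_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            confusion_matrix([0, 1], [0])


class TestClassMetrics:
    def test_f1_harmonic_mean_worked_example(self):
        # P=0.80, R=0.36 -> F1 = 2*0.8*0.36/1.16 = 0.4966 -> 0.50 at 2 d.p.
        p, r = 0.80, 0.36
        f1 = 2 * p * r / (p + r)
        assert round(f1, 2) == 0.50

    def test_perfect_class(self):
        cm = np.diag([5, 5, 5])
        assert class_metrics(cm, 0) == (1.0, 1.0, 1.0)

    def test_zero_precision_or_recall_gives_zero_f1(self):
        cm = np.array([[0, 3, 0], [0, 3, 0], [0, 0, 3]])
        p, r, f1 = class_metrics(cm, 0)
        assert (p, r, f1) == (0.0, 0.0, 0.0)


class TestAccuracy:
    def test_diagonal_is_one(self):
        assert accuracy(np.diag([3, 4, 5])) == 1.0

    def test_majority_dump(self):
        cm = confusion_matrix([0, 1, 2], [0, 0, 0])
        assert accuracy(cm) == pytest.approx(1 / 3)

    @given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)), min_size=1, max_size=50))
    @settings(derandomize=True, max_examples=40)
    def test_equals_mean_per_sample_correctness(self, pairs):
        y_true = [t for t, _ in pairs]
        y_pred = [p for _, p in pairs]
        cm = confusion_matrix(y_true, y_pred)
        assert accuracy(cm) == pytest.approx(
            np.mean([t == p for t, p in pairs])
        )


class TestAverages:
    def test_macro_is_unweighted_mean(self):
        per = [(0.9, 0.99, 0.94), (0.8, 0.36, 0.50), (0.7, 0.28, 0.40)]
        macro = macro_average(per)
        assert macro["recall"] == pytest.approx(np.mean([0.99, 0.36, 0.28]))
        assert macro["f1"] == pytest.approx(np.mean([0.94, 0.50, 0.40]))

    def test_identical_classes_collapse(self):
        per = [(0.7, 0.6, 0.65)] * 3
        macro = macro_average(per)
        assert (macro["precision"], macro["recall"], macro["f1"]) == pytest.approx(
            (0.7, 0.6, 0.65)
        )

    def test_equal_sizes_weighted_equals_macro(self):
        per = [(0.9, 0.8, 0.85), (0.6, 0.5, 0.55), (0.3, 0.2, 0.25)]
        w = weighted_average(per, [10, 10, 10])
        m = macro_average(per)
        for key in ("precision", "recall", "f1"):
            assert w[key] == pytest.approx(m[key])

    def test_single_class_weights(self):
        per = [(0.9, 0.8, 0.85), (0.6, 0.5, 0.55), (0.3, 0.2, 0.25)]
        w = weighted_average(per, [7, 0, 0])
        assert (w["precision"], w["recall"], w["f1"]) == (0.9, 0.8, 0.85)

    @given(
        st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)), min_size=3, max_size=60).filter(
            lambda pairs: {t for t, _ in pairs} == {0, 1, 2}
        )
    )
    @settings(derandomize=True, max_examples=40)
    def test_weighted_recall_equals_accuracy(self, pairs):
        """Class-size-weighted recall is the multiclass accuracy identity."""
        cm = confusion_matrix([t for t, _ in pairs], [p for _, p in pairs])
        per = [class_metrics(cm, c) for c in range(3)]
        w = weighted_average(per, cm.sum(axis=1))
        assert w["recall"] == pytest.approx(accuracy(cm))


def mann_whitney_auc(y_pos: np.ndarray, scores: np.ndarray) -> float:
    """Pair-counting oracle: fraction of (positive, negative) pairs ranked
    correctly, ties counting half."""
    pos = scores[y_pos == 1]
    neg = scores[y_pos == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def scores_for(self, y, sharp=True, seed=0):
        rng = np.random.default_rng(seed)
        s = np.zeros((len(y), 3))
        for i, c in enumerate(y):
            s[i] = rng.dirichlet([1, 1, 1])
            if sharp:
                s[i] = 0.05 * s[i]
                s[i, c] += 0.95
        return s / s.sum(axis=1, keepdims=True)

    def test_perfectly_separating_scores_give_auc_one(self):
        y = np.array([0, 0, 1, 1, 2, 2])
        _, aucs, macro, _ = roc_auc(y, self.scores_for(y, sharp=True))
        assert all(a == pytest.approx(1.0) for a in aucs.values())
        assert macro == pytest.approx(1.0)

    def test_random_scores_near_chance(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 3, size=3000)
        scores = rng.dirichlet([1, 1, 1], size=3000)
        _, aucs, macro, _ = roc_auc(y, scores)
        assert macro == pytest.approx(0.5, abs=0.03)

    def test_six_sample_binary_toy_matches_pair_counting(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        s1 = np.array([0.1, 0.8, 0.4, 0.35, 0.9, 0.2])
        scores = np.column_stack([1 - s1, s1, np.zeros(6)])
        _, aucs, _, _ = roc_auc(y, scores, classes=(0, 1, 2))
        assert aucs[1] == pytest.approx(mann_whitney_auc((y == 1).astype(int), s1))

    def test_matches_pair_counting_oracle_on_random_cases(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            y = rng.integers(0, 3, size=30)
            if len(np.unique(y)) < 3:
                continue
            scores = rng.dirichlet([1, 1, 1], size=30)
            _, aucs, _, _ = roc_auc(y, scores)
            for c in (0, 1, 2):
                expected = mann_whitney_auc((y == c).astype(int), scores[:, c])
                assert aucs[c] == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_sklearn_ovr(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 3, size=100)
        scores = rng.dirichlet([2, 1, 1], size=100)
        _, aucs, macro, _ = roc_auc(y, scores)
        expected = roc_auc_score(y, scores, multi_class="ovr", average="macro")
        assert macro == pytest.approx(expected, abs=1e-12)

    def test_constant_scores_flagged_as_degenerate(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        scores = np.full((6, 3), 1 / 3)
        _, aucs, macro, warnings = roc_auc(y, scores)
        assert macro == 0.5
        assert any("degenerate" in w for w in warnings)


def test_report_assembles_all_sections():
    y_true = [0, 0, 1, 1, 2, 2, 0, 1]
    y_pred = [0, 0, 1, 0, 2, 2, 0, 1]
    rng = np.random.default_rng(4)
    scores = rng.dirichlet([1, 1, 1], size=8)
    report = evaluate(y_true, y_pred, scores)
    assert report.confusion.sum() == 8
    for m in report.per_class.values():
        assert all(0.0 <= v <= 1.0 for v in m.values())
    assert report.weighted["recall"] == pytest.approx(report.accuracy)
    assert set(report.roc) == {0, 1, 2}
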