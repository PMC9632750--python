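import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermofuse.evaluation import (confusion_matrix, evaluate_predictions,
                                  per_class_metrics, roc_auc,
                                  weighted_average)


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def counting_oracle(y_true, y_pred, cls):
    """One-vs-rest counts by direct enumeration."""
    tp = sum(t == cls and p == cls for t, p in zip(y_true, y_pred))
    fp = sum(t != cls and p == cls for t, p in zip(y_true, y_pred))
    fn = sum(t == cls and p != cls for t, p in zip(y_true, y_pred))
    tn = sum(t != cls and p != cls for t, p in zip(y_true, y_pred))
    return tp, fp, fn, tn


def pair_counting_auc(y_true, scores, cls):
    """AUC as the probability a positive outranks a negative (ties 1/2)."""
    pos = [s for t, s in zip(y_true, scores) if t == cls]
    neg = [s for t, s in zip(y_true, scores) if t != cls]
    if not pos or not neg:
        return float("nan")
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = ["a", "b", "c", "a"]
        cc = confusion_matrix(y, y, ("a", "b", "c"))
        assert np.trace(cc.matrix) == 4
        assert cc.fp.sum() == cc.fn.sum() == 0

    def test_four_sample_enumeration(self):
        cc = confusion_matrix(["A", "A", "B", "B"], ["A", "B", "B", "B"],
                              ("A", "B"))
        a = list(cc.classes).index("A")
        assert (cc.tp[a], cc.fn[a], cc.fp[a], cc.tn[a]) == (1, 1, 0, 2)

    def test_constant_predictor_fp_equals_total_minus_support(self):
        y_true = ["a", "b", "c", "b", "c", "c"]
        cc = confusion_matrix(y_true, ["c"] * 6, ("a", "b", "c"))
        c = list(cc.classes).index("c")
        assert cc.fp[c] == 6 - 3

    def test_counts_sum_to_total_for_every_class(self, rng):
        y_true = rng.choice(list("abc"), size=30)
        y_pred = rng.choice(list("abc"), size=30)
        cc = confusion_matrix(y_true, y_pred, ("a", "b", "c"))
        np.testing.assert_array_equal(cc.tp + cc.fp + cc.fn + cc.tn, 30)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["a", "z"], ["a", "a"], ("a", "b"))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["a"], ["a", "b"], ("a", "b"))


class TestPerClassMetrics:
    def test_symmetric_counts_give_half(self):
        cc = confusion_matrix(["a", "a", "b", "b"], ["a", "b", "a", "b"],
                              ("a", "b"))
        rep = per_class_metrics(cc)
        row = rep.per_class.loc["a"]
        assert row["precision"] == row["recall"] == row["f1"] == 0.5

    def test_hand_computed_row(self):
        # class a: TP=3, FN=1, FP=0, TN=6
        y_true = ["a"] * 4 + ["b"] * 6
        y_pred = ["a", "a", "a", "b"] + ["b"] * 6
        rep = per_class_metrics(confusion_matrix(y_true, y_pred, ("a", "b")))
        row = rep.per_class.loc["a"]
        assert row["recall"] == pytest.approx(0.75)
        assert row["precision"] == pytest.approx(1.0)
        assert row["f1"] == pytest.approx(6 / 7)
        assert row["accuracy"] == pytest.approx(0.9)
        assert row["specificity"] == pytest.approx(1.0)

    def test_perfect_recall_and_specificity_force_zero_errors(self):
        y = ["a", "b", "a", "b", "b"]
        rep = per_class_metrics(confusion_matrix(y, y, ("a", "b")))
        assert (rep.per_class["recall"] == 1).all()
        assert (rep.per_class["specificity"] == 1).all()
        assert rep.confusion.fp.sum() == rep.confusion.fn.sum() == 0

    def test_zero_division_reported_as_zero_with_flag(self):
        # class b never predicted and absent: precision/recall 0/0
        rep = per_class_metrics(confusion_matrix(["a", "a"], ["a", "a"],
                                                 ("a", "b")))
        assert rep.per_class.loc["b", "recall"] == 0.0
        assert any("recall" in f for f in rep.flags)

    def test_micro_accuracy_is_trace_over_total(self):
        y_true = ["a", "b", "c", "a", "b"]
        y_pred = ["a", "b", "a", "a", "c"]
        rep = per_class_metrics(confusion_matrix(y_true, y_pred,
                                                 ("a", "b", "c")))
        assert rep.overall_accuracy == pytest.approx(3 / 5)


class TestWeightedAverage:
    def test_equal_supports_is_arithmetic_mean(self):
        assert weighted_average([0.2, 0.8], [5, 5]) == pytest.approx(0.5)

    def test_two_class_arithmetic(self):
        assert weighted_average([1.0, 0.0], [3, 1]) == pytest.approx(0.75)

    def test_single_class_is_identity(self):
        assert weighted_average([0.37], [9]) == pytest.approx(0.37)

    def test_result_bounded_by_extremes(self, rng):
        vals = rng.random(5)
        sups = rng.integers(1, 20, size=5)
        w = weighted_average(vals, sups)
        assert vals.min() - 1e-12 <= w <= vals.max() + 1e-12


class TestRocAuc:
    CLASSES = ("a", "b")

    def test_perfect_separation_gives_one(self):
        y = ["a", "a", "b", "b"]
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        aucs, weighted = roc_auc(y, scores, self.CLASSES)
        assert aucs["a"] == aucs["b"] == weighted == 1.0

    def test_constant_scores_give_half(self):
        y = ["a", "b", "a", "b"]
        aucs, _ = roc_auc(y, np.full((4, 2), 0.5), self.CLASSES)
        assert aucs["a"] == aucs["b"] == 0.5

    def test_six_sample_mann_whitney_equivalence(self):
        y = ["a", "b", "a", "b", "b", "a"]
        scores = np.array([[0.9], [0.4], [0.7], [0.7], [0.2], [0.3]])
        scores = np.hstack([scores, 1 - scores])
        aucs, _ = roc_auc(y, scores, self.CLASSES)
        assert aucs["a"] == pytest.approx(
            pair_counting_auc(y, scores[:, 0], "a"))

    def test_absent_class_reported_missing(self):
        y = ["a", "b", "a"]
        aucs, weighted = roc_auc(y, np.full((3, 3), 0.5), ("a", "b", "c"))
        assert np.isnan(aucs["c"])
        assert weighted == pytest.approx(0.5)  # a and b contribute 0.5 each

    def test_agrees_with_sklearn_on_random_data(self, rng):
        from sklearn.metrics import roc_auc_score
        y = rng.choice(["a", "b", "c"], size=40)
        scores = rng.random((40, 3))
        scores /= scores.sum(axis=1, keepdims=True)
        aucs, _ = roc_auc(y, scores, ("a", "b", "c"))
        for j, cls in enumerate(("a", "b", "c")):
            expected = roc_auc_score((y == cls).astype(int), scores[:, j])
            assert aucs[cls] == pytest.approx(expected, abs=1e-12)


@given(data=st.data())
@settings(max_examples=300, deadline=None)
def test_metric_suite_matches_bruteforce_oracles_on_small_sets(data):
    """Per-class metrics and AUC equal exhaustive counting on <=12 samples."""
    n = data.draw(st.integers(min_value=2, max_value=12))
    classes = ("a", "b", "c")
    y_true = data.draw(st.lists(st.sampled_from(classes), min_size=n,
                                max_size=n))
    y_pred = data.draw(st.lists(st.sampled_from(classes), min_size=n,
                                max_size=n))
    scores = np.array(data.draw(st.lists(
        st.lists(st.integers(0, 4), min_size=3, max_size=3),
        min_size=n, max_size=n)), dtype=float)
    cc = confusion_matrix(y_true, y_pred, classes)
    rep = per_class_metrics(cc)
    for i, cls in enumerate(classes):
        tp, fp, fn, tn = counting_oracle(y_true, y_pred, cls)
        assert (cc.tp[i], cc.fp[i], cc.fn[i], cc.tn[i]) == (tp, fp, fn, tn)
        row = rep.per_class.loc[cls]
        assert row["accuracy"] == pytest.approx((tp + tn) / n)
        if tp + fn:
            assert row["recall"] == pytest.approx(tp / (tp + fn))
        if tp + fp:
            assert row["precision"] == pytest.approx(tp / (tp + fp))
    aucs, _ = roc_auc(y_true, scores, classes)
    for j, cls in enumerate(classes):
        expected = pair_counting_auc(y_true, scores[:, j], cls)
        if np.isnan(expected):
            assert np.isnan(aucs[cls])
        else:
            assert aucs[cls] == pytest.approx(expected)
    # micro consistency: trace equals summed TP
    assert np.trace(cc.matrix) == cc.tp.sum()


def test_evaluate_predictions_attaches_auc_columns(rng):
    y_true = rng.choice(["a", "b"], size=20)
    scores = rng.random((20, 2))
    scores /= scores.sum(axis=1, keepdims=True)
    y_pred = np.array(["a", "b"])[scores.argmax(axis=1)]
    rep = evaluate_predictions(y_true, y_pred, scores, ("a", "b"))
    assert "auc" in rep.per_class.columns
    assert "auc" in rep.weighted
    d = rep.to_dict()
    assert set(d["per_class"]) == {"a", "b"}
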