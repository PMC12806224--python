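"""Metric suite: hand-computed cases, invariances, library cross-checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from prothyena.metrics import (ConfusionCounts, mcc, mcc_from_labels,
                               accuracy, f1_macro, auroc, auprc, spearman,
                               regression_losses, classification_report,
                               regression_report)


class TestMCC:
    def test_perfect_and_inverted(self):
        assert mcc(ConfusionCounts(tp=50, tn=50, fp=0, fn=0)) == 1.0
        assert mcc(ConfusionCounts(tp=0, tn=0, fp=50, fn=50)) == -1.0

    def test_hand_computed_mixed_case(self):
        c = ConfusionCounts(tp=90, fp=10, tn=80, fn=20)
        expected = 7000 / np.sqrt(100 * 110 * 90 * 100)
        assert mcc(c) == pytest.approx(expected, abs=1e-12)
        assert mcc(c) == pytest.approx(0.70352647, abs=1e-6)

    def test_degenerate_marginal_returns_zero(self):
        assert mcc(ConfusionCounts(tp=0, tn=50, fp=0, fn=50)) == 0.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            mcc(ConfusionCounts(tp=0, tn=0, fp=0, fn=0))

    def test_class_swap_symmetry(self, rng):
        tp, tn, fp, fn = rng.integers(1, 50, size=4)
        a = mcc(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        b = mcc(ConfusionCounts(tp=tn, tn=tp, fp=fn, fn=fp))
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_sklearn(self, rng):
        y = rng.integers(0, 2, size=200)
        p = rng.integers(0, 2, size=200)
        assert mcc_from_labels(y, p) == pytest.approx(
            matthews_corrcoef(y, p), abs=1e-12)


class TestF1Macro:
    def test_perfect(self):
        assert f1_macro([0, 1, 2], [0, 1, 2], 3) == 1.0

    def test_all_predicted_positive(self):
        """Binary, all predicted 1, labels half positive: mean(0, 2/3)."""
        y = [0, 0, 1, 1]
        p = [1, 1, 1, 1]
        assert f1_macro(y, p, 2) == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_relabeling_invariance(self, rng):
        y = rng.integers(0, 3, size=100)
        p = rng.integers(0, 3, size=100)
        perm = np.array([2, 0, 1])
        assert f1_macro(y, p, 3) == pytest.approx(
            f1_macro(perm[y], perm[p], 3), abs=1e-12)


class TestAUROC:
    def test_perfect_and_reversed(self):
        y = [1, 0, 1, 0]
        assert auroc(y, [0.9, 0.1, 0.8, 0.2]) == 1.0
        assert auroc(y, [0.1, 0.9, 0.2, 0.8]) == 0.0

    def test_pair_enumeration_case(self):
        # pairs won: (0.9 vs 0.8, 0.9 vs 0.1, 0.4 vs 0.1) + half for none
        assert auroc([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.1]) == pytest.approx(0.75)

    def test_ties_count_half(self):
        assert auroc([1, 0], [0.5, 0.5]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 1], [0.2, 0.4])

    def test_complement_and_monotone_invariance(self, rng):
        y = rng.integers(0, 2, size=50)
        y[0], y[1] = 0, 1
        s = rng.normal(size=50)
        a = auroc(y, s)
        assert a + auroc(y, -s) == pytest.approx(1.0, abs=1e-12)
        assert auroc(y, np.exp(2.0 * s)) == pytest.approx(a, abs=1e-12)

    def test_matches_sklearn(self, rng):
        y = rng.integers(0, 2, size=300)
        y[0], y[1] = 0, 1
        s = rng.normal(size=300).round(1)  # induce ties
        assert auroc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestAUPRC:
    def test_perfect_ranking(self):
        assert auprc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_single_positive_ranked_first(self):
        y = [1] + [0] * 9
        s = np.linspace(1, 0.1, 10)
        assert auprc(y, s) == 1.0

    def test_random_scores_near_prevalence(self, rng):
        n, prev = 4000, 0.3
        y = (rng.random(n) < prev).astype(int)
        s = rng.random(n)
        assert auprc(y, s) == pytest.approx(y.mean(), abs=0.05)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            auprc([0, 0], [0.1, 0.2])


class TestSpearman:
    def test_monotone_and_reversal(self, rng):
        x = rng.normal(size=30)
        assert spearman(x, np.exp(x)) == 1.0
        assert spearman(x, -x) == -1.0

    def test_hand_rank_formula(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d^2 sum = 2 -> 1 - 12/60
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1, 2, 3])


class TestRegressionLosses:
    def test_zero_residuals(self):
        assert regression_losses([1, 2], [1, 2]) == (0.0, 0.0, 0.0)

    def test_unit_residuals(self):
        mse, mae, t = regression_losses([1.0, -1.0], [0.0, 0.0], nu=1.0)
        assert (mse, mae) == (1.0, 1.0)
        assert t == pytest.approx(np.log(2.0), abs=1e-12)

    def test_student_t_subquadratic_growth(self):
        _, _, small = regression_losses([1.0], [0.0])
        _, _, big = regression_losses([10.0], [0.0])
        assert big / small < 100.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            regression_losses([1, 2], [1])


class TestReports:
    def test_binary_report_keys_match_task_metric_set(self, rng):
        y = rng.integers(0, 2, size=100)
        y[:2] = [0, 1]
        s = np.clip(y * 0.6 + rng.normal(0, 0.2, 100), 0, 1)
        rep = classification_report(y, s, n_classes=2)
        assert set(rep) == {"accuracy", "f1_macro", "mcc", "auroc",
                            "confusion"}
        conf = rep["confusion"]
        assert sum(conf.values()) == 100

    def test_multiclass_report_includes_auprc(self, rng):
        y = rng.integers(0, 3, size=120)
        s = rng.random((120, 3))
        s /= s.sum(axis=1, keepdims=True)
        rep = classification_report(y, s, n_classes=3)
        assert set(rep) == {"accuracy", "f1_macro", "auroc", "auprc"}

    def test_regression_report_keys(self, rng):
        x = rng.normal(size=60)
        rep = regression_report(x, x + rng.normal(0, 0.1, 60))
        assert set(rep) == {"spearman", "mse", "mae", "student_t_loss"}
        assert rep.to_json()  # serializes

    def test_null_predictions_near_chance(self, rng):
        """Random scores land metrics in their null neighborhoods."""
        y = rng.integers(0, 2, size=2000)
        s = rng.random(2000)
        rep = classification_report(y, s, n_classes=2)
        assert abs(rep["auroc"] - 0.5) < 0.05
        assert abs(rep["mcc"]) < 0.08
        assert abs(rep["accuracy"] - 0.5) < 0.05


@settings(max_examples=60, deadline=None)
@given(st.lists(st.integers(0, 1), min_size=4, max_size=60),
       st.integers(0, 2 ** 31 - 1))
def test_bounded_metrics_respect_ranges(labels, seed):
    labels = np.array(labels)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    scores = np.random.default_rng(seed).random(len(labels))
    preds = (scores > 0.5).astype(int)
    assert 0.0 <= accuracy(labels, preds) <= 1.0
    assert 0.0 <= f1_macro(labels, preds, 2) <= 1.0
    assert -1.0 <= mcc_from_labels(labels, preds) <= 1.0
    assert 0.0 <= auroc(labels, scores) <= 1.0
    assert 0.0 < auprc(labels, scores) <= 1.0
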