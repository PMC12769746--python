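"""Evaluation metrics: hand-computed confusion-matrix examples, brute-force
curve oracles, and cross-checks against scikit-learn."""

import numpy as np
import pytest
from sklearn import metrics as skm

import fedlora as fl
from fedlora.metrics import mcc_binary, pooled_equals_summed_micro


def cm2x2(tp, fn, fp, tn):
    """Rows true, columns predicted; class 0 is 'positive'."""
    return fl.ConfusionMatrix(np.array([[tp, fn], [fp, tn]]))


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        cm = fl.confusion_matrix([0, 1, 2, 3], [0, 1, 2, 3], 4)
        np.testing.assert_array_equal(cm.counts, np.eye(4, dtype=int))

    def test_hand_count(self):
        cm = fl.confusion_matrix([0, 0, 1, 1], [0, 1, 1, 1], 2)
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 2]])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fl.confusion_matrix([], [], 2)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            fl.confusion_matrix([0, 5], [0, 1], 4)


class TestClassificationMetrics:
    def test_diagonal_gives_all_ones(self):
        cm = fl.ConfusionMatrix(np.diag([5, 3, 2]))
        rep = fl.classification_metrics(cm)
        assert rep.accuracy == rep.f1_macro == rep.precision_micro == 1.0
        assert rep.kappa == rep.mcc == 1.0

    def test_binary_hand_example(self):
        """TP=40, TN=45, FP=5, FN=10: accuracy .85, precision 40/45,
        recall .8, F1 2pr/(p+r)."""
        cm = cm2x2(40, 10, 5, 45)
        rep = fl.classification_metrics(cm)
        p, r = 40 / 45, 0.8
        assert rep.accuracy == pytest.approx(0.85)
        tp0, fp0, fn0, _ = cm.one_vs_rest(0)
        assert tp0 / (tp0 + fp0) == pytest.approx(p)
        assert tp0 / (tp0 + fn0) == pytest.approx(r)
        # class-0 F1 appears in the macro average together with class 1
        f1_0 = 2 * p * r / (p + r)
        assert f1_0 == pytest.approx(0.842, abs=5e-4)

    def test_micro_precision_equals_accuracy(self):
        import warnings as _w
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(0, 30, size=(4, 4))
            counts[0, 0] += 1  # non-empty
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                rep = fl.classification_metrics(fl.ConfusionMatrix(counts))
            assert rep.precision_micro == pytest.approx(rep.accuracy)
            assert rep.recall_micro == pytest.approx(rep.accuracy)

    def test_zero_denominator_flagged_not_dropped(self):
        cm = fl.ConfusionMatrix(np.array([[5, 0], [3, 0]]))  # nothing predicted 1
        with pytest.warns(UserWarning, match="zero denominator"):
            rep = fl.classification_metrics(cm)
        assert 1 in rep.zero_division_classes
        assert np.isfinite(rep.f1_macro)

    def test_agrees_with_sklearn_on_random_predictions(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 4, 300)
        p = rng.integers(0, 4, 300)
        rep = fl.classification_metrics(fl.confusion_matrix(y, p, 4))
        assert rep.accuracy == pytest.approx(skm.accuracy_score(y, p))
        assert rep.f1_macro == pytest.approx(skm.f1_score(y, p, average="macro"))
        assert rep.kappa == pytest.approx(skm.cohen_kappa_score(y, p))
        assert rep.mcc == pytest.approx(skm.matthews_corrcoef(y, p))


class TestKappa:
    def test_hand_example_070(self):
        """cm [[45,5],[10,40]]: p_o=.85, p_e=.5, kappa=.70."""
        cm = fl.ConfusionMatrix(np.array([[45, 5], [10, 40]]))
        assert fl.cohens_kappa(cm) == pytest.approx(0.70)
        rep = fl.classification_metrics(cm)
        assert rep.p_observed == pytest.approx(0.85)
        assert rep.p_chance == pytest.approx(0.50)

    def test_independent_predictions_near_zero(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 10_000)
        p = rng.integers(0, 2, 10_000)
        assert abs(fl.cohens_kappa(fl.confusion_matrix(y, p, 2))) <= 0.05

    def test_kappa_not_above_accuracy(self):
        """kappa <= accuracy whenever chance agreement is positive."""
        rng = np.random.default_rng(9)
        for _ in range(1000):
            counts = rng.integers(0, 20, size=(3, 3))
            if counts.sum() == 0 or np.trace(counts) == counts.sum():
                continue
            cm = fl.ConfusionMatrix(counts)
            po, = [np.trace(counts) / counts.sum()]
            try:
                k = fl.cohens_kappa(cm)
            except ZeroDivisionError:
                continue
            assert k <= po + 1e-12

    def test_degenerate_single_cell_rejected(self):
        with pytest.raises(ZeroDivisionError):
            fl.cohens_kappa(fl.ConfusionMatrix(np.array([[7, 0], [0, 0]])))


class TestMCC:
    def test_perfect_binary(self):
        assert fl.mcc(cm2x2(10, 0, 0, 10)) == pytest.approx(1.0)

    def test_hand_example(self):
        """TP=40, TN=45, FP=5, FN=10 -> (1800-50)/sqrt(45*50*50*55)."""
        got = fl.mcc(cm2x2(40, 10, 5, 45))
        assert got == pytest.approx(1750 / np.sqrt(45 * 50 * 50 * 55), rel=1e-9)
        assert got == pytest.approx(0.704, abs=5e-4)

    def test_all_one_class_predictions_zero(self):
        assert fl.mcc(fl.ConfusionMatrix(np.array([[5, 0], [5, 0]]))) == 0.0

    def test_generalized_equals_binary_formula_exhaustive(self):
        """The multiclass correlation form reduces to the TP/TN/FP/FN
        formula on every 2x2 matrix with entries up to 12."""
        rng = range(13)
        for tp in rng:
            for fn in rng:
                for fp in rng:
                    for tn in rng:
                        if tp + fn + fp + tn == 0:
                            continue
                        got = fl.mcc(cm2x2(tp, fn, fp, tn))
                        # binary formula with class 0 positive
                        expected = mcc_binary(tp, tn, fp, fn)
                        assert got == pytest.approx(expected, abs=1e-12), \
                            (tp, fn, fp, tn)


class TestMicroCurves:
    def test_perfect_ordering_auc_ap_one(self):
        y = np.array([0, 0, 1, 1])
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        roc, pr = fl.micro_curves(y, scores)
        assert roc.area == pytest.approx(1.0)
        assert pr.area == pytest.approx(1.0)
        assert (roc.x[0], roc.y[0]) == (0.0, 0.0)
        assert (roc.x[-1], roc.y[-1]) == (1.0, 1.0)

    def test_binary_hand_auc(self):
        """Labels (1,1,0,0) with positive scores (.9,.4,.8,.1): 3 of 4
        label-pairs concordant, AUC = 0.75 on the positive class."""
        y = np.array([1, 1, 0, 0])
        pos = np.array([0.9, 0.4, 0.8, 0.1])
        scores = np.stack([1 - pos, pos], axis=1)
        # micro-averaging a 2-class one-hot duplicates the binary problem
        roc, _ = fl.micro_curves(y, scores)
        assert roc.area == pytest.approx(0.75)

    def test_auc_equals_pair_concordance_bruteforce(self):
        """Mann-Whitney oracle: AUC equals the fraction of concordant
        (positive, negative) pairs, ties counting half, at n <= 200."""
        rng = np.random.default_rng(3)
        n = 200
        y = rng.integers(0, 4, n)
        scores = rng.random((n, 4))
        scores = scores / scores.sum(1, keepdims=True)
        roc, _ = fl.micro_curves(y, scores)
        onehot = np.eye(4, dtype=int)[y].ravel()
        flat = scores.ravel()
        pos = flat[onehot == 1]
        neg = flat[onehot == 0]
        gt = (pos[:, None] > neg[None, :]).sum()
        eq = (pos[:, None] == neg[None, :]).sum()
        assert roc.area == pytest.approx((gt + 0.5 * eq) / (len(pos) * len(neg)))

    def test_random_scores_auc_half(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 4, 10_000)
        scores = rng.random((10_000, 4))
        roc, _ = fl.micro_curves(y, scores)
        assert roc.area == pytest.approx(0.5, abs=0.02)

    def test_single_class_truth_rejected(self):
        onehot = np.tile([1, 0], (5, 1))
        scores = np.random.default_rng(0).random((5, 2))
        # flattened one-hot always has both levels; pass degenerate directly
        with pytest.raises(ValueError):
            fl.micro_curves(np.zeros((5, 1), dtype=int) + 1,
                            np.ones((5, 1)))

    def test_non_finite_scores_rejected(self):
        with pytest.raises(ValueError):
            fl.micro_curves(np.array([0, 1]), np.array([[np.inf, 0], [0, 1]]))


class TestAggregation:
    def test_summed_matrices_match_pooled_predictions(self):
        rng = np.random.default_rng(21)
        ys, ps, cms = [], [], []
        for _ in range(5):
            y = rng.integers(0, 4, 100)
            p = rng.integers(0, 4, 100)
            ys.append(y)
            ps.append(p)
            cms.append(fl.confusion_matrix(y, p, 4))
        pooled = fl.confusion_matrix(np.concatenate(ys), np.concatenate(ps), 4)
        summed = pooled_equals_summed_micro(cms)
        np.testing.assert_array_equal(summed.counts, pooled.counts)
        a = fl.classification_metrics(summed)
        b = fl.classification_metrics(pooled)
        assert a.precision_micro == b.precision_micro
        assert a.accuracy == b.accuracy
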