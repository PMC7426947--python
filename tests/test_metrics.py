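"""Confusion matrices, printed metric formulas, hierarchy collapsing and
one-vs-rest AUC against brute-force oracles (and scikit-learn spot checks)."""

import numpy as np
import pytest
from sklearn.metrics import f1_score, roc_auc_score

from auxrad import metrics as mx


class TestConfusionMatrix:
    def test_hand_enumeration(self):
        cm = mx.confusion_matrix([0, 0, 1], [0, 1, 1], 2)
        np.testing.assert_array_equal(cm, [[1, 1], [0, 1]])

    def test_perfect_is_diagonal(self):
        y = [0, 1, 2, 2, 1]
        cm = mx.confusion_matrix(y, y, 3)
        assert np.trace(cm) == 5 and cm.sum() == 5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mx.confusion_matrix([], [], 2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mx.confusion_matrix([0, 3], [0, 1], 2)


class TestPerClassCounts:
    def test_hand_computation(self):
        cm = np.array([[5, 2], [1, 4]])
        assert mx.per_class_counts(cm, 0) == (5, 1, 2, 4)

    def test_diagonal_has_no_errors(self):
        cm = np.diag([3, 4, 5])
        for c in range(3):
            tp, fp, fn, tn = mx.per_class_counts(cm, c)
            assert fp == 0 and fn == 0

    def test_counts_partition_total(self):
        rng = np.random.default_rng(0)
        cm = rng.integers(0, 20, (7, 7))
        for c in range(7):
            assert sum(mx.per_class_counts(cm, c)) == cm.sum()


def brute_metrics(cm):
    """Direct per-formula recomputation, one-vs-rest."""
    k = cm.shape[0]
    total = cm.sum()
    acc = np.trace(cm) / total
    precision, recall, f1 = [], [], []
    for c in range(k):
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c, :].sum() - tp
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        precision.append(p); recall.append(r); f1.append(f)
    return acc, precision, recall, f1, float(np.mean(f1))


class TestMetrics:
    def test_formula_example(self):
        # TP=3, FP=1, FN=2, TN=4
        cm = np.array([[3, 2], [1, 4]])
        rep = mx.metrics(cm)
        assert rep.precision[0] == pytest.approx(0.75)
        assert rep.recall[0] == pytest.approx(0.6)
        assert rep.f1[0] == pytest.approx(2 * 0.75 * 0.6 / 1.35, abs=1e-9)

    def test_perfect_and_all_wrong(self):
        assert mx.metrics(np.diag([4, 5])).accuracy == 1.0
        assert all(f == 1.0 for f in mx.metrics(np.diag([4, 5])).f1)
        assert mx.metrics(np.array([[0, 3], [2, 0]])).accuracy == 0.0

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            k = int(rng.integers(2, 8))
            cm = rng.integers(0, 30, (k, k))
            if cm.sum() == 0:
                continue
            rep = mx.metrics(cm)
            acc, p, r, f1, avg = brute_metrics(cm)
            assert rep.accuracy == pytest.approx(acc, abs=1e-9)
            np.testing.assert_allclose(rep.precision, p, atol=1e-9)
            np.testing.assert_allclose(rep.recall, r, atol=1e-9)
            np.testing.assert_allclose(rep.f1, f1, atol=1e-9)
            assert rep.avg_f1 == pytest.approx(avg, abs=1e-9)

    def test_macro_f1_agrees_with_sklearn(self):
        rng = np.random.default_rng(8)
        y_true = rng.integers(0, 4, 200)
        y_pred = rng.integers(0, 4, 200)
        cm = mx.confusion_matrix(y_true, y_pred, 4)
        assert mx.metrics(cm).avg_f1 == pytest.approx(
            f1_score(y_true, y_pred, average="macro"), abs=1e-12)

    def test_f1_between_precision_and_recall(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            cm = rng.integers(0, 10, (5, 5))
            if cm.sum() == 0:
                continue
            rep = mx.metrics(cm)
            for p, r, f in zip(rep.precision, rep.recall, rep.f1):
                if p + r == 0:
                    continue
                assert min(p, r) - 1e-12 <= f <= max(p, r) + 1e-12
                assert f <= (p + r) / 2 + 1e-12

    def test_zero_denominator_flagged(self):
        cm = np.array([[5, 0], [3, 0]])   # class 1 never predicted or right
        rep = mx.metrics(cm)
        assert rep.precision[1] == 0.0
        assert (1, "precision") in rep.undefined


class TestCollapse:
    def brute_collapse(self, cm, mapping, k_out):
        out = np.zeros((k_out, k_out), dtype=int)
        k = cm.shape[0]
        for i in range(k):
            for j in range(k):
                out[mapping[i], mapping[j]] += cm[i, j]
        return out

    def test_total_conserved(self):
        rng = np.random.default_rng(1)
        cm = rng.integers(0, 15, (7, 7))
        for level in (3, 2):
            assert mx.collapse_cm(cm, level).sum() == cm.sum()

    def test_within_group_confusion_vanishes(self):
        cm = np.zeros((7, 7), dtype=int)
        cm[1, 2] = 5                      # A1 predicted as A2
        cm3 = mx.collapse_cm(cm, 3)
        assert cm3[1, 1] == 5 and np.trace(cm3) == 5

    def test_matches_brute_force_double_sum(self):
        rng = np.random.default_rng(2)
        cm = rng.integers(0, 9, (7, 7))
        np.testing.assert_array_equal(
            mx.collapse_cm(cm, 2),
            self.brute_collapse(cm, {i: mx.MID_TO_COARSE[mx.FINE_TO_MID[i]]
                                     for i in range(7)}, 2))

    def test_collapse_commutes(self):
        rng = np.random.default_rng(3)
        cm = rng.integers(0, 9, (7, 7))
        via_mid = mx.collapse(mx.collapse_cm(cm, 3), mx.MID_TO_COARSE, 2)
        np.testing.assert_array_equal(mx.collapse_cm(cm, 2), via_mid)

    def test_unmapped_label_rejected(self):
        with pytest.raises(ValueError):
            mx.collapse(np.zeros((3, 3)), {0: 0, 1: 0}, 2)


def brute_auc(y, s):
    """Pairwise positive-vs-negative probability, ties counted half."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert mx.roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert mx.roc_auc([0, 1, 0, 1], [0.5] * 4) == 0.5

    def test_hand_example(self):
        assert mx.roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == \
            pytest.approx(0.75)

    def test_rank_formula_equals_pairwise_brute_force(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n = int(rng.integers(5, 200))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.random(n), 2)   # induce ties
            assert mx.roc_auc(y, s) == pytest.approx(brute_auc(y, s),
                                                     abs=1e-12)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 150)
        s = rng.random(150)
        assert mx.roc_auc(y, s) == pytest.approx(roc_auc_score(y, s),
                                                 abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            mx.roc_auc([1, 1, 1], [0.1, 0.5, 0.9])
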