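"""Closed forms of the smoothed cross-entropy, linearity of the weighted
objective, and hand-checked / pair-counting oracles for the metrics."""

import numpy as np
import pytest

from phf3.autograd import Tensor
from phf3.losses import label_smoothing_ce, total_loss
from phf3.metrics import (
    MetricsReport,
    confusion_matrix,
    per_class_metrics,
    roc_auc,
)


def plain_cross_entropy(v, y):
    """Independent oracle: mean −log softmax at the true class."""
    v = np.asarray(v, dtype=np.float64)
    p = np.exp(v - v.max(1, keepdims=True))
    p /= p.sum(1, keepdims=True)
    return float(np.mean(-np.log(p[np.arange(len(y)), y])))


def pair_counting_auc(scores, positives):
    """Mann–Whitney oracle: fraction of (pos, neg) pairs ranked correctly,
    ties counted one half."""
    pos = scores[positives]
    neg = scores[~positives]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestLabelSmoothingCE:
    def test_epsilon_zero_is_plain_cross_entropy(self, rng):
        v = rng.normal(size=(12, 4)) * 3
        y = rng.integers(0, 4, 12)
        assert label_smoothing_ce(v, y, 0.0) == pytest.approx(
            plain_cross_entropy(v, y), abs=1e-7
        )

    @pytest.mark.parametrize("eps", [0.0, 0.1, 0.5])
    def test_uniform_logits_give_log_k(self, eps):
        # both the target and uniform terms equal ln K on flat logits
        assert label_smoothing_ce(np.zeros((5, 4)), [0, 1, 2, 3, 0], eps) == \
            pytest.approx(np.log(4), abs=1e-6)

    def test_hand_derived_single_sample_value(self):
        # softmax(2,0,0,0) = (0.7112, 0.0963, 0.0963, 0.0963):
        # 0.9·0.3408 + 0.1·1.8408 ≈ 0.4908
        v = np.array([[2.0, 0.0, 0.0, 0.0]])
        assert label_smoothing_ce(v, [0], 0.1) == pytest.approx(0.4908, abs=1e-3)

    def test_label_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            label_smoothing_ce(np.zeros((2, 4)), [0, 4], 0.1)

    def test_batch_permutation_invariance(self, rng):
        v = rng.normal(size=(9, 4))
        y = rng.integers(0, 4, 9)
        perm = rng.permutation(9)
        assert label_smoothing_ce(v, y, 0.1) == pytest.approx(
            label_smoothing_ce(v[perm], y[perm], 0.1), abs=1e-6
        )

    def test_convex_in_logits(self, rng):
        """Midpoint inequality on random logit pairs."""
        y = rng.integers(0, 4, 6)
        for _ in range(20):
            a = rng.normal(size=(6, 4)) * 2
            b = rng.normal(size=(6, 4)) * 2
            mid = label_smoothing_ce((a + b) / 2, y, 0.1)
            assert mid <= (label_smoothing_ce(a, y, 0.1)
                           + label_smoothing_ce(b, y, 0.1)) / 2 + 1e-9

    def test_gradient_flows(self):
        v = Tensor(np.zeros((3, 4)), requires_grad=True)
        label_smoothing_ce(v, [0, 1, 2], 0.1).backward()
        assert v.grad is not None and np.any(v.grad != 0)


class TestTotalLoss:
    def test_unit_weights_sum(self):
        assert total_loss(1.0, 1.0, 1.0, (1, 1, 1)) == pytest.approx(3.0)

    def test_default_weights_double_combine_term(self, rng):
        a, b, c = rng.normal(size=3)
        assert total_loss(a, b, c) == pytest.approx(a + b + 2 * c)

    def test_zero_weights_give_zero(self):
        assert total_loss(5.0, 2.0, 9.0, (0, 0, 0)) == 0.0

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            total_loss(1.0, 1.0, 1.0, (1, -1, 2))

    def test_exactly_linear_in_components(self, rng):
        a, b, c = rng.normal(size=3)
        base = total_loss(a, b, c, (1, 1, 2))
        assert total_loss(2 * a, b, c, (1, 1, 2)) - base == pytest.approx(a)


class TestConfusionAndRates:
    def test_perfect_predictions_are_diagonal(self):
        y = np.array([0, 1, 2, 3, 2, 1])
        cm = confusion_matrix(y, y, 4)
        assert cm.sum() == 6 and np.all(cm == np.diag(np.diag(cm)))

    def test_two_class_worked_example(self):
        cm = confusion_matrix([0, 0, 1, 1], [0, 1, 1, 1], 2)
        np.testing.assert_array_equal(cm, [[1, 1], [0, 2]])
        rates = per_class_metrics(cm)
        assert rates["SEN"][0] == pytest.approx(0.5)
        assert rates["SPE"][0] == pytest.approx(1.0)
        assert rates["PPV"][0] == pytest.approx(1.0)
        assert rates["NPV"][0] == pytest.approx(2 / 3)
        assert rates["ACC"][0] == pytest.approx(0.75)
        assert rates["F1"][0] == pytest.approx(2 / 3)
        assert rates["total_accuracy"] == pytest.approx(0.75)

    def test_diagonal_confusion_gives_ones(self):
        rates = per_class_metrics(np.diag([5, 3, 2, 7]))
        for name in ("ACC", "SEN", "SPE", "PPV", "NPV", "F1"):
            np.testing.assert_allclose(rates[name], 1.0)

    def test_absent_class_flagged_undefined_not_zero(self):
        # class 2 never true and never predicted
        cm = confusion_matrix([0, 1, 0, 1], [0, 1, 1, 1], 3)
        rates = per_class_metrics(cm)
        assert np.isnan(rates["SEN"][2]) and np.isnan(rates["PPV"][2])
        assert (2, "SEN") in rates["undefined"]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 1], [0], 2)


class TestROCAUC:
    def test_perfect_separation(self):
        scores = np.eye(3)[[0, 1, 2, 0]]
        auc = roc_auc(scores, [0, 1, 2, 0])
        np.testing.assert_allclose(auc, 1.0)

    def test_label_independent_scores_give_half(self):
        scores = np.tile([0.25, 0.25, 0.25, 0.25], (8, 1))
        auc = roc_auc(scores, [0, 1, 2, 3] * 2)
        np.testing.assert_allclose(auc, 0.5)

    def test_single_inversion_hand_example(self):
        # 2 positives, 2 negatives, one inverted pair → 3/4 ... choose scores
        # with exactly one of four pairs wrong: AUC = 0.875 needs 8 pairs.
        # 4 positives, 2 negatives, one wrong pair: 7.5/8? Use the classic
        # construction: pos scores (0.9, 0.8, 0.6, 0.4), neg (0.7, 0.1) →
        # wrong pairs: (0.6 vs 0.7), (0.4 vs 0.7) = 2 of 8 → 0.75. Instead:
        # pos (0.9, 0.8, 0.6, 0.5), neg (0.55, 0.1): wrong: (0.5 vs 0.55)
        # → 7/8 = 0.875.
        pos = [0.9, 0.8, 0.6, 0.5]
        neg = [0.55, 0.1]
        y = np.array([1, 1, 1, 1, 0, 0])
        scores = np.array(pos + neg)
        expected = pair_counting_auc(scores, y.astype(bool))
        assert expected == pytest.approx(0.875)
        got = roc_auc(np.c_[1 - scores, scores], y, 2)
        assert got[1] == pytest.approx(0.875)

    def test_matches_pair_counting_oracle_on_small_inputs(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 13))
            y = rng.integers(0, 3, n)
            if len(np.unique(y)) < 2:
                continue
            raw = rng.random((n, 3))
            # quantize to force ties sometimes
            raw = np.round(raw, 1)
            scores = raw / raw.sum(1, keepdims=True)
            auc = roc_auc(scores, y, 3)
            for c in range(3):
                pos = y == c
                if pos.any() and (~pos).any():
                    assert auc[c] == pytest.approx(
                        pair_counting_auc(scores[:, c], pos), abs=1e-9
                    )

    def test_single_class_truth_flagged(self):
        auc = roc_auc(np.random.rand(4, 2), [1, 1, 1, 1], 2)
        assert np.isnan(auc).all() or np.isnan(auc[0])


class TestMetricsReport:
    def test_confusion_sums_to_n_and_serializes(self, rng):
        y = rng.integers(0, 4, 40)
        pred = rng.integers(0, 4, 40)
        scores = rng.random((40, 4))
        scores /= scores.sum(1, keepdims=True)
        report = MetricsReport.from_predictions(y, pred, scores)
        assert report.confusion.sum() == 40
        frame = report.to_frame()
        assert list(frame.index) == ["ACC", "SEN", "SPE", "PPV", "NPV", "F1", "AUC"]
        assert frame.shape == (7, 4)
        import json

        payload = json.loads(report.to_json())
        assert payload["total_accuracy"] == pytest.approx(report.total_accuracy)
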