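import numpy as np
import pytest

import segpipe as sp
from segpipe.errors import ConfigurationError, ValidationError
from segpipe.metrics import (TverskyParams, categorical_crossentropy,
                             classwise_dice, classwise_jaccard,
                             confusion_counts, crossentropy_dice,
                             crossentropy_dice_grad, get_loss, get_metric,
                             jaccard_index, register_metric, soft_dice,
                             tversky_index, tversky_loss, tversky_loss_grad)
from segpipe.preprocessing import one_hot_encode

EPS = 1e-5


def hard_case(rng, shape=(6, 6), n_classes=3):
    truth = rng.integers(0, n_classes, size=shape).astype(np.int32)
    pred = rng.integers(0, n_classes, size=shape).astype(np.int32)
    return truth, pred


def dice_from_counts(tp, fp, fn, eps=EPS):
    return (2 * tp + eps) / (2 * tp + fp + fn + eps)


class TestSoftDice:
    def test_perfect_prediction(self, rng):
        t = one_hot_encode(rng.integers(0, 3, (5, 5)).astype(np.int32), 3)
        assert soft_dice(t, t) == pytest.approx(1.0, abs=1e-6)

    def test_disjoint_masks_near_zero(self):
        truth = np.zeros((200,), np.int32)
        truth[:100] = 1
        pred = np.zeros((200,), np.int32)
        pred[100:] = 1
        t, p = one_hot_encode(truth, 2), one_hot_encode(pred, 2)
        # foreground channel alone: |T|=|P|=100, overlap 0
        fg = soft_dice(t[..., 1:], p[..., 1:])
        assert fg == pytest.approx(EPS / (200 + EPS), rel=1e-6)

    def test_hand_counted_binary_case(self):
        # |truth| = 6, |pred| = 6, overlap 4 -> 8/12
        truth = np.zeros((4, 4), np.int32)
        truth[0, :4] = 1
        truth[1, :2] = 1
        pred = np.zeros((4, 4), np.int32)
        pred[0, 2:] = 1
        pred[1, :2] = 1
        pred[2, :2] = 1
        t, p = one_hot_encode(truth, 2), one_hot_encode(pred, 2)
        assert soft_dice(t[..., 1:], p[..., 1:]) == pytest.approx(2 / 3, abs=1e-4)

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            soft_dice(np.zeros((3, 2)), np.zeros((4, 2)))


class TestClasswiseDice:
    def test_absent_class_scores_one(self):
        truth = np.zeros((4, 4), np.int32)
        truth[0, 0] = 1
        scores, _ = classwise_dice(one_hot_encode(truth, 3),
                                   one_hot_encode(truth, 3))
        assert scores[2] == pytest.approx(1.0)  # eps/eps convention

    def test_confusion_oracle_single_class(self):
        # class 1: tp=4, fp=2, fn=2
        truth = np.zeros((4, 4), np.int32)
        pred = np.zeros((4, 4), np.int32)
        truth.ravel()[:6] = 1
        pred.ravel()[2:8] = 1
        scores, _ = classwise_dice(one_hot_encode(truth, 2),
                                   one_hot_encode(pred, 2))
        assert scores[1] == pytest.approx(2 / 3, abs=1e-4)


class TestTversky:
    def test_worked_example(self):
        # tp=4, fp=1, fn=3, alpha=0.3, beta=0.7 -> TI = 4 / 6.4 = 0.625
        truth = np.array([1] * 7 + [0], np.int32)
        pred = np.array([1] * 4 + [0] * 3 + [1], np.int32)
        t = one_hot_encode(truth, 2)[..., 1:]
        p = one_hot_encode(pred, 2)[..., 1:]
        ti = tversky_index(t, p, TverskyParams(0.3, 0.7, 1e-9))
        assert ti[0] == pytest.approx(0.625, abs=1e-6)

    def test_perfect_prediction_zero_loss(self, rng):
        t = one_hot_encode(rng.integers(0, 3, (6, 6)).astype(np.int32), 3)
        assert tversky_loss(t, t) == pytest.approx(0.0, abs=1e-4)

    def test_half_half_equals_classwise_dice_loss(self, rng):
        for _ in range(10):
            truth, pred = hard_case(rng)
            t = one_hot_encode(truth, 3)
            p = one_hot_encode(pred, 3).astype(np.float64)
            p = 0.7 * p + 0.1  # soften so the identity is exercised off 0/1
            tl = tversky_loss(t, p, TverskyParams(0.5, 0.5, EPS))
            _, mean_dice = classwise_dice(t, p, EPS)
            assert tl == pytest.approx(1.0 - mean_dice, abs=1e-9)

    def test_invalid_params(self):
        with pytest.raises(ValidationError):
            TverskyParams(0.0, 0.0)
        with pytest.raises(ValidationError):
            TverskyParams(-0.1, 0.7)


class TestJaccard:
    def test_identical_masks(self, rng):
        t = one_hot_encode(rng.integers(0, 2, (5, 5)).astype(np.int32), 2)
        assert jaccard_index(t, t) == pytest.approx(1.0, abs=1e-6)

    def test_hand_counts(self):
        # tp=4, fp=2, fn=2 -> 4/8
        truth = np.zeros((16,), np.int32)
        pred = np.zeros((16,), np.int32)
        truth[:6] = 1
        pred[2:8] = 1
        t = one_hot_encode(truth, 2)[..., 1:]
        p = one_hot_encode(pred, 2)[..., 1:]
        assert jaccard_index(t, p) == pytest.approx(0.5, abs=1e-5)

    def test_dice_jaccard_relation_on_hard_masks(self, rng):
        for _ in range(20):
            truth, pred = hard_case(rng)
            t, p = one_hot_encode(truth, 3), one_hot_encode(pred, 3)
            d_scores, _ = classwise_dice(t, p, EPS)
            j_scores, _ = classwise_jaccard(t, p, EPS)
            np.testing.assert_allclose(j_scores, d_scores / (2 - d_scores),
                                       atol=1e-9)


class TestCrossentropyDice:
    def test_perfect_prediction_near_minus_one(self, rng):
        t = one_hot_encode(rng.integers(0, 3, (6, 6)).astype(np.int32), 3)
        assert crossentropy_dice(t, t) == pytest.approx(-1.0, abs=1e-4)

    def test_uniform_prediction_closed_form(self, rng):
        truth = rng.integers(0, 2, (8, 8)).astype(np.int32)
        t = one_hot_encode(truth, 2)
        p = np.full(t.shape, 0.5)
        ce = categorical_crossentropy(t, p)
        assert ce == pytest.approx(np.log(2), abs=1e-9)
        assert crossentropy_dice(t, p) == pytest.approx(
            np.log(2) - soft_dice(t, p), abs=1e-9)

    def test_compositional(self, rng):
        truth = rng.integers(0, 3, (6, 6)).astype(np.int32)
        t = one_hot_encode(truth, 3)
        p = rng.random(t.shape)
        p = p / p.sum(axis=-1, keepdims=True)
        assert crossentropy_dice(t, p) == pytest.approx(
            categorical_crossentropy(t, p) - soft_dice(t, p), abs=1e-12)


class TestConfusionOracle:
    def test_all_metrics_agree_with_confusion_counting(self, rng):
        for _ in range(100):
            truth, pred = hard_case(rng, shape=(5, 7), n_classes=3)
            t, p = one_hot_encode(truth, 3), one_hot_encode(pred, 3)
            cc = confusion_counts(truth, pred, 3)
            d_scores, _ = classwise_dice(t, p, EPS)
            j_scores, _ = classwise_jaccard(t, p, EPS)
            ti = tversky_index(t, p, TverskyParams(0.3, 0.7, EPS))
            for c in range(3):
                tp, fp, fn = cc.tp[c], cc.fp[c], cc.fn[c]
                assert d_scores[c] == pytest.approx(
                    dice_from_counts(tp, fp, fn), abs=1e-6)
                assert j_scores[c] == pytest.approx(
                    (tp + EPS / 2) / (tp + fp + fn + EPS / 2), abs=1e-6)
                assert ti[c] == pytest.approx(
                    (tp + EPS / 2) / (tp + 0.3 * fp + 0.7 * fn + EPS / 2),
                    abs=1e-6)


class TestProperties:
    def test_permutation_invariance(self, rng):
        truth, pred = hard_case(rng, shape=(36,))
        t, p = one_hot_encode(truth, 3), one_hot_encode(pred, 3)
        perm = rng.permutation(36)
        for fn in (soft_dice, jaccard_index, tversky_loss, crossentropy_dice):
            assert fn(t, p) == pytest.approx(fn(t[perm], p[perm]), abs=1e-12)

    def test_flipping_a_correct_voxel_never_helps(self, rng):
        truth = rng.integers(0, 2, (6, 6)).astype(np.int32)
        truth[0, 0] = 1
        pred = truth.copy()
        before, _ = classwise_dice(one_hot_encode(truth, 2),
                                   one_hot_encode(pred, 2))
        pred[0, 0] = 0
        after, _ = classwise_dice(one_hot_encode(truth, 2),
                                  one_hot_encode(pred, 2))
        assert after[1] < before[1] and after[0] <= before[0] + 1e-12

    def test_scores_within_unit_interval(self, rng):
        truth, pred = hard_case(rng)
        t, p = one_hot_encode(truth, 3), one_hot_encode(pred, 3)
        assert 0.0 <= soft_dice(t, p) <= 1.0
        assert 0.0 <= jaccard_index(t, p) <= 1.0
        assert 0.0 <= tversky_loss(t, p, TverskyParams(1.0, 1.0, EPS)) <= 1.0


class TestTrainingLoss:
    def test_absent_classes_excluded_from_class_mean(self, rng):
        from segpipe.metrics import tversky_training_loss
        truth = one_hot_encode(rng.integers(0, 2, (5, 5)).astype(np.int32), 3)
        pred = rng.uniform(0.05, 0.95, truth.shape)
        # class 2 absent: the masked loss must equal the 2-class computation
        masked = tversky_training_loss(truth, pred)
        two_class = tversky_loss(truth[..., :2], pred[..., :2])
        assert masked == pytest.approx(two_class, abs=1e-12)

    def test_equals_plain_loss_when_all_classes_present(self, rng):
        from segpipe.metrics import tversky_training_loss
        truth = one_hot_encode(
            np.arange(9).reshape(3, 3).astype(np.int32) % 3, 3)
        pred = rng.uniform(0.05, 0.95, truth.shape)
        assert tversky_training_loss(truth, pred) == pytest.approx(
            tversky_loss(truth, pred), abs=1e-12)

    def test_masked_gradient_matches_finite_differences(self, rng):
        from segpipe.metrics import (tversky_training_loss,
                                     tversky_training_loss_grad)
        truth = one_hot_encode(rng.integers(0, 2, (4, 4)).astype(np.int32), 3)
        pred = rng.uniform(0.05, 0.95, truth.shape)
        g = tversky_training_loss_grad(truth, pred)
        assert np.all(g[..., 2] == 0.0)  # absent class: no death pressure
        for idx in [(0, 0, 0), (2, 3, 1)]:
            eps = 1e-6
            up, dn = pred.copy(), pred.copy()
            up[idx] += eps
            dn[idx] -= eps
            num = (tversky_training_loss(truth, up)
                   - tversky_training_loss(truth, dn)) / (2 * eps)
            assert g[idx] == pytest.approx(num, rel=1e-4, abs=1e-9)


class TestGradients:
    def test_loss_gradients_match_finite_differences(self, rng):
        truth = one_hot_encode(rng.integers(0, 3, (4, 4)).astype(np.int32), 3)
        pred = rng.uniform(0.05, 0.95, truth.shape)
        for loss, grad in [
            (lambda t, p: tversky_loss(t, p), lambda t, p: tversky_loss_grad(t, p)),
            (crossentropy_dice, crossentropy_dice_grad),
        ]:
            g = grad(truth, pred)
            for idx in [(0, 0, 0), (2, 3, 1), (3, 1, 2)]:
                eps = 1e-6
                up, dn = pred.copy(), pred.copy()
                up[idx] += eps
                dn[idx] -= eps
                num = (loss(truth, up) - loss(truth, dn)) / (2 * eps)
                assert g[idx] == pytest.approx(num, rel=1e-4, abs=1e-9)


class TestRegistry:
    def test_register_and_apply_custom_metric(self, rng):
        def accuracy(t, p):
            return float((t.argmax(-1) == p.argmax(-1)).mean())
        register_metric("accuracy", accuracy)
        truth, pred = hard_case(rng)
        t, p = one_hot_encode(truth, 3), one_hot_encode(pred, 3)
        assert get_metric("accuracy").fn(t, p) == pytest.approx(
            float((truth == pred).mean()))

    def test_unknown_and_duplicate(self):
        with pytest.raises(ConfigurationError):
            get_metric("nope")
        register_metric("once", lambda t, p: 0.0)
        with pytest.raises(ConfigurationError):
            register_metric("once", lambda t, p: 0.0)

    def test_metric_without_gradient_rejected_as_loss(self):
        register_metric("scoreonly", lambda t, p: 0.0)
        with pytest.raises(ConfigurationError):
            get_loss("scoreonly")
        assert get_loss("tversky") is not None
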