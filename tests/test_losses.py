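import numpy as np
import pytest

from labelrefine import (
    LossWeights,
    combine,
    confidence_loss,
    consistency_loss,
    generalized_dice_loss,
)
from labelrefine.losses import (
    confidence_grad,
    consistency_grad,
    generalized_dice_grad,
)

RNG = np.random.default_rng(123)


def _random_probs(h, w, c):
    raw = RNG.random((h, w, c))
    return raw / raw.sum(axis=-1, keepdims=True)


def _one_hot(labels, c):
    return np.eye(c)[labels]


class TestLossWeights:
    def test_defaults(self):
        w = LossWeights()
        assert (w.w_sup, w.w_cons, w.w_conf) == (1.0, 0.1, 0.1)

    @pytest.mark.parametrize("kwargs", [
        dict(w_sup=-1.0), dict(w_cons=float("nan")), dict(w_conf=float("inf")),
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LossWeights(**kwargs)


class TestGeneralizedDice:
    def test_perfect_prediction_is_zero(self):
        labels = RNG.integers(0, 3, size=(8, 8))
        pred = _one_hot(labels, 3)
        assert generalized_dice_loss(pred, labels) == pytest.approx(0.0, abs=1e-12)

    def test_total_miss_is_one(self):
        labels = np.zeros((8, 8), dtype=int)
        pred = _one_hot(np.ones((8, 8), dtype=int), 3)
        assert generalized_dice_loss(pred, labels) == pytest.approx(1.0, abs=1e-12)

    def test_range(self):
        for _ in range(20):
            labels = RNG.integers(0, 3, size=(8, 8))
            loss = generalized_dice_loss(_random_probs(8, 8, 3), labels)
            assert 0.0 <= loss <= 1.0

    def test_interpolation_monotone_toward_truth(self):
        labels = RNG.integers(0, 3, size=(8, 8))
        truth = _one_hot(labels, 3)
        start = _random_probs(8, 8, 3)
        losses = [
            generalized_dice_loss((1 - a) * start + a * truth, labels)
            for a in np.linspace(0, 1, 6)
        ]
        assert all(x >= y for x, y in zip(losses, losses[1:]))

    def test_absent_class_keeps_loss_finite(self):
        labels = np.zeros((8, 8), dtype=int)  # classes 1..2 absent
        loss = generalized_dice_loss(_random_probs(8, 8, 3), labels)
        assert np.isfinite(loss)

    def test_batch_is_mean_of_samples(self):
        labels = RNG.integers(0, 3, size=(2, 8, 8))
        pred = np.stack([_random_probs(8, 8, 3) for _ in range(2)])
        batched = generalized_dice_loss(pred, labels)
        singles = [generalized_dice_loss(pred[i], labels[i]) for i in range(2)]
        assert batched == pytest.approx(np.mean(singles), abs=1e-12)

    def test_gradient_matches_finite_difference(self):
        labels = RNG.integers(0, 3, size=(6, 6))
        pred = _random_probs(6, 6, 3)
        _, grad = generalized_dice_grad(pred, labels)
        eps = 1e-6
        for _ in range(10):
            i, j, c = RNG.integers(6), RNG.integers(6), RNG.integers(3)
            up, down = pred.copy(), pred.copy()
            up[i, j, c] += eps
            down[i, j, c] -= eps
            num = (generalized_dice_loss(up, labels)
                   - generalized_dice_loss(down, labels)) / (2 * eps)
            assert grad[0, i, j, c] == pytest.approx(num, abs=1e-7)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            generalized_dice_loss(_random_probs(4, 4, 3), np.full((4, 4), 5))


class TestConsistency:
    def test_identical_maps_zero(self):
        p = _random_probs(8, 8, 4)
        assert consistency_loss(p, p) == 0.0

    def test_symmetry(self):
        a, b = _random_probs(8, 8, 4), _random_probs(8, 8, 4)
        assert consistency_loss(a, b) == pytest.approx(consistency_loss(b, a))

    def test_value_is_mse(self):
        a, b = _random_probs(8, 8, 4), _random_probs(8, 8, 4)
        assert consistency_loss(a, b) == pytest.approx(np.mean((a - b) ** 2))

    def test_gradients_are_opposite(self):
        a, b = _random_probs(4, 4, 3), _random_probs(4, 4, 3)
        _, ga, gb = consistency_grad(a, b)
        assert np.allclose(ga, -gb)

    def test_gradient_matches_finite_difference(self):
        a, b = _random_probs(4, 4, 3), _random_probs(4, 4, 3)
        _, ga, _ = consistency_grad(a, b)
        eps = 1e-6
        up, down = a.copy(), a.copy()
        up[1, 2, 0] += eps
        down[1, 2, 0] -= eps
        num = (consistency_loss(up, b) - consistency_loss(down, b)) / (2 * eps)
        assert ga[0, 1, 2, 0] == pytest.approx(num, abs=1e-9)


class TestConfidence:
    def test_one_hot_is_zero(self):
        labels = RNG.integers(0, 4, size=(8, 8))
        assert confidence_loss(_one_hot(labels, 4)) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_is_one(self):
        p = np.full((8, 8, 4), 0.25)
        assert confidence_loss(p) == pytest.approx(1.0, abs=1e-12)

    def test_sharpening_decreases_entropy(self):
        p = _random_probs(8, 8, 4)
        sharper = p**2 / (p**2).sum(axis=-1, keepdims=True)
        assert confidence_loss(sharper) < confidence_loss(p)

    def test_gradient_matches_finite_difference(self):
        p = _random_probs(4, 4, 3)
        _, grad = confidence_grad(p)
        eps = 1e-7
        up, down = p.copy(), p.copy()
        up[2, 1, 2] += eps
        down[2, 1, 2] -= eps
        num = (confidence_loss(up) - confidence_loss(down)) / (2 * eps)
        assert grad[0, 2, 1, 2] == pytest.approx(num, rel=1e-5)


class TestCombine:
    def test_weighted_sum(self):
        w = LossWeights(1.0, 0.1, 0.1)
        assert combine(0.5, 0.2, 0.3, w) == pytest.approx(0.5 + 0.02 + 0.03)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            combine(float("nan"), 0.0, 0.0, LossWeights())
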