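import numpy as np
import pytest

from vesselseg import (
    ElasticTransform,
    MSSWeights,
    TverskyParams,
    consistency_loss,
    focal_tversky_loss,
    mss_loss,
    supervised_loss,
    total_loss,
    tversky_index,
)
from vesselseg.autodiff import Tensor
from vesselseg.deform import warp
from vesselseg.nets import MultiScaleOutput

P_PAPER = TverskyParams(alpha=0.7, beta=0.75, gamma=1.0, epsilon=1e-6)


def test_tversky_hand_counted_example():
    # TP=1, FN=1, FP=1 -> (1+eps)/(1 + 0.7 + 0.75 + eps)
    ti = tversky_index([1, 1, 0, 0], [1, 0, 1, 0], P_PAPER).item()
    assert ti == pytest.approx((1 + 1e-6) / (2.45 + 1e-6), abs=1e-9)
    assert ti == pytest.approx(0.40816, abs=1e-5)


def test_tversky_perfect_prediction_is_one(rng):
    y = (rng.random((6, 6, 6)) > 0.7).astype(float)
    assert tversky_index(y, y, P_PAPER).item() == pytest.approx(1.0, abs=1e-6)


def test_tversky_empty_prediction_limit():
    for n in (4, 64, 4096):
        y = np.ones(n)
        ti = tversky_index(np.zeros(n), y, P_PAPER).item()
        assert ti == pytest.approx(1e-6 / (0.7 * n + 1e-6), rel=1e-9)
    assert ti < 1e-8  # vanishes as the target grows


def test_tversky_equals_dice_at_half_weights(rng):
    """With alpha = beta = 0.5 the index reduces to Dice; cross-checked
    against an independent set-arithmetic implementation."""
    p = TverskyParams(alpha=0.5, beta=0.5, gamma=1.0, epsilon=1e-9)
    for _ in range(50):
        a = rng.random(200) > 0.6
        b = rng.random(200) > 0.6
        expected = (
            1.0
            if not (a.any() or b.any())
            else 2 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
        )
        ti = tversky_index(a.astype(float), b.astype(float), p).item()
        assert ti == pytest.approx(expected, abs=1e-6)


def test_focal_tversky_worked_examples():
    ftl = focal_tversky_loss([1, 1, 0, 0], [1, 0, 1, 0], P_PAPER).item()
    assert ftl == pytest.approx(0.59184, abs=1e-5)  # gamma=1: 1 - TI
    # TI = 0.75, gamma = 2 -> sqrt(1 - 0.75) = 0.5
    p2 = TverskyParams(gamma=2.0, epsilon=1e-6)
    pred = np.array([1.0, 1, 0, 0])
    target = np.array([1.0, 1, 1, 0])  # TP=2, FN=1: TI = 2/(2 + 0.7)
    ti = tversky_index(pred, target, p2).item()
    assert focal_tversky_loss(pred, target, p2).item() == pytest.approx(
        (1 - ti) ** 0.5, abs=1e-9
    )
    assert (1 - 0.75) ** (1 / 2.0) == pytest.approx(0.5)


def test_focal_tversky_perfect_is_zero(rng):
    y = (rng.random(64) > 0.5).astype(float)
    assert focal_tversky_loss(y, y, P_PAPER).item() == pytest.approx(0.0, abs=1e-5)


@pytest.mark.parametrize("gamma", [1.0, 4 / 3, 2.0, 3.0])
def test_focal_tversky_monotone_in_overlap(gamma, rng):
    """Better overlap (higher TI) must never increase the loss."""
    p = TverskyParams(gamma=gamma)
    y = np.zeros(100)
    y[:30] = 1
    losses = []
    for k in (0, 10, 20, 30):  # increasingly correct predictions
        pred = np.zeros(100)
        pred[:k] = 1
        losses.append(focal_tversky_loss(pred, y, p).item())
    assert losses == sorted(losses, reverse=True)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        TverskyParams(gamma=0.5)
    with pytest.raises(ValueError):
        TverskyParams(alpha=-1)
    with pytest.raises(ValueError):
        TverskyParams(epsilon=0)


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="shape"):
        tversky_index(np.zeros(3), np.zeros(4), P_PAPER)


def _const_output(values):
    return MultiScaleOutput([Tensor(np.asarray(v)) for v in values])


def test_mss_single_map_equals_ftl(rng):
    pred = rng.random(27)
    y = (rng.random(27) > 0.5).astype(float)
    p = TverskyParams()
    single = mss_loss(_const_output([pred]), y, MSSWeights([1.0]), p).item()
    assert single == pytest.approx(focal_tversky_loss(pred, y, p).item(), abs=1e-9)


def test_mss_weighted_mean_and_rescale_invariance(rng):
    y = np.ones(10)
    # three maps with known per-tap losses
    preds = [np.full(10, v) for v in (0.9, 0.7, 0.5)]
    p = TverskyParams(gamma=1.0, epsilon=1e-9)
    per_tap = [focal_tversky_loss(m, y, p).item() for m in preds]
    out = _const_output(preds)
    equal = mss_loss(out, y, MSSWeights([1, 1, 1]), p).item()
    assert equal == pytest.approx(np.mean(per_tap), abs=1e-9)
    w = MSSWeights([1.0, 0.5, 0.25])
    v1 = mss_loss(out, y, w, p).item()
    v10 = mss_loss(out, y, MSSWeights([10, 5, 2.5]), p).item()
    assert v1 == pytest.approx(v10, abs=1e-12)
    expected = np.dot(w.alphas, per_tap) / sum(w.alphas)
    assert v1 == pytest.approx(expected, abs=1e-9)


def test_mss_length_mismatch():
    with pytest.raises(ValueError, match="weights"):
        mss_loss(_const_output([np.ones(4)]), np.ones(4), MSSWeights([1, 1]), TverskyParams())


def test_supervised_loss_sums_branches(rng):
    y = (rng.random(50) > 0.5).astype(float)
    p = TverskyParams()
    w = MSSWeights([1.0])
    out1 = _const_output([rng.random(50)])
    out2 = _const_output([rng.random(50)])
    total = supervised_loss(out1, y, out2, y, w, p).item()
    expected = (
        mss_loss(out1, y, w, p).item() + mss_loss(out2, y, w, p).item()
    )
    assert total == pytest.approx(expected, abs=1e-9)
    perfect = _const_output([y])
    assert supervised_loss(perfect, y, perfect, y, w, p).item() == pytest.approx(
        0.0, abs=1e-3
    )


def test_total_loss_is_plain_sum():
    assert total_loss(0.8, 0.1).item() == pytest.approx(0.9)
    assert total_loss(0.0, 0.0).item() == 0.0


def test_consistency_zero_for_identity_transform_binary_maps(rng):
    shape = (16, 16, 16)
    t = ElasticTransform.sample(rng, shape, max_displacement=0.0)
    binary = (rng.random((1, 1) + shape) > 0.8).astype(np.float64)
    out = MultiScaleOutput([Tensor(binary)])
    c = consistency_loss(out, out, t, TverskyParams(epsilon=1e-6)).item()
    assert c == pytest.approx(0.0, abs=1e-5)


def test_consistency_zero_for_equivariant_predictor_nearest(rng):
    """If f is the identity network, f(t(x)) equals t(f(x)) exactly under a
    nearest-neighbour warp, so the consistency comparison vanishes for any
    sampled transform on binary input."""
    shape = (16, 16, 16)
    x = (rng.random(shape) > 0.8).astype(np.float64)
    for _ in range(5):
        t = ElasticTransform.sample(rng, shape)
        tx = warp(x, t.field, mode="nearest")  # branch-2 input = prediction
        target = warp(x, t.field, mode="nearest")  # t applied to f(x) = x
        c = focal_tversky_loss(tx, target, TverskyParams(epsilon=1e-6)).item()
        assert c == pytest.approx(0.0, abs=1e-5)


def test_consistency_zero_when_both_maps_empty(rng):
    shape = (16, 16, 16)
    t = ElasticTransform.sample(rng, shape)
    zeros = MultiScaleOutput([Tensor(np.zeros((1, 1) + shape))])
    c = consistency_loss(zeros, zeros, t, TverskyParams()).item()
    assert c == pytest.approx(0.0, abs=1e-6)


def test_losses_differentiable_numeric_gradients(rng):
    """Central-difference check of d FTL / d pred at random interior points."""
    p = TverskyParams()
    y = (rng.random(40) > 0.6).astype(float)
    pred = Tensor(rng.uniform(0.05, 0.95, 40), requires_grad=True)
    focal_tversky_loss(pred, y, p).backward()
    eps = 1e-6
    for _ in range(20):
        i = rng.integers(0, 40)
        orig = pred.data[i]
        pred.data[i] = orig + eps
        up = focal_tversky_loss(pred.detach(), y, p).item()
        pred.data[i] = orig - eps
        dn = focal_tversky_loss(pred.detach(), y, p).item()
        pred.data[i] = orig
        num = (up - dn) / (2 * eps)
        assert abs(num - pred.grad[i]) < 1e-4
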