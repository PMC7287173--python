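"""Network architecture, Soft-Dice loss, augmentation and training loop."""

import numpy as np
import pytest

from octseg import (PhantomSpec, generate_phantom, extract_patches,
                    iterations_per_epoch)
from octseg.network import (NetworkConfig, OCTNet, soft_dice_loss,
                            soft_dice_grad, train, augment_pair)
from octseg.network.layers import (MaxPool2x2, MaxUnpool2x2, softmax_backward,
                                   softmax_channels)

from conftest import small_spec


def test_forward_preserves_patch_dimensions():
    """A 526x75 patch maps to a 526x75 probability map with 3 classes."""
    net = OCTNet(NetworkConfig())  # full-size: 4 blocks, 64 filters of 7x3
    x = np.random.default_rng(0).random((1, 1, 526, 75))
    p = net.forward(x, training=False)
    assert p.shape == (1, 3, 526, 75)
    assert np.abs(p.sum(axis=1) - 1.0).max() < 1e-5


def test_probabilities_sum_to_one_on_zero_input():
    net = OCTNet(NetworkConfig(n_blocks=2, filters_per_conv=4))
    p = net.forward(np.zeros((2, 1, 16, 12)), training=True)
    assert np.allclose(p.sum(axis=1), 1.0)
    assert p.min() >= 0.0


def test_pool_unpool_index_round_trip():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(2, 3, 8, 6))
    pool = MaxPool2x2()
    pooled = pool.forward(x)
    unpool = MaxUnpool2x2()
    back = unpool.forward(pooled, pool.indices)
    # each max value is restored at its argmax position, zeros elsewhere
    flat = back.reshape(2, 3, 4, 2, 3, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = flat.reshape(2, 3, 4, 3, 4)
    restored = np.take_along_axis(flat, pool.indices[..., None], axis=-1)[..., 0]
    assert np.allclose(restored, pooled)
    assert (back != 0).sum() <= pooled.size


def test_soft_dice_examples():
    g = np.zeros((2, 4, 4))
    g[0, :2] = 1
    g[1, 2:] = 1
    assert soft_dice_loss(g, g) == 0.0
    swapped = g[::-1]
    assert soft_dice_loss(swapped, g) == 1.0
    # 1-pixel 2-class toy: 1 - 2*0.8 / (0.8^2 + 0.2^2 + 1)
    pred = np.array([0.8, 0.2]).reshape(2, 1, 1)
    gt = np.array([1.0, 0.0]).reshape(2, 1, 1)
    assert soft_dice_loss(pred, gt) == pytest.approx(1 - 1.6 / 1.68)


def test_soft_dice_symmetry_and_range():
    rng = np.random.default_rng(2)
    for _ in range(20):
        a = rng.dirichlet(np.ones(3), size=(5, 4)).transpose(2, 0, 1)
        b = rng.dirichlet(np.ones(3), size=(5, 4)).transpose(2, 0, 1)
        z = soft_dice_loss(a, b)
        assert 0.0 <= z <= 1.0
        assert z == pytest.approx(soft_dice_loss(b, a))
    assert soft_dice_loss(np.zeros((2, 3, 3)), np.zeros((2, 3, 3))) == 0.0


def test_loss_gradient_matches_finite_differences():
    rng = np.random.default_rng(3)
    z = rng.normal(size=(1, 3, 6, 5))
    g = np.eye(3)[rng.integers(0, 3, (1, 6, 5))].transpose(0, 3, 1, 2)
    p = softmax_channels(z)
    dz = softmax_backward(p, soft_dice_grad(p, g))
    eps = 1e-6
    for idx in [(0, 0, 2, 3), (0, 1, 0, 0), (0, 2, 5, 4)]:
        zp = z.copy(); zp[idx] += eps
        zm = z.copy(); zm[idx] -= eps
        num = (soft_dice_loss(softmax_channels(zp), g)
               - soft_dice_loss(softmax_channels(zm), g)) / (2 * eps)
        assert dz[idx] == pytest.approx(num, rel=1e-4, abs=1e-9)


def test_augment_preserves_labels_and_shape():
    img, mask, _ = generate_phantom(small_spec(seed=4))
    rng = np.random.default_rng(0)
    for _ in range(5):
        ai, am = augment_pair(img.pixels, mask.labels, rng)
        assert ai.shape == img.shape and am.shape == mask.shape
        assert set(np.unique(am)) <= set(np.unique(mask.labels))


def test_horizontal_flip_is_involution():
    img, mask, _ = generate_phantom(small_spec(seed=5))
    assert np.array_equal(img.pixels[:, ::-1][:, ::-1], img.pixels)
    # zero-strength augmentation is the identity
    rng = np.random.default_rng(1)
    ai, am = augment_pair(img.pixels, mask.labels, rng,
                          max_rotation_deg=0.0, max_shift_px=0)
    flipped = not np.array_equal(ai, img.pixels)
    if flipped:
        ai, am = ai[:, ::-1], am[:, ::-1]
    assert np.array_equal(ai, img.pixels) and np.array_equal(am, mask.labels)


def test_iterations_per_epoch_uses_ceiling():
    assert iterations_per_epoch(2730, 4) == 683
    assert iterations_per_epoch(8, 4) == 2
    assert iterations_per_epoch(9, 4) == 3


def test_learning_rate_schedule():
    cfg = NetworkConfig()
    assert cfg.lr_at_epoch(0) == pytest.approx(0.001)
    assert cfg.lr_at_epoch(19) == pytest.approx(0.001)
    assert cfg.lr_at_epoch(20) == pytest.approx(0.0001)
    assert cfg.lr_at_epoch(39) == pytest.approx(0.0001)
    assert cfg.lr_at_epoch(40) == pytest.approx(0.00001)


def test_forward_deterministic_in_eval_mode():
    net = OCTNet(NetworkConfig(n_blocks=2, filters_per_conv=4, seed=7))
    x = np.random.default_rng(0).random((1, 1, 24, 20))
    assert np.array_equal(net.forward(x), net.forward(x))


def _patch_set(n_phantoms, speckle, seed0=0):
    pairs = []
    for seed in range(seed0, seed0 + n_phantoms):
        spec = small_spec(speckle_level=speckle, seed=seed)
        img, mask, _ = generate_phantom(spec)
        pairs.extend(extract_patches(img, mask, 48))
    return pairs


def test_training_reaches_low_dice_loss_on_clean_phantoms():
    """Noise-free phantoms with distinct layer intensities: loss < 0.2 in 10 epochs."""
    pairs = _patch_set(16, speckle=0.0)
    cfg = NetworkConfig(n_blocks=2, filters_per_conv=8, epochs=10,
                        batch_size=4, seed=0, augment=False)
    ms = train(pairs[:28], pairs[28:], cfg)
    assert ms.history[-1]["train_loss"] < 0.2


def test_checkpoint_minimizes_validation_loss():
    pairs = _patch_set(4, speckle=0.2, seed0=50)
    cfg = NetworkConfig(n_blocks=2, filters_per_conv=4, epochs=3,
                        batch_size=4, seed=1)
    ms = train(pairs[:6], pairs[6:], cfg)
    vals = [h["val_loss"] for h in ms.history]
    assert ms.history[ms.best_epoch]["val_loss"] == min(vals)
    assert ms.history[ms.best_epoch]["val_loss"] <= vals[-1]


def test_empty_training_set_rejected():
    with pytest.raises(ValueError, match="empty"):
        train([], [], NetworkConfig())


def test_model_state_save_load_round_trip(tmp_path):
    pairs = _patch_set(2, speckle=0.1, seed0=80)
    cfg = NetworkConfig(n_blocks=2, filters_per_conv=4, epochs=1,
                        batch_size=4, seed=2, augment=False)
    ms = train(pairs[:3], pairs[3:], cfg)
    ms.save(tmp_path / "m.pkl")
    from octseg.network import ModelState
    back = ModelState.load(tmp_path / "m.pkl")
    x = pairs[0][0][None, None]
    assert np.allclose(back.build().forward(x), ms.build().forward(x))
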