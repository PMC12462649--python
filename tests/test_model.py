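"""Network construction, forward contract, loss, schedule and
checkpointing."""

import numpy as np
import pytest

from petmri3d.model import (
    ModelConfig,
    build_model,
    focal_loss,
    focal_loss_grad,
    forward,
    load_model,
    lr_at,
    save_model,
)
from petmri3d.nn.layers import global_avg_pool


def _x(shape, seed=0):
    return np.random.default_rng(seed).random(shape).astype(np.float32)


def test_two_channel_model_accepts_standard_input():
    cfg = ModelConfig(in_channels=2, stage_filters=(4, 8), dense_units=16, seed=0)
    m = build_model(cfg)
    p = forward(m, _x((64, 64, 32, 2)))
    assert 0.0 < p < 1.0


def test_seeded_init_is_reproducible(tiny_model_config):
    a = build_model(tiny_model_config).net.state_dict()
    b = build_model(tiny_model_config).net.state_dict()
    assert a.keys() == b.keys()
    for k in a:
        np.testing.assert_array_equal(a[k], b[k])


def test_parameter_count_grows_with_stage_filters():
    small = build_model(ModelConfig(in_channels=1, stage_filters=(8, 16)))
    big = build_model(ModelConfig(in_channels=1, stage_filters=(64, 128)))
    assert big.net.n_parameters() > small.net.n_parameters()


def test_one_model_handles_variable_depth(tiny_model):
    p32 = forward(tiny_model, _x((16, 16, 32, 1)))
    p48 = forward(tiny_model, _x((16, 16, 48, 1)))
    assert 0.0 < p32 < 1.0 and 0.0 < p48 < 1.0


def test_wrong_channel_count_raises(tiny_model):
    with pytest.raises(ValueError, match="channel"):
        forward(tiny_model, _x((16, 16, 12, 2)))


def test_inference_is_batch_composition_invariant(tiny_model):
    x = _x((2, 16, 16, 12, 1), seed=5)
    batch = forward(tiny_model, x)
    dup = forward(tiny_model, np.concatenate([x, x]))
    np.testing.assert_allclose(np.tile(batch, 2), dup, rtol=1e-5)
    single = forward(tiny_model, x[0])
    np.testing.assert_allclose(batch[0], single, rtol=1e-5)


def test_gap_is_invariant_to_depth_for_constant_features():
    feat = np.full((1, 3, 4, 4, 8), 0.7, dtype=np.float32)
    pooled1, _ = global_avg_pool(feat)
    pooled2, _ = global_avg_pool(np.concatenate([feat, feat], axis=4))
    np.testing.assert_allclose(pooled1, pooled2, rtol=1e-6)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        ModelConfig(in_channels=3)
    with pytest.raises(ValueError):
        ModelConfig(stage_filters=(128, 64))
    with pytest.raises(ValueError):
        ModelConfig(decay_rate=0.0)


# -- focal loss --------------------------------------------------------------

def test_focal_loss_reduces_to_half_bce_at_gamma0():
    cfg = ModelConfig(focal_gamma=0.0, focal_alpha=0.5)
    p = np.array([0.2, 0.7, 0.9])
    y = np.array([1, 0, 1])
    bce = -(y * np.log(p) + (1 - y) * np.log(1 - p))
    np.testing.assert_allclose(focal_loss(p, y, cfg), 0.5 * bce, rtol=1e-12)


def test_focal_loss_vanishes_for_confident_correct():
    cfg = ModelConfig()
    assert focal_loss(1 - 1e-9, 1, cfg) < 1e-6
    assert focal_loss(0.5, 1, ModelConfig(focal_gamma=2.0, focal_alpha=0.25)) == pytest.approx(
        0.25 * 0.25 * np.log(2), rel=1e-10
    )


def test_focal_loss_gradient_matches_finite_difference():
    cfg = ModelConfig(focal_gamma=2.0, focal_alpha=0.25)
    for p in (0.2, 0.5, 0.9):
        for y in (0, 1):
            eps = 1e-6
            num = (focal_loss(p + eps, y, cfg) - focal_loss(p - eps, y, cfg)) / (2 * eps)
            assert focal_loss_grad(p, y, cfg) == pytest.approx(num, rel=1e-4)


def test_gradient_flow_is_finite_everywhere(tiny_model_config):
    m = build_model(tiny_model_config)
    x = np.moveaxis(_x((4, 16, 16, 12, 1), seed=2), -1, 1)
    y = np.array([1.0, 0.0, 1.0, 0.0])
    m.net.zero_grad()
    probs = m.net.forward(x, training=True)
    m.net.backward(focal_loss_grad(probs, y, tiny_model_config).astype(np.float32))
    for _, layer in m.net._layers():
        for k, g in layer.grads.items():
            assert np.isfinite(g).all()


# -- learning-rate schedule --------------------------------------------------

def test_lr_schedule_values_and_monotonicity():
    cfg = ModelConfig()
    assert lr_at(0, cfg) == pytest.approx(1e-4)
    assert lr_at(100_000, cfg) == pytest.approx(9.6e-5)
    steps = np.arange(0, 300_000, 25_000)
    lrs = [lr_at(int(s), cfg) for s in steps]
    assert all(a >= b for a, b in zip(lrs, lrs[1:]))


# -- checkpointing -----------------------------------------------------------

def test_checkpoint_roundtrip_preserves_outputs(tmp_path, tiny_model_config):
    m = build_model(tiny_model_config)
    x = _x((16, 16, 12, 1), seed=8)
    before = forward(m, x)
    path = tmp_path / "model.npz"
    save_model(m, path)
    loaded = load_model(path)
    assert loaded.fingerprint == m.fingerprint
    assert forward(loaded, x) == pytest.approx(before, rel=1e-6)
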