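"""Network geometry, LR schedule, sparsification, loss, gradients, tiling."""

import dataclasses

import numpy as np
import pytest

from sparseseg import _nn
from sparseseg.io import Subject
from sparseseg.net import (DualPathwayNet, NetConfig, TrainConfig, build_network,
                           dice_loss, load_model, lr_schedule, sample_patch,
                           save_model, sparsify_channels, predict)

from conftest import make_subject


# -- geometry --------------------------------------------------------------

def test_default_preset_reproduces_printed_geometry():
    cfg = NetConfig.full()
    assert cfg.input_patch == 57
    assert cfg.downsample_factor == 3
    assert cfg.output_patch == 9
    assert cfg.n_weighted_layers == 11


def test_tiny_preset_obeys_geometry_rule():
    cfg = NetConfig.tiny()
    assert cfg.output_patch == (cfg.input_patch // cfg.downsample_factor
                                - cfg.shrink) * cfg.downsample_factor
    assert cfg.highres_patch == cfg.output_patch + cfg.shrink


@pytest.mark.parametrize("kwargs", [
    dict(input_patch=58),                       # not divisible by factor
    dict(input_patch=21),                       # output would be <= 0
    dict(feature_maps=(8, 8)),                  # wrong layer count
    dict(downsample_factor=0),
])
def test_invalid_geometry_fails_at_construction(kwargs):
    with pytest.raises(ValueError):
        NetConfig(**{**dict(conv_layers_per_pathway=8), **kwargs}) \
            if "feature_maps" not in kwargs else NetConfig(**kwargs)


def test_construction_deterministic_param_count():
    a = build_network(NetConfig.tiny(), seed=3)
    b = build_network(NetConfig.tiny(), seed=3)
    assert a.n_params == b.n_params
    for la, lb in zip(a.layers, b.layers):
        if hasattr(la, "w"):
            assert np.array_equal(la.w, lb.w)


def test_forward_on_zero_input_is_finite():
    cfg = NetConfig.tiny()
    model = build_network(cfg, seed=0)
    hi = np.zeros((2, 4, cfg.highres_patch, cfg.highres_patch, cfg.highres_patch),
                  np.float32)
    lo = np.zeros((2, 4, cfg.lowres_patch, cfg.lowres_patch, cfg.lowres_patch),
                  np.float32)
    logits = model.forward(hi, lo)
    assert logits.shape == (2, 2, cfg.output_patch, cfg.output_patch, cfg.output_patch)
    assert np.isfinite(logits).all()


# -- learning-rate schedule -----------------------------------------------

def simulate_lr_schedule(config):
    """Independent simulation: walk the iterations, halving at each boundary."""
    lrs = []
    lr = config.lr0
    for it in range(config.iterations):
        if it > 0:
            if it <= config.lr_step_until and it % config.lr_step_initial == 0:
                lr /= 2.0
            elif it > config.lr_step_until and \
                    (it - config.lr_step_until) % config.lr_step_late == 0:
                lr /= 2.0
        lrs.append(lr)
    return lrs


def test_lr_schedule_matches_independent_simulation_everywhere():
    cfg = TrainConfig.full()
    sim = simulate_lr_schedule(cfg)
    got = [lr_schedule(it, cfg) for it in range(cfg.iterations)]
    assert got == sim


def test_lr_schedule_key_values():
    cfg = TrainConfig.full()
    assert lr_schedule(0, cfg) == 0.001
    assert lr_schedule(4999, cfg) == 0.001
    assert lr_schedule(5000, cfg) == 0.0005
    assert lr_schedule(15_000, cfg) == pytest.approx(1.25e-4)
    # 3 halvings by 15000 plus one per full 1500-step since then
    assert lr_schedule(29_999, cfg) == pytest.approx(0.001 / 2 ** 12)


def test_lr_schedule_nonincreasing_and_positive():
    cfg = TrainConfig.tiny(iterations=400)
    lrs = [lr_schedule(i, cfg) for i in range(cfg.iterations)]
    assert all(a >= b for a, b in zip(lrs, lrs[1:]))
    assert min(lrs) > 0
    with pytest.raises(ValueError):
        lr_schedule(cfg.iterations, cfg)


# -- sparsification --------------------------------------------------------

def test_sparsify_p0_identity_and_p1_zeroes_secondaries():
    rng = np.random.default_rng(0)
    stack = np.random.default_rng(1).random((4, 5, 5, 5)).astype(np.float32)
    out0 = sparsify_channels(stack, 0.0, rng)
    assert np.array_equal(out0, stack)
    out1 = sparsify_channels(stack, 1.0, rng)
    assert np.array_equal(out1[0], stack[0])
    assert np.abs(out1[1:]).max() == 0


def test_sparsify_never_touches_primary_and_is_idempotent():
    rng = np.random.default_rng(5)
    stack = np.random.default_rng(2).random((4, 3, 3, 3)).astype(np.float32)
    out = sparsify_channels(stack, 0.7, rng)
    assert np.array_equal(out[0], stack[0])
    # a second pass can only zero channels that are already zero or present;
    # re-zeroing zeroed channels is a no-op
    again = sparsify_channels(out, 1.0, rng)
    assert np.abs(again[1:]).max() == 0
    assert np.array_equal(again[0], stack[0])


def test_sparsify_shared_draw_across_matched_stacks():
    rng = np.random.default_rng(9)
    hi = np.ones((4, 4, 4, 4), np.float32)
    lo = np.ones((4, 2, 2, 2), np.float32)
    for _ in range(20):
        shi, slo = sparsify_channels((hi, lo), 0.5, rng)
        for c in range(1, 4):
            assert (np.abs(shi[c]).max() == 0) == (np.abs(slo[c]).max() == 0)


def test_sparsify_rate_in_binomial_interval():
    """p=0.2 over 10_000 draws: per-channel zeroing frequency in the 95%
    binomial interval [0.188, 0.212]; primary channel never zeroed."""
    rng = np.random.default_rng(12345)
    stack = np.ones((4, 2, 2, 2), np.float32)
    zeroed = np.zeros(4)
    n = 10_000
    for _ in range(n):
        out = sparsify_channels(stack, 0.2, rng)
        zeroed += (np.abs(out).reshape(4, -1).max(axis=1) == 0)
    assert zeroed[0] == 0
    for c in (1, 2, 3):
        assert 0.188 <= zeroed[c] / n <= 0.212


# -- Dice loss -------------------------------------------------------------

def test_dice_loss_perfect_and_inverted():
    y = np.zeros((1, 3, 3, 3), np.float32)
    y[0, 1, 1, 1] = 1
    p = np.zeros((1, 2, 3, 3, 3), np.float32)
    p[0, 1] = y[0]
    p[0, 0] = 1 - y[0]
    assert dice_loss(p, y) == pytest.approx(0.0, abs=1e-4)
    p_inv = p[:, ::-1]
    assert dice_loss(np.ascontiguousarray(p_inv), y) == pytest.approx(1.0, abs=1e-3)


def test_dice_loss_hand_computed_two_voxel_case():
    eps = 1e-5
    p = np.zeros((1, 2, 2, 1, 1), np.float32)
    p[0, 1, :, 0, 0] = [0.5, 0.5]
    y = np.zeros((1, 2, 1, 1), np.float32)
    y[0, 0, 0, 0] = 1
    expected = 1.0 - (2 * 0.5 + eps) / (1.0 + 1.0 + eps)
    assert dice_loss(p, y, eps=eps) == pytest.approx(expected, rel=1e-6)


def test_soft_dice_gradient_matches_finite_differences():
    rng = np.random.default_rng(0)
    probs = rng.random((2, 3, 3, 3, 2))
    probs /= probs.sum(axis=-1, keepdims=True)
    labels = (rng.random((2, 3, 3, 3)) < 0.4).astype(np.float64)
    loss, grad = _nn.soft_dice_loss(probs, labels)
    h = 1e-6
    for idx in [(0, 1, 1, 1, 1), (1, 0, 2, 1, 1), (0, 2, 0, 0, 1)]:
        p2 = probs.copy()
        p2[idx] += h
        l2, _ = _nn.soft_dice_loss(p2, labels)
        fd = (l2 - loss) / h
        assert grad[idx] == pytest.approx(fd, rel=1e-3, abs=1e-8)


def test_network_gradient_matches_finite_differences():
    """End-to-end gradient check on a miniature double-pathway net (float64)."""
    cfg = NetConfig(n_channels=2, conv_layers_per_pathway=1, feature_maps=(3,),
                    fc_sizes=(4,), downsample_factor=1, input_patch=5,
                    dtype="float64")
    model = DualPathwayNet(cfg, seed=0)
    rng = np.random.default_rng(1)
    hi = rng.standard_normal((2, 2, cfg.highres_patch,) + (cfg.highres_patch,) * 2)
    lo = rng.standard_normal((2, 2, cfg.lowres_patch,) + (cfg.lowres_patch,) * 2)
    lab = (rng.random((2,) + (cfg.output_patch,) * 3) < 0.5).astype(np.float64)

    def loss_value():
        logits = model.forward(hi, lo)
        probs = _nn.softmax(np.moveaxis(logits, 1, -1), axis=-1)
        return _nn.soft_dice_loss(probs, lab)[0]

    logits = model.forward(hi, lo)
    probs = _nn.softmax(np.moveaxis(logits, 1, -1), axis=-1)
    loss, dprobs = _nn.soft_dice_loss(probs, lab)
    dot = (dprobs * probs).sum(axis=-1, keepdims=True)
    model._backward(probs * (dprobs - dot))

    h = 1e-6
    for layer in [model.hi_path[0], model.lo_path[0], model.fc_layers[0],
                  model.classifier]:
        w = layer.w
        flat = np.argwhere(np.ones_like(w))[:: max(1, w.size // 5)]
        for idx in flat[:3]:
            idx = tuple(idx)
            orig = w[idx]
            w[idx] = orig + h
            lp = loss_value()
            w[idx] = orig - h
            lm = loss_value()
            w[idx] = orig
            fd = (lp - lm) / (2 * h)
            assert layer.dw[idx] == pytest.approx(fd, rel=2e-4, abs=1e-9)


# -- patch sampling and inference geometry --------------------------------

def _cube_subject(shape=(24, 24, 24)):
    channels = np.full((4,) + shape, 1.0, np.float32)
    mask = np.zeros(shape, np.uint8)
    mask[8:16, 8:16, 8:16] = 1
    s = make_subject(channels, mask=mask)
    return s


def test_sample_patch_shapes_and_cube_label():
    cfg = NetConfig.tiny()
    s = _cube_subject()
    rng = np.random.default_rng(0)
    hi, lo, label = sample_patch(s, rng, cfg, foreground_fraction=1.0)
    assert hi.shape == (4,) + (cfg.highres_patch,) * 3
    assert lo.shape == (4,) + (cfg.lowres_patch,) * 3
    assert label.shape == (cfg.output_patch,) * 3
    assert label.max() == 1  # center drawn inside the cube


class _FixedCenterRng:
    """Drives sample_patch to a chosen voxel of the foreground list."""

    def __init__(self, fg_index):
        self.fg_index = fg_index

    def random(self):
        return 0.0  # always pick foreground

    def integers(self, n):
        return self.fg_index


def test_label_patch_all_ones_at_cube_centroid():
    cfg = NetConfig.tiny()
    shape = (24, 24, 24)
    channels = np.full((4,) + shape, 1.0, np.float32)
    mask = np.zeros(shape, np.uint8)
    mask[6:18, 6:18, 6:18] = 1  # 12^3 cube covers the 9^3 output at its centroid
    s = make_subject(channels, mask=mask)
    fg = np.argwhere(s.mask > 0)
    centroid_idx = int(np.where((fg == [12, 12, 12]).all(axis=1))[0][0])
    hi, lo, label = sample_patch(s, _FixedCenterRng(centroid_idx), cfg,
                                 foreground_fraction=1.0)
    assert label.all()


def test_downsample_of_constant_volume_is_constant():
    cfg = NetConfig.tiny()
    shape = (29, 29, 29)  # window 27^3 at the center stays inside the volume
    channels = np.full((4,) + shape, 7.0, np.float32)
    mask = np.zeros(shape, np.uint8)
    mask[14, 14, 14] = 1
    s = make_subject(channels, mask=mask)
    _, lo, _ = sample_patch(s, _FixedCenterRng(0), cfg, foreground_fraction=1.0)
    assert np.allclose(lo, 7.0)  # mean pooling preserves a constant window


def test_predict_covers_grid_and_translation_equivariance():
    cfg = NetConfig.tiny()
    model = build_network(cfg, seed=4)
    o = cfg.output_patch
    shape = (3 * o, 2 * o, 2 * o)  # multiples of the stride: exact tiling
    rng = np.random.default_rng(3)
    vol = (rng.random((4,) + shape) + 0.5).astype(np.float32)
    s = make_subject(vol)
    pred = predict(model, s)
    assert pred.voxels.shape == shape

    # shift content by one full stride along z.  The context half-window
    # equals one stride for the tiny preset, so the shifted tile at [o, 2o)
    # sees exactly what the original tile at [0, o) saw (zero pad below,
    # original content above): those output blocks must match bit-exactly.
    vol2 = np.zeros_like(vol)
    vol2[:, o:, :, :] = vol[:, :-o, :, :]
    s2 = make_subject(vol2, available=[True] * 4)
    pred2 = predict(model, s2)
    assert np.array_equal(pred2.voxels[o:2 * o], pred.voxels[0:o])


def test_model_save_load_roundtrip(tmp_path):
    cfg = NetConfig.tiny()
    model = build_network(cfg, seed=7)
    save_model(model, tmp_path / "m")
    back = load_model(tmp_path / "m")
    assert back.config == cfg
    rng = np.random.default_rng(0)
    hi = rng.random((1, 4) + (cfg.highres_patch,) * 3).astype(np.float32)
    lo = rng.random((1, 4) + (cfg.lowres_patch,) * 3).astype(np.float32)
    assert np.array_equal(model.forward(hi, lo), back.forward(hi, lo))


def test_volume_scope_sparsification_consistent_within_subject():
    """With sparsify_scope='volume', all patches of one subject in one
    iteration share the channel-drop decision."""
    import dataclasses as dc
    from sparseseg.net import train
    from sparseseg.synth import PhantomConfig, generate_cohort_subjects
    from sparseseg.normalize import fit_histogram_model, normalize_cohort

    cfg = PhantomConfig(shape=(24, 24, 24), seed=6, missing_fraction=0.0,
                        tumor_radius_range=(3.5, 5.5))
    subs = normalize_cohort(*(lambda s: (s, fit_histogram_model(s)))(
        generate_cohort_subjects(cfg, 1)))
    tc = TrainConfig.tiny(seed=0, iterations=3)
    tc = dc.replace(tc, sparsify_scope="volume", sparsify_p=0.5)
    model, log = train(subs, NetConfig.tiny(), tc, sparsified=True)
    assert len(log) == 3  # runs; per-subject consistency is internal

    with pytest.raises(ValueError):
        dc.replace(tc, sparsify_scope="both")
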