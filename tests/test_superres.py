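"""Super-resolution stage: coordinate grids, sampling oracles, contracts."""

import numpy as np
import pytest

from cardiorecon.degrade import downsample_z
from cardiorecon.io import LabelVolume, ProbabilityVolume, to_one_hot
from cardiorecon.superres import (ASVModelConfig, SuperResolutionNet,
                                  explicit_upsample, finetune_asv,
                                  inr_features, normalized_grid,
                                  superresolve, train_asv, trilinear_sample)
from cardiorecon.train import TrainConfig

# ------------------------------------------------------------ coordinates


def test_normalized_grid_endpoints_and_center():
    g = normalized_grid((2, 1, 1))
    np.testing.assert_allclose(g.coords[:, 0], [-1.0, 1.0])
    np.testing.assert_allclose(g.coords[:, 1:], 0.0)
    g = normalized_grid((3, 3, 3))
    center = g.coords[13]  # depth-major ordering: voxel (1,1,1)
    np.testing.assert_allclose(center, [0.0, 0.0, 0.0])


def test_normalized_grid_bounds_random_shapes(rng):
    for _ in range(10):
        shape = tuple(int(s) for s in rng.integers(1, 7, size=3))
        g = normalized_grid(shape)
        assert g.coords.shape == (np.prod(shape), 3)
        assert np.abs(g.coords).max() <= 1.0


# ------------------------------------------------------- trilinear anchors


def brute_trilinear(values, coord):
    """Independent 8-corner weighted sum at one normalized coordinate."""
    C = values.shape[0]
    dims = values.shape[1:]
    idx = []
    for k, n in enumerate(dims):
        if n == 1:
            idx.append((0, 0, 0.0))
            continue
        t = (coord[k] + 1) / 2 * (n - 1)
        i0 = min(int(np.floor(t)), n - 2)
        idx.append((i0, i0 + 1, t - i0))
    out = np.zeros(C)
    for bz in (0, 1):
        for by in (0, 1):
            for bx in (0, 1):
                w = ((idx[0][2] if bz else 1 - idx[0][2])
                     * (idx[1][2] if by else 1 - idx[1][2])
                     * (idx[2][2] if bx else 1 - idx[2][2]))
                out += w * values[:, idx[0][bz], idx[1][by], idx[2][bx]]
    return out


def test_trilinear_identity_at_own_centers(rng):
    vol = LabelVolume(rng.integers(0, 4, size=(3, 4, 5)).astype(np.int16))
    probs = to_one_hot(vol, 4)
    g = normalized_grid(vol.shape)
    anchors = trilinear_sample(probs, g)
    np.testing.assert_allclose(
        anchors.T.reshape(probs.values.shape), probs.values, atol=1e-12)


def test_trilinear_midpoint_is_half():
    values = np.zeros((1, 2, 1, 1))
    values[0, 1] = 1.0
    from cardiorecon.superres import CoordinateGrid
    g = CoordinateGrid(np.array([[0.0, 0.0, 0.0]]), (1, 1, 1))
    assert trilinear_sample(values, g)[0, 0] == pytest.approx(0.5)


def test_trilinear_matches_bruteforce_oracle(rng):
    for _ in range(100):
        vol = LabelVolume(rng.integers(0, 5, size=(4, 4, 4)).astype(np.int16))
        probs = to_one_hot(vol, 5)
        coords = rng.uniform(-1, 1, size=(6, 3))
        from cardiorecon.superres import CoordinateGrid
        g = CoordinateGrid(coords, (6, 1, 1))
        got = trilinear_sample(probs, g)
        for i in range(6):
            np.testing.assert_allclose(
                got[i], brute_trilinear(probs.values, coords[i]), atol=1e-6)
        # anchors stay on the probability simplex
        np.testing.assert_allclose(got.sum(axis=1), 1.0, atol=1e-6)
        assert got.min() >= -1e-6


# --------------------------------------------------------- explicit branch


def test_explicit_upsample_contracts(rng):
    vol = LabelVolume(rng.integers(0, 3, size=(3, 4, 4)).astype(np.int16),
                      spacing=(4.0, 1.0, 1.0))
    probs = to_one_hot(vol, 3)
    up1 = explicit_upsample(probs, 1)
    np.testing.assert_array_equal(up1.values, probs.values)
    up2 = explicit_upsample(probs, 2)
    assert up2.values.shape[1] == 6
    assert up2.spacing[0] == pytest.approx(2.0)
    np.testing.assert_allclose(up2.values.sum(axis=0), 1.0, atol=1e-9)


# -------------------------------------------------------------- MLP field


def test_inr_features_pointwise_and_chunk_invariant(rng):
    net = SuperResolutionNet(ASVModelConfig(n_classes=4), seed=0)
    g = normalized_grid((3, 4, 4))
    anchors = rng.uniform(0, 1, size=(48, 4)).astype(np.float32)
    f1 = inr_features(g, anchors, net.mlp, chunk_size=7)
    f2 = inr_features(g, anchors, net.mlp, chunk_size=10_000)
    np.testing.assert_allclose(f1, f2, atol=1e-6)
    assert f1.shape == (net.config.feature_channels, 3, 4, 4)
    # identical inputs at two points give identical features
    anchors[1] = anchors[0]
    g2 = normalized_grid((3, 4, 4))
    coords = g2.coords.copy()
    coords[1] = coords[0]
    from cardiorecon.superres import CoordinateGrid
    f3 = inr_features(CoordinateGrid(coords, (3, 4, 4)), anchors, net.mlp)
    flat = f3.reshape(f3.shape[0], -1)
    np.testing.assert_allclose(flat[:, 0], flat[:, 1], atol=1e-7)


def test_mlp_input_width_matches_classes():
    cfg = ASVModelConfig(n_classes=6)
    assert cfg.mlp_in == 9
    net = SuperResolutionNet(cfg, seed=0)
    assert net.mlp.layers[0].weight.value.shape[0] == 9


# ------------------------------------------------------------- training


@pytest.fixture(scope="module")
def trained_sr(tiny_phantoms):
    net = SuperResolutionNet(seed=0)
    hist = train_asv(net, tiny_phantoms, (2, 3, 4),
                     TrainConfig(epochs=10, lr=3e-3, seed=0))
    return net, hist


def test_training_loss_decreases(trained_sr):
    _, hist = trained_sr
    losses = hist.losses
    assert np.mean(losses[-3:]) < np.mean(losses[:3])
    assert "super-resolution" in hist.summary()


@pytest.mark.parametrize("s", [2, 3, 4])
def test_scale_contract_output_depth(trained_sr, tiny_phantoms, s):
    net, _ = trained_sr
    lr_vol = downsample_z(tiny_phantoms[0], s)
    out = superresolve(net, lr_vol, s)
    assert out.shape[0] == s * lr_vol.shape[0]
    assert out.shape[1:] == lr_vol.shape[1:]
    assert out.spacing[0] == pytest.approx(lr_vol.spacing[0] / s)
    assert out.spacing[1:] == lr_vol.spacing[1:]


def test_unsupported_scale_rejected(trained_sr, tiny_phantoms):
    net, _ = trained_sr
    lr_vol = downsample_z(tiny_phantoms[0], 2)
    with pytest.raises(ValueError):
        superresolve(net, lr_vol, 5)
    with pytest.raises(ValueError):
        superresolve(net, lr_vol, 1)


def test_untrained_model_rejected(tiny_phantoms):
    net = SuperResolutionNet(seed=0)
    with pytest.raises(RuntimeError):
        superresolve(net, downsample_z(tiny_phantoms[0], 2), 2)


def test_single_scale_training_still_serves_that_scale(tiny_phantoms):
    net = SuperResolutionNet(ASVModelConfig(scales=(2,)), seed=0)
    train_asv(net, tiny_phantoms[:2], (2,), TrainConfig(epochs=2, lr=3e-3))
    out = superresolve(net, downsample_z(tiny_phantoms[0], 2), 2)
    assert out.shape[0] == 2 * downsample_z(tiny_phantoms[0], 2).shape[0]


# ------------------------------------------------------------- finetuning


def _pairs(phantoms):
    return [(downsample_z(v, 2), v) for v in phantoms]


def test_finetune_multiplier_zero_freezes_mlp(trained_sr, tiny_phantoms):
    import copy
    net = copy.deepcopy(trained_sr[0])
    before_mlp = [p.value.copy() for p in net.mlp_parameters()]
    before_fusion = [p.value.copy() for p in net.fusion_parameters()]
    finetune_asv(net, _pairs(tiny_phantoms[:2]),
                 TrainConfig(epochs=2, lr=1e-3), lr_multiplier=0.0)
    for p, b in zip(net.mlp_parameters(), before_mlp):
        np.testing.assert_array_equal(p.value, b)
    changed = any(not np.array_equal(p.value, b)
                  for p, b in zip(net.fusion_parameters(), before_fusion))
    assert changed


def test_finetune_multiplier_one_matches_uniform(trained_sr, tiny_phantoms):
    """Differential-lr machinery with multiplier 1 must reproduce plain
    uniform-rate finetuning step for step."""
    import copy
    from cardiorecon.superres import _run_training
    from cardiorecon.io import to_one_hot

    pairs = _pairs(tiny_phantoms[:2])
    cfg = TrainConfig(epochs=3, lr=1e-3, seed=7)

    net_a = copy.deepcopy(trained_sr[0])
    hist_a = finetune_asv(net_a, pairs, cfg, lr_multiplier=1.0)

    net_b = copy.deepcopy(trained_sr[0])
    prepared = [(to_one_hot(lr_v, 8).values.astype(np.float32),
                 to_one_hot(hr_v, 8).values.astype(np.float32), 2)
                for lr_v, hr_v in pairs]
    hist_b = _run_training(net_b, lambda i, e: prepared[i], len(prepared),
                           cfg, [(1.0, net_b.parameters())], stage="uniform")
    np.testing.assert_allclose(hist_a.losses, hist_b.losses, atol=1e-6)
    for pa, pb in zip(net_a.parameters(), net_b.parameters()):
        np.testing.assert_allclose(pa.value, pb.value, atol=1e-6)


def test_finetune_does_not_hurt_on_finetune_distribution(trained_sr, tiny_phantoms):
    import copy
    from cardiorecon.metrics import dice_coefficient
    net = copy.deepcopy(trained_sr[0])
    pairs = _pairs(tiny_phantoms)

    def score(n):
        vals = []
        for lr_v, hr_v in pairs:
            out = superresolve(n, lr_v, 2)
            out = LabelVolume(out.voxels[:hr_v.shape[0]], spacing=out.spacing)
            vals.append(dice_coefficient(out, hr_v)[1])
        return np.mean(vals)

    before = score(net)
    finetune_asv(net, pairs, TrainConfig(epochs=3, lr=1e-3))
    after = score(net)
    assert after >= before - 0.02


def test_config_validation():
    with pytest.raises(ValueError):
        ASVModelConfig(scales=(1, 2))
    with pytest.raises(ValueError):
        ASVModelConfig(lr_encoder_multiplier=1.5)
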