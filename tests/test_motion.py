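"""Motion-correction stage: shape contracts, loss math, transfer protocol."""

import copy

import numpy as np
import pytest

from cardiorecon.degrade import severity_preset
from cardiorecon.io import LabelVolume, ProbabilityVolume, to_one_hot
from cardiorecon.motion import (DSLModelConfig, ShapePriorAutoencoder,
                                build_dsl_model, combined_loss, correct,
                                decode, encode, finetune_mri, pretrain_ct)
from cardiorecon.train import TrainConfig

# --------------------------------------------------------- shape contracts


def test_latent_shape_contract():
    model = build_dsl_model(seed=0)
    x = ProbabilityVolume(
        to_one_hot(LabelVolume(np.zeros((6, 32, 32), np.int16)), 8).values)
    z = encode(model, x)
    assert z.shape == (64, 6, 8, 8)


@pytest.mark.parametrize("shape", [(4, 16, 16), (6, 32, 24), (3, 8, 8)])
def test_roundtrip_shape_and_simplex(shape, rng):
    model = build_dsl_model(seed=1)
    vol = LabelVolume(rng.integers(0, 8, size=shape).astype(np.int16))
    x = to_one_hot(vol, 8)
    z = encode(model, x)
    assert z.shape[0] == 64
    assert z.shape[1] == shape[0]
    assert z.shape[2:] == (shape[1] // 4, shape[2] // 4)
    probs = decode(model, z)
    assert probs.values.shape == x.values.shape
    np.testing.assert_allclose(probs.values.sum(axis=0), 1.0, atol=1e-6)
    assert np.isfinite(probs.values).all()


def test_indivisible_inplane_dims_rejected():
    model = build_dsl_model(seed=0)
    x = to_one_hot(LabelVolume(np.zeros((4, 10, 16), np.int16)), 8)
    with pytest.raises(ValueError, match="divisible"):
        encode(model, x)


def test_same_seed_builds_identical_models():
    a = build_dsl_model(seed=3)
    b = build_dsl_model(seed=3)
    assert a.encoder_checksum() == b.encoder_checksum()
    assert a.decoder_checksum() == b.decoder_checksum()
    c = build_dsl_model(seed=4)
    assert c.encoder_checksum() != a.encoder_checksum()


def test_encode_deterministic(rng):
    model = build_dsl_model(seed=0)
    x = to_one_hot(LabelVolume(rng.integers(0, 8, size=(4, 16, 16))
                               .astype(np.int16)), 8)
    z1 = encode(model, x)
    z2 = encode(model, x)
    np.testing.assert_array_equal(z1.values, z2.values)


def test_config_validation():
    with pytest.raises(ValueError):
        DSLModelConfig(n_pool_stages=0, conv_channels=())
    with pytest.raises(ValueError):
        DSLModelConfig(conv_channels=(8,))  # one width for two stages


# ------------------------------------------------------------- loss maths


def scalar_loss(pred, target, lam1, lam2, eps):
    """Straightforward per-element reference implementation."""
    C = pred.shape[0]
    n_vox = pred[0].size
    l1 = 0.0
    inter = 0.0
    denom = eps
    for c in range(C):
        p = pred[c].ravel()
        y = target[c].ravel()
        for i in range(n_vox):
            l1 += abs(p[i] - y[i])
            inter += p[i] * y[i]
            denom += p[i] ** 2 + y[i] ** 2
    l1 /= n_vox
    dice = 1.0 - 2.0 * inter / denom
    return lam1 * l1 + lam2 * dice, l1, dice


def test_loss_single_voxel_worked_example():
    pred = np.array([0.6, 0.4]).reshape(2, 1, 1, 1)
    target = np.array([1.0, 0.0]).reshape(2, 1, 1, 1)
    parts = combined_loss(pred, target, lam1=0.5, lam2=0.5, eps=1e-5)
    assert parts.l1 == pytest.approx(0.8)
    assert parts.dice == pytest.approx(1 - 1.2 / (0.36 + 0.16 + 1.0 + 1e-5))
    ref_total, ref_l1, ref_dice = scalar_loss(pred, target, 0.5, 0.5, 1e-5)
    assert parts.total == pytest.approx(ref_total, abs=1e-12)
    assert parts.total == pytest.approx(0.5053, abs=1e-4)


def test_loss_identity_and_disjoint():
    y = np.zeros((3, 2, 2, 2), np.float64)
    y[0] = 1.0
    parts = combined_loss(y, y)
    assert parts.l1 == 0.0
    assert parts.dice == pytest.approx(0.0, abs=1e-5)
    other = np.zeros_like(y)
    other[1] = 1.0
    parts = combined_loss(other, y)
    assert parts.dice == pytest.approx(1.0, abs=1e-5)


def test_loss_matches_scalar_reference_on_random_tensors(rng):
    for _ in range(5):
        pred = rng.uniform(0, 1, size=(3, 2, 3, 2))
        target = np.moveaxis(np.eye(3)[rng.integers(0, 3, size=(2, 3, 2))],
                             -1, 0)
        parts = combined_loss(pred, target, lam1=0.7, lam2=0.3, eps=1e-5)
        ref_total, ref_l1, ref_dice = scalar_loss(pred, target, 0.7, 0.3, 1e-5)
        assert parts.total == pytest.approx(ref_total, abs=1e-6)
        assert parts.l1 == pytest.approx(ref_l1, abs=1e-6)
        assert parts.dice == pytest.approx(ref_dice, abs=1e-6)


def test_loss_rejects_bad_weights_and_shapes():
    y = np.zeros((2, 1, 1, 1))
    with pytest.raises(ValueError):
        combined_loss(y, y, lam1=0.0)
    with pytest.raises(ValueError):
        combined_loss(y, np.zeros((3, 1, 1, 1)))


# ----------------------------------------------------- training contracts

SMALL_CFG = DSLModelConfig(conv_channels=(4, 8), latent_channels=16)


@pytest.fixture(scope="module")
def pretrained_small(tiny_phantoms):
    model = ShapePriorAutoencoder(SMALL_CFG, seed=0)
    hist = pretrain_ct(model, tiny_phantoms, severity_preset("medium"),
                       TrainConfig(epochs=8, lr=3e-3, seed=0))
    return model, hist


def test_pretraining_loss_decreases(pretrained_small):
    _, hist = pretrained_small
    assert hist.losses[-1] < hist.losses[0]
    assert len(hist.history) == 8
    assert "pretrain" in hist.summary()


def test_pretraining_deterministic(tiny_phantoms):
    losses = []
    for _ in range(2):
        model = ShapePriorAutoencoder(SMALL_CFG, seed=5)
        hist = pretrain_ct(model, tiny_phantoms[:2], severity_preset("easy"),
                           TrainConfig(epochs=2, lr=1e-3, seed=9))
        losses.append(hist.final_loss)
    assert losses[0] == losses[1]


def test_finetune_freezes_decoder_exactly(pretrained_small, tiny_phantoms):
    model = copy.deepcopy(pretrained_small[0])
    dec_before = model.decoder_checksum()
    enc_before = model.encoder_checksum()
    pairs = [(v, v) for v in tiny_phantoms[:2]]
    finetune_mri(model, pairs, TrainConfig(epochs=2, lr=1e-3, seed=0))
    assert model.decoder_checksum() == dec_before
    assert model.encoder_checksum() != enc_before


def test_finetune_warns_on_unpretrained(tiny_phantoms):
    model = ShapePriorAutoencoder(SMALL_CFG, seed=0)
    with pytest.warns(UserWarning, match="unpretrained"):
        finetune_mri(model, [(tiny_phantoms[0], tiny_phantoms[0])],
                     TrainConfig(epochs=1, lr=1e-4))


def test_correct_output_labels_valid(pretrained_small, tiny_phantoms):
    model = pretrained_small[0]
    out = correct(model, tiny_phantoms[0])
    assert out.shape == tiny_phantoms[0].shape
    assert out.spacing == tiny_phantoms[0].spacing
    assert 0 <= out.voxels.min() and out.voxels.max() <= 7


def test_correct_autopads_odd_inplane_dims(pretrained_small):
    model = pretrained_small[0]
    vol = LabelVolume(np.ones((4, 10, 14), np.int16))
    out = correct(model, vol)
    assert out.shape == (4, 10, 14)


def test_correct_requires_trained_model():
    model = ShapePriorAutoencoder(SMALL_CFG, seed=0)
    with pytest.raises(RuntimeError):
        correct(model, LabelVolume(np.zeros((4, 8, 8), np.int16)))


def test_empty_dataset_rejected():
    model = ShapePriorAutoencoder(SMALL_CFG, seed=0)
    with pytest.raises(ValueError):
        pretrain_ct(model, [], severity_preset("easy"))
    with pytest.raises(ValueError):
        finetune_mri(model, [])


def test_checkpoint_round_trip(tmp_path, pretrained_small):
    model = pretrained_small[0]
    model.save(tmp_path / "ckpt.npz")
    back = ShapePriorAutoencoder.load(tmp_path / "ckpt.npz")
    assert back.encoder_checksum() == model.encoder_checksum()
    assert back.decoder_checksum() == model.decoder_checksum()
    assert back.trained
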