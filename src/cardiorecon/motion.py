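"""Inter-slice motion correction via a learned anatomical shape prior.

The corrector is a 3D convolutional autoencoder with *anisotropic*
down/upsampling: pooling and upsampling act only in-plane with kernel
(1, 2, 2), so the latent representation — the *latent volume map*
``Z`` of shape ``(C_latent, D, H/4, W/4)`` — keeps every slice of the input
stack while compressing in-plane detail by a factor 4 per axis.  Compressing
the plane forces the code to discard high-frequency boundary jitter (the
signature of slice misalignment) and keep only the dominant chamber
topology; preserving the depth axis keeps the slice-wise progression of the
anatomy addressable, which is what makes the autoencoder a *motion*
corrector rather than a generic denoiser.

Training follows a cross-domain transfer protocol:

1. *pretraining* on clean volumes paired with freshly degraded copies
   (regenerated every epoch, i.e. degradation as augmentation), so the
   manifold is learned from geometry that was never motion-corrupted;
2. *finetuning* on target-domain pairs with the decoder frozen — only the
   encoder adapts to the target distribution, while the decoder keeps
   producing shapes from the clean manifold.

Inference (:func:`correct`) projects a corrupted stack onto the manifold:
one-hot encode, encode/decode, argmax.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .degrade import DegradationConfig, degrade, severity_preset
from .io import (LabelVolume, ProbabilityVolume, argmax_labels, to_one_hot,
                 upsample_z_repeat)
from .train import TrainConfig, TrainingResults, smooth_targets

__all__ = [
    "DSLModelConfig",
    "LatentVolumeMap",
    "ShapePriorAutoencoder",
    "MotionCorrectionModel",
    "MotionCorrectionResults",
    "build_dsl_model",
    "encode",
    "decode",
    "combined_loss",
    "pretrain_ct",
    "finetune_mri",
    "correct",
]


@dataclass(frozen=True)
class DSLModelConfig:
    """Architecture of the shape-prior autoencoder.

    ``n_pool_stages`` (1, 2, 2)-poolings give an in-plane compression of
    ``2 ** n_pool_stages`` per axis (default 4).  ``conv_channels`` are the
    per-stage widths before the ``latent_channels``-wide latent map.
    """

    in_channels: int = 8
    latent_channels: int = 64
    n_pool_stages: int = 2
    conv_channels: tuple[int, ...] = (8, 16)
    decoder_refine_convs: int = 1
    #: residual connection from the one-hot input to the output logits used
    #: by the full correction pass.  Starting from (a scaled copy of) the
    #: input keeps rare small structures — which would otherwise lose the
    #: softmax competition for the whole training run — trainable at desk
    #: scale; the autoencoder path learns the correction on top.  0 disables.
    input_residual_init: float = 3.0

    def __post_init__(self):
        if self.n_pool_stages < 1:
            raise ValueError("need at least one pooling stage")
        if len(self.conv_channels) != self.n_pool_stages:
            raise ValueError("one conv width per pooling stage required")
        if self.in_channels < 2 or self.latent_channels < 1:
            raise ValueError("invalid channel configuration")

    @property
    def inplane_factor(self) -> int:
        return 2 ** self.n_pool_stages


@dataclass(frozen=True)
class LatentVolumeMap:
    """Spatially preserved compressed code: ``(C_latent, D, H/f, W/f)``."""

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        if self.values.ndim != 4:
            raise ValueError("latent volume map must be 4D")

    @property
    def shape(self):
        return self.values.shape


def _param_checksum(params: list[nn.Parameter]) -> str:
    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p.value).tobytes())
    return h.hexdigest()


class ShapePriorAutoencoder:
    """Encoder/decoder pair realizing the latent-volume-map architecture."""

    def __init__(self, config: DSLModelConfig | None = None, seed: int = 0):
        self.config = config if config is not None else DSLModelConfig()
        rng = np.random.default_rng(seed)
        cfg = self.config
        enc: list[nn.Layer] = []
        prev = cfg.in_channels
        for width in cfg.conv_channels:
            enc += [nn.Conv3d(prev, width, rng=rng), nn.InstanceNorm(width),
                    nn.ReLU(), nn.MaxPoolInPlane()]
            prev = width
        enc.append(nn.Conv3d(prev, cfg.latent_channels, rng=rng))
        self.encoder = nn.Sequential(*enc)

        dec: list[nn.Layer] = [nn.Conv3d(cfg.latent_channels,
                                         cfg.conv_channels[-1], rng=rng),
                               nn.InstanceNorm(cfg.conv_channels[-1]),
                               nn.ReLU()]
        widths = list(cfg.conv_channels)
        for i in range(len(widths) - 1, 0, -1):
            dec += [nn.UpsampleInPlane(),
                    nn.Conv3d(widths[i], widths[i - 1], rng=rng),
                    nn.InstanceNorm(widths[i - 1]), nn.ReLU()]
        dec.append(nn.UpsampleInPlane())
        # full-resolution refinement: nearest upsampling alone leaves 2x2
        # blocks, so boundary sharpness needs at least one conv at full res
        for _ in range(cfg.decoder_refine_convs):
            dec += [nn.Conv3d(widths[0], widths[0], rng=rng),
                    nn.InstanceNorm(widths[0]), nn.ReLU()]
        final = nn.Conv3d(widths[0], cfg.in_channels, rng=rng)
        # zero-initialized logits: training starts from uniform class
        # probabilities instead of a random (and quickly saturating) state
        final.weight.value[...] = 0.0
        dec.append(final)
        self.decoder = nn.Sequential(*dec)
        # counted with the decoder parameters, so the finetune freeze
        # covers it as well
        self.residual_scale = nn.Parameter(
            np.array(cfg.input_residual_init, dtype=np.float32),
            name="input_residual_scale")
        self.trained = False
        self._cache: tuple[np.ndarray, np.ndarray] | None = None
        self._probs: np.ndarray | None = None

    # -- parameter access ---------------------------------------------------
    def encoder_parameters(self) -> list[nn.Parameter]:
        return self.encoder.parameters()

    def decoder_parameters(self) -> list[nn.Parameter]:
        return self.decoder.parameters() + [self.residual_scale]

    def parameters(self) -> list[nn.Parameter]:
        return self.encoder_parameters() + self.decoder_parameters()

    def encoder_checksum(self) -> str:
        return _param_checksum(self.encoder_parameters())

    def decoder_checksum(self) -> str:
        return _param_checksum(self.decoder_parameters())

    # -- forward / backward -------------------------------------------------
    def _check_divisible(self, shape) -> None:
        f = self.config.inplane_factor
        if shape[1] % f or shape[2] % f:
            raise ValueError(
                f"in-plane dims {shape[1:]} must be divisible by {f}")

    def encode_values(self, x: np.ndarray) -> np.ndarray:
        self._check_divisible(x.shape[1:])
        return self.encoder.forward(x)

    def decode_values(self, z: np.ndarray) -> np.ndarray:
        logits = self.decoder.forward(z)
        self._probs = nn.softmax_channels(logits)
        return self._probs

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Full correction pass: autoencoder logits plus the scaled
        input-residual path, softmaxed to probabilities."""
        logits = self.decoder.forward(self.encoder.forward(x))
        logits = logits + self.residual_scale.value * x
        probs = nn.softmax_channels(logits)
        self._cache = (probs, x)
        return probs

    def backward(self, dprobs: np.ndarray) -> None:
        if self._cache is None:
            raise RuntimeError("backward requires a prior forward pass")
        probs, x = self._cache
        dlogits = nn.softmax_backward(probs, dprobs)
        self.residual_scale.grad += (dlogits * x).sum()
        self.encoder.backward(self.decoder.backward(dlogits))
        self._cache = None

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint as ``.npz`` parameters plus a JSON manifest sidecar."""
        path = Path(path)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.parameters())}
        np.savez_compressed(path, **arrays)
        manifest = {"config": asdict(self.config), "trained": self.trained,
                    "encoder_checksum": self.encoder_checksum(),
                    "decoder_checksum": self.decoder_checksum()}
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path) -> "ShapePriorAutoencoder":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        cfg_d = manifest["config"]
        cfg_d["conv_channels"] = tuple(cfg_d["conv_channels"])
        model = cls(DSLModelConfig(**cfg_d))
        with np.load(path if path.suffix == ".npz"
                     else path.with_suffix(".npz")) as data:
            for i, p in enumerate(model.parameters()):
                p.value[...] = data[f"p{i}"]
        model.trained = manifest["trained"]
        return model


# -- module-level operations -------------------------------------------------

def build_dsl_model(cfg: DSLModelConfig | None = None,
                    seed: int = 0) -> ShapePriorAutoencoder:
    """Construct a freshly initialized shape-prior autoencoder."""
    return ShapePriorAutoencoder(cfg, seed=seed)


def encode(model: ShapePriorAutoencoder, x: ProbabilityVolume,
           provenance: str = "") -> LatentVolumeMap:
    z = model.encode_values(x.values.astype(np.float32))
    return LatentVolumeMap(z, provenance=provenance)


def decode(model: ShapePriorAutoencoder, z: LatentVolumeMap,
           spacing=(1.0, 1.0, 1.0)) -> ProbabilityVolume:
    probs = model.decode_values(z.values)
    return ProbabilityVolume(probs, spacing=spacing)


def combined_loss(pred, target, lam1: float = 0.5, lam2: float = 0.5,
                  eps: float = 1e-5) -> nn.LossParts:
    """Weighted L1 + soft-Dice loss on probability fields.

    Accepts :class:`ProbabilityVolume` or raw ``(C, ...)`` arrays.
    """
    p = pred.values if isinstance(pred, ProbabilityVolume) else np.asarray(pred)
    t = target.values if isinstance(target, ProbabilityVolume) else np.asarray(target)
    return nn.combined_loss(p, t, lam1=lam1, lam2=lam2, eps=eps)


def _degraded_input(clean: LabelVolume, deg_cfg: DegradationConfig,
                    rng: np.random.Generator) -> LabelVolume:
    """Degrade a clean volume and re-expand it to the clean depth.

    The degraded stack is at reduced depth; nearest z-repetition brings it
    back so input and reconstruction target have identical shapes (the same
    expansion a clinical viewer applies to a thick-slice stack).
    """
    deg, _ = degrade(clean, deg_cfg, rng)
    up = upsample_z_repeat(deg, deg_cfg.z_factor)
    if up.shape[0] > clean.shape[0]:
        up = LabelVolume(up.voxels[:clean.shape[0]], spacing=up.spacing,
                         class_names=up.class_names)
    return up


def _train_epochs(model: ShapePriorAutoencoder, make_pairs, n_cases: int,
                  cfg: TrainConfig, params: list[nn.Parameter],
                  stage: str) -> TrainingResults:
    opt = nn.Adam(params, lr=cfg.lr)
    order_rng = np.random.default_rng(cfg.seed + 1)
    results = TrainingResults(stage=stage, config=cfg, n_cases=n_cases)
    for epoch in range(cfg.epochs):
        order = (order_rng.permutation(n_cases) if cfg.shuffle
                 else np.arange(n_cases))
        tot = l1 = dc = 0.0
        for idx in order:
            x, y = make_pairs(int(idx), epoch)
            probs = model.forward(x)
            parts, dprobs = nn.combined_loss_grad(
                probs, y, lam1=cfg.lam1, lam2=cfg.lam2, eps=cfg.eps)
            if not np.isfinite(parts.total):
                raise FloatingPointError(
                    f"{stage}: non-finite loss at epoch {epoch}, case {idx}: "
                    f"{parts}")
            opt.zero_grad()
            model.backward(dprobs)
            opt.step()
            tot += parts.total
            l1 += parts.l1
            dc += parts.dice
        results.history.append(nn.LossParts(
            total=tot / n_cases, l1=l1 / n_cases, dice=dc / n_cases))
    model.trained = True
    return results


def pretrain_ct(model: ShapePriorAutoencoder, phantoms: list[LabelVolume],
                deg_cfg: DegradationConfig,
                train: TrainConfig | None = None) -> TrainingResults:
    """Manifold pretraining on clean volumes with fresh per-epoch degradations.

    Every epoch each clean case is degraded anew (augmentation semantics) and
    the autoencoder is trained to reconstruct the clean target from it.
    """
    if not phantoms:
        raise ValueError("pretraining requires at least one case")
    cfg = train if train is not None else TrainConfig()
    n_classes = model.config.in_channels
    deg_rng = np.random.default_rng(cfg.seed + 1_000_003)
    targets = [smooth_targets(to_one_hot(v, n_classes).values.astype(np.float32),
                              cfg.label_smoothing)
               for v in phantoms]

    def make_pairs(idx: int, epoch: int):
        x_vol = _degraded_input(phantoms[idx], deg_cfg, deg_rng)
        x = to_one_hot(x_vol, n_classes).values.astype(np.float32)
        return x, targets[idx]

    return _train_epochs(model, make_pairs, len(phantoms), cfg,
                         model.parameters(), stage="motion-correction pretrain")


def finetune_mri(model: ShapePriorAutoencoder,
                 cases: list[tuple[LabelVolume, LabelVolume]],
                 train: TrainConfig | None = None) -> TrainingResults:
    """Target-domain finetuning with the decoder frozen.

    ``cases`` are (input, target) pairs used exactly as given — no synthetic
    degradation is applied.  Only encoder parameters receive updates; the
    decoder stays bit-identical, preserving the pretrained shape manifold.
    """
    import warnings
    if not cases:
        raise ValueError("finetuning requires at least one case")
    if not model.trained:
        warnings.warn("finetuning an unpretrained model; the frozen decoder "
                      "is random", stacklevel=2)
    cfg = train if train is not None else TrainConfig()
    n_classes = model.config.in_channels
    pairs = []
    for x_vol, y_vol in cases:
        if x_vol.shape != y_vol.shape:
            raise ValueError("finetune input/target shape mismatch")
        pairs.append((to_one_hot(x_vol, n_classes).values.astype(np.float32),
                      smooth_targets(
                          to_one_hot(y_vol, n_classes).values.astype(np.float32),
                          cfg.label_smoothing)))

    def make_pairs(idx: int, epoch: int):
        return pairs[idx]

    return _train_epochs(model, make_pairs, len(pairs), cfg,
                         model.encoder_parameters(),
                         stage="motion-correction finetune")


def correct(model: ShapePriorAutoencoder, vol: LabelVolume) -> LabelVolume:
    """Project a (motion-corrupted) label volume onto the learned manifold.

    In-plane dims not divisible by the pooling factor are symmetrically
    zero-padded and cropped back after decoding.  Spacing and class names are
    preserved.
    """
    if not model.trained:
        raise RuntimeError("model must be trained before correction")
    f = model.config.inplane_factor
    D, H, W = vol.shape
    ph, pw = (-H) % f, (-W) % f
    padded = np.pad(vol.voxels, ((0, 0), (ph // 2, ph - ph // 2),
                                 (pw // 2, pw - pw // 2)))
    x = to_one_hot(LabelVolume(padded, spacing=vol.spacing),
                   model.config.in_channels).values.astype(np.float32)
    probs = model.forward(x)
    labels = probs.argmax(axis=0).astype(np.int16)
    labels = labels[:, ph // 2: ph // 2 + H, pw // 2: pw // 2 + W]
    return LabelVolume(labels, spacing=vol.spacing, class_names=vol.class_names)


# -- statsmodels-style facade -------------------------------------------------

class MotionCorrectionModel:
    """Model object binding clean training volumes to a degradation model.

    ``fit`` pretrains the shape prior and returns a
    :class:`MotionCorrectionResults` carrying the trained network, the loss
    history, and correction/finetuning entry points.
    """

    def __init__(self, volumes: list[LabelVolume],
                 degradation: DegradationConfig | str = "medium",
                 config: DSLModelConfig | None = None, seed: int = 0):
        if isinstance(degradation, str):
            degradation = severity_preset(degradation)
        self.volumes = list(volumes)
        self.degradation = degradation
        self.config = config if config is not None else DSLModelConfig()
        self.seed = seed

    def fit(self, train: TrainConfig | None = None) -> "MotionCorrectionResults":
        cfg = train if train is not None else TrainConfig()
        network = ShapePriorAutoencoder(self.config, seed=self.seed)
        history = pretrain_ct(network, self.volumes, self.degradation, cfg)
        return MotionCorrectionResults(network=network, pretrain=history,
                                       degradation=self.degradation)


@dataclass
class MotionCorrectionResults:
    network: ShapePriorAutoencoder
    pretrain: TrainingResults
    degradation: DegradationConfig
    finetune: TrainingResults | None = None

    def finetune_on(self, cases: list[tuple[LabelVolume, LabelVolume]],
                    train: TrainConfig | None = None) -> "MotionCorrectionResults":
        self.finetune = finetune_mri(self.network, cases, train)
        return self

    def correct(self, vol: LabelVolume) -> LabelVolume:
        return correct(self.network, vol)

    def summary(self) -> str:
        parts = [self.pretrain.summary(),
                 f"degradation severity: {self.degradation.severity}"]
        if self.finetune is not None:
            parts.append(self.finetune.summary())
        return "\n\n".join(parts)
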