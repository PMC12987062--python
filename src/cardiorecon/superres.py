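"""Through-plane (z-axis) label super-resolution with an implicit field.

A low-resolution label stack is lifted to ``s_z`` times its slice count by
modelling the label field as a continuous function of normalized spatial
coordinates.  For every target voxel the pipeline combines three
ingredients:

- *semantic anchors*: trilinear samples of the LR one-hot field at the
  voxel's normalized coordinate (a coarse, topology-preserving guess);
- *implicit features*: a small coordinate-conditioned MLP applied pointwise
  to ``[z, y, x, anchors]``, producing a feature field that varies smoothly
  along depth;
- *explicit interpolation*: the LR field linearly interpolated along z only.

A shallow fusion convnet consumes the concatenation of the explicit branch
and the feature field and emits per-class logits; softmax + argmax gives the
HR label map, whose depth is exactly ``s_z * D_lr``.

Coordinates use the voxel-center convention: along an axis of length ``n``,
index ``i`` maps to ``-1 + 2 i / (n - 1)`` (an axis of length 1 maps to 0),
and the same convention drives the trilinear sampler and the explicit
z-interpolation, so sampling an LR grid at its own centers is the identity.

Training uses a degradation-reconstruction scheme: high-resolution volumes
are dynamically downsampled along z by a factor drawn from the training
scale set (x2/x3/x4 by default) and the network is supervised against the
original.  Finetuning on target-domain (LR, HR) pairs uses differential
learning rates: the pretrained representation path (the coordinate MLP)
trains at a reduced rate while the fusion network adapts at the full rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .degrade import downsample_z
from .io import LabelVolume, ProbabilityVolume, to_one_hot
from .train import TrainConfig, TrainingResults, smooth_targets

__all__ = [
    "CoordinateGrid",
    "ASVModelConfig",
    "SuperResolutionNet",
    "SuperResolutionModel",
    "SuperResolutionResults",
    "normalized_grid",
    "trilinear_sample",
    "explicit_upsample",
    "inr_features",
    "superresolve",
    "train_asv",
    "finetune_asv",
]


@dataclass(frozen=True)
class CoordinateGrid:
    """Normalized target-voxel coordinates.

    ``coords`` is ``(N, 3)`` with columns ``(z, y, x)`` in ``[-1, 1]``,
    ordered depth-major then row-major (x fastest), ``N = D * H * W``.
    """

    coords: np.ndarray
    target_shape: tuple[int, int, int]

    def __post_init__(self):
        if self.coords.shape != (int(np.prod(self.target_shape)), 3):
            raise ValueError("coords must be (prod(target_shape), 3)")


def _axis_coords(n: int) -> np.ndarray:
    if n == 1:
        return np.zeros(1)
    return -1.0 + 2.0 * np.arange(n) / (n - 1)


def normalized_grid(target_shape: tuple[int, int, int]) -> CoordinateGrid:
    """Voxel-center normalized coordinates for a target grid."""
    D, H, W = (int(s) for s in target_shape)
    if min(D, H, W) < 1:
        raise ValueError("all target dims must be >= 1")
    zz, yy, xx = np.meshgrid(_axis_coords(D), _axis_coords(H),
                             _axis_coords(W), indexing="ij")
    coords = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    return CoordinateGrid(coords=coords, target_shape=(D, H, W))


def _index_weights(c: np.ndarray, n: int):
    """Map normalized coords to (lower index, upper index, frac weight)."""
    if n == 1:
        z = np.zeros(c.shape, dtype=np.intp)
        return z, z, np.zeros_like(c)
    t = np.clip((c + 1.0) / 2.0 * (n - 1), 0.0, n - 1)
    i0 = np.floor(t).astype(np.intp)
    i0 = np.minimum(i0, n - 2)
    return i0, i0 + 1, t - i0


def trilinear_sample(lr: ProbabilityVolume | np.ndarray,
                     grid: CoordinateGrid) -> np.ndarray:
    """Trilinear samples of each channel at the grid coordinates: (N, C).

    Interpolation weights are convex, so anchor vectors stay on the
    probability simplex whenever the input field does.
    """
    values = lr.values if isinstance(lr, ProbabilityVolume) else np.asarray(lr)
    C, D, H, W = values.shape
    coords = grid.coords
    if np.abs(coords).max() > 1 + 1e-9:
        raise ValueError("grid coordinates must lie in [-1, 1]")
    z0, z1, wz = _index_weights(coords[:, 0], D)
    y0, y1, wy = _index_weights(coords[:, 1], H)
    x0, x1, wx = _index_weights(coords[:, 2], W)
    out = np.zeros((coords.shape[0], C), dtype=values.dtype)
    for zi, fz in ((z0, 1.0 - wz), (z1, wz)):
        for yi, fy in ((y0, 1.0 - wy), (y1, wy)):
            w_zy = fz * fy
            for xi, fx in ((x0, 1.0 - wx), (x1, wx)):
                w = w_zy * fx
                out += w[:, None] * values[:, zi, yi, xi].T
    return out


def explicit_upsample(lr: ProbabilityVolume, s_z: int) -> ProbabilityVolume:
    """Linear interpolation along depth only, to ``s_z * D_lr`` slices."""
    if s_z < 1:
        raise ValueError("scale must be >= 1")
    values = _explicit_upsample_values(lr.values, s_z)
    sz, sy, sx = lr.spacing
    return ProbabilityVolume(values, spacing=(sz / s_z, sy, sx))


def _explicit_upsample_values(values: np.ndarray, s_z: int) -> np.ndarray:
    C, Dl, H, W = values.shape
    Dh = s_z * Dl
    if Dh == 1:
        return values.copy()
    t = np.arange(Dh) * (Dl - 1) / (Dh - 1)
    i0 = np.minimum(np.floor(t).astype(np.intp), max(Dl - 2, 0))
    i1 = np.minimum(i0 + 1, Dl - 1)
    w = (t - i0)[None, :, None, None]
    return values[:, i0] * (1.0 - w) + values[:, i1] * w


def inr_features(grid: CoordinateGrid, anchors: np.ndarray,
                 mlp: nn.Sequential, chunk_size: int = 1 << 16) -> np.ndarray:
    """Pointwise MLP over ``[coords, anchors]``, reshaped to a 4D field.

    The map is applied per point, so chunking cannot change results; the
    chunk size only bounds peak memory.
    """
    if anchors.shape[0] != grid.coords.shape[0]:
        raise ValueError("anchors row count must equal grid size")
    inp = np.concatenate([grid.coords, anchors], axis=1).astype(np.float32)
    outs = [mlp.forward(inp[i:i + chunk_size])
            for i in range(0, inp.shape[0], chunk_size)]
    feats = np.concatenate(outs, axis=0)
    D, H, W = grid.target_shape
    return feats.T.reshape(feats.shape[1], D, H, W)


@dataclass(frozen=True)
class ASVModelConfig:
    """Architecture and training policy of the super-resolution stage."""

    n_classes: int = 8
    mlp_hidden: tuple[int, ...] = (32, 32)
    feature_channels: int = 8         # C', width of the implicit feature field
    fusion_channels: tuple[int, ...] = (12, 12)
    scales: tuple[int, ...] = (2, 3, 4)
    lr_encoder_multiplier: float = 0.1
    chunk_size: int = 1 << 16
    #: residual connection from the explicit branch to the logits,
    #: initialized so training starts at explicit-interpolation quality
    #: (all structures present) instead of from uniform probabilities
    explicit_residual_init: float = 4.0

    def __post_init__(self):
        if any(int(s) != s or s < 2 for s in self.scales):
            raise ValueError("scales must be integers >= 2")
        if not (0.0 <= self.lr_encoder_multiplier <= 1.0):
            raise ValueError("lr multiplier must lie in [0, 1]")

    @property
    def mlp_in(self) -> int:
        return self.n_classes + 3


class SuperResolutionNet:
    """Implicit-field SR network: coordinate MLP plus fusion convnet."""

    def __init__(self, config: ASVModelConfig | None = None, seed: int = 0):
        self.config = config if config is not None else ASVModelConfig()
        cfg = self.config
        rng = np.random.default_rng(seed)
        mlp_layers: list[nn.Layer] = []
        prev = cfg.mlp_in
        for h in cfg.mlp_hidden:
            mlp_layers += [nn.Linear(prev, h, rng=rng), nn.ReLU()]
            prev = h
        mlp_layers.append(nn.Linear(prev, cfg.feature_channels, rng=rng))
        self.mlp = nn.Sequential(*mlp_layers)

        fusion: list[nn.Layer] = []
        prev = cfg.n_classes + cfg.feature_channels
        for f in cfg.fusion_channels:
            fusion += [nn.Conv3d(prev, f, rng=rng), nn.InstanceNorm(f),
                       nn.ReLU()]
            prev = f
        final = nn.Conv3d(prev, cfg.n_classes, rng=rng)
        final.weight.value[...] = 0.0  # fusion output starts at zero ...
        fusion.append(final)
        self.fusion = nn.Sequential(*fusion)
        # ... so the initial logits are the scaled explicit branch
        self.residual_scale = nn.Parameter(
            np.array(cfg.explicit_residual_init, dtype=np.float32),
            name="explicit_residual_scale")
        self.trained = False
        self._cache = None

    def mlp_parameters(self) -> list[nn.Parameter]:
        return self.mlp.parameters()

    def fusion_parameters(self) -> list[nn.Parameter]:
        return self.fusion.parameters() + [self.residual_scale]

    def parameters(self) -> list[nn.Parameter]:
        return self.mlp_parameters() + self.fusion_parameters()

    def save(self, path) -> None:
        """Checkpoint as ``.npz`` parameters plus a JSON manifest sidecar."""
        import json
        from dataclasses import asdict
        from pathlib import Path
        path = Path(path)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.parameters())}
        np.savez_compressed(path, **arrays)
        manifest = {"config": asdict(self.config), "trained": self.trained}
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path) -> "SuperResolutionNet":
        import json
        from pathlib import Path
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        cfg_d = manifest["config"]
        for key in ("mlp_hidden", "fusion_channels", "scales"):
            cfg_d[key] = tuple(cfg_d[key])
        net = cls(ASVModelConfig(**cfg_d))
        with np.load(path if path.suffix == ".npz"
                     else path.with_suffix(".npz")) as data:
            for i, p in enumerate(net.parameters()):
                p.value = np.asarray(data[f"p{i}"])
        net.trained = manifest["trained"]
        return net

    def forward(self, lr_values: np.ndarray, s_z: int,
                keep_cache: bool = False) -> np.ndarray:
        """Full SR forward pass on a one-hot LR field: probabilities at HR."""
        C, Dl, H, W = lr_values.shape
        grid = normalized_grid((s_z * Dl, H, W))
        anchors = trilinear_sample(lr_values, grid).astype(np.float32)
        if keep_cache:
            # single-batch MLP so layer caches survive for backward
            inp = np.concatenate([grid.coords, anchors], axis=1).astype(np.float32)
            feats = self.mlp.forward(inp)
            f_field = feats.T.reshape(feats.shape[1], *grid.target_shape)
        else:
            f_field = inr_features(grid, anchors, self.mlp,
                                   self.config.chunk_size)
        x_up = _explicit_upsample_values(lr_values, s_z).astype(np.float32)
        m = np.concatenate([x_up, f_field], axis=0)
        logits = self.fusion.forward(m)
        logits += self.residual_scale.value * x_up
        probs = nn.softmax_channels(logits)
        if keep_cache:
            self._cache = (probs, x_up)
        return probs

    def backward(self, dprobs: np.ndarray) -> None:
        if self._cache is None:
            raise RuntimeError("backward requires forward(keep_cache=True)")
        probs, x_up = self._cache
        dlogits = nn.softmax_backward(probs, dprobs)
        self.residual_scale.grad += (dlogits * x_up).sum()
        dm = self.fusion.backward(dlogits)
        df_field = dm[self.config.n_classes:]
        df = df_field.reshape(df_field.shape[0], -1).T
        self.mlp.backward(np.ascontiguousarray(df))
        self._cache = None


def superresolve(model: SuperResolutionNet, lr_vol: LabelVolume,
                 s_z: int) -> LabelVolume:
    """Super-resolve a label stack by an integer factor along z.

    The factor must belong to the model's trained scale set; arbitrary
    fractional scales are rejected (the field representation is continuous,
    but the training scheme is not resolution-agnostic).
    """
    if not model.trained:
        raise RuntimeError("model must be trained before super-resolution")
    if int(s_z) != s_z or s_z < 2:
        raise ValueError("scale must be an integer >= 2")
    if s_z not in model.config.scales:
        raise ValueError(f"scale {s_z} not in trained scale set "
                         f"{model.config.scales}")
    x = to_one_hot(lr_vol, model.config.n_classes).values.astype(np.float32)
    probs = model.forward(x, int(s_z))
    labels = probs.argmax(axis=0).astype(np.int16)
    sz, sy, sx = lr_vol.spacing
    return LabelVolume(labels, spacing=(sz / s_z, sy, sx),
                       class_names=lr_vol.class_names)


def _run_training(net: SuperResolutionNet, make_case, n_cases: int,
                  cfg: TrainConfig, groups, stage: str) -> TrainingResults:
    opt = nn.Adam([], lr=cfg.lr, groups=groups)
    order_rng = np.random.default_rng(cfg.seed + 1)
    results = TrainingResults(stage=stage, config=cfg, n_cases=n_cases)
    for epoch in range(cfg.epochs):
        order = (order_rng.permutation(n_cases) if cfg.shuffle
                 else np.arange(n_cases))
        tot = l1 = dc = 0.0
        for idx in order:
            lr_values, target, s = make_case(int(idx), epoch)
            probs = net.forward(lr_values, s, keep_cache=True)
            d_target = target.shape[1]
            parts, grad = nn.combined_loss_grad(
                probs[:, :d_target], target,
                lam1=cfg.lam1, lam2=cfg.lam2, eps=cfg.eps)
            if not np.isfinite(parts.total):
                raise FloatingPointError(
                    f"{stage}: non-finite loss at epoch {epoch}, case {idx}")
            dprobs = np.zeros_like(probs)
            dprobs[:, :d_target] = grad
            opt.zero_grad()
            net.backward(dprobs)
            opt.step()
            tot += parts.total
            l1 += parts.l1
            dc += parts.dice
        results.history.append(nn.LossParts(
            total=tot / n_cases, l1=l1 / n_cases, dice=dc / n_cases))
    net.trained = True
    return results


def train_asv(net: SuperResolutionNet, clean_hr_cases: list[LabelVolume],
              scales: tuple[int, ...] | None = None,
              train: TrainConfig | None = None) -> TrainingResults:
    """Multi-scale degradation-reconstruction pretraining.

    Each step draws a scale from the training set, downsamples a clean HR
    volume along z by that factor, and supervises the SR pipeline against
    the original (predictions cropped to the target depth when the factor
    does not divide it).
    """
    if not clean_hr_cases:
        raise ValueError("training requires at least one case")
    cfg = train if train is not None else TrainConfig()
    scales = tuple(scales) if scales is not None else net.config.scales
    if any(int(s) != s or s < 2 for s in scales):
        raise ValueError("scales must be integers >= 2")
    n_classes = net.config.n_classes
    targets = [smooth_targets(to_one_hot(v, n_classes).values.astype(np.float32),
                              cfg.label_smoothing)
               for v in clean_hr_cases]
    scale_rng = np.random.default_rng(cfg.seed + 2_000_003)

    def make_case(idx: int, epoch: int):
        s = int(scale_rng.choice(scales))
        lr_vol = downsample_z(clean_hr_cases[idx], s)
        x = to_one_hot(lr_vol, n_classes).values.astype(np.float32)
        return x, targets[idx], s

    return _run_training(net, make_case, len(clean_hr_cases), cfg,
                         [(1.0, net.parameters())], stage="super-resolution")


def finetune_asv(net: SuperResolutionNet,
                 cases: list[tuple[LabelVolume, LabelVolume]],
                 train: TrainConfig | None = None,
                 lr_multiplier: float | None = None) -> TrainingResults:
    """Target-domain finetuning with differential learning rates.

    All parameters stay trainable, but the pretrained representation path
    (the coordinate MLP) trains at ``lr * lr_multiplier`` while the fusion
    network trains at the full rate.  A multiplier of 0 leaves the MLP
    bit-identical; 1 reproduces uniform-rate finetuning.
    """
    import warnings
    if not cases:
        raise ValueError("finetuning requires at least one case")
    if not net.trained:
        warnings.warn("finetuning an unpretrained SR model", stacklevel=2)
    cfg = train if train is not None else TrainConfig()
    mult = (net.config.lr_encoder_multiplier if lr_multiplier is None
            else float(lr_multiplier))
    n_classes = net.config.n_classes
    prepared = []
    for lr_vol, hr_vol in cases:
        s = int(np.ceil(hr_vol.shape[0] / lr_vol.shape[0]))
        if s < 2 or s * lr_vol.shape[0] < hr_vol.shape[0]:
            raise ValueError("LR/HR depths imply an unsupported scale")
        prepared.append((
            to_one_hot(lr_vol, n_classes).values.astype(np.float32),
            smooth_targets(to_one_hot(hr_vol, n_classes).values.astype(np.float32),
                           cfg.label_smoothing), s))

    def make_case(idx: int, epoch: int):
        return prepared[idx]

    groups = [(mult, net.mlp_parameters()), (1.0, net.fusion_parameters())]
    return _run_training(net, make_case, len(prepared), cfg, groups,
                         stage="super-resolution finetune")


# -- statsmodels-style facade -------------------------------------------------

class SuperResolutionModel:
    """Binds clean HR training volumes to an SR architecture; ``fit`` runs
    the multi-scale degradation-reconstruction training."""

    def __init__(self, volumes: list[LabelVolume],
                 config: ASVModelConfig | None = None, seed: int = 0):
        self.volumes = list(volumes)
        self.config = config if config is not None else ASVModelConfig()
        self.seed = seed

    def fit(self, train: TrainConfig | None = None) -> "SuperResolutionResults":
        net = SuperResolutionNet(self.config, seed=self.seed)
        history = train_asv(net, self.volumes, self.config.scales, train)
        return SuperResolutionResults(network=net, pretrain=history)


@dataclass
class SuperResolutionResults:
    network: SuperResolutionNet
    pretrain: TrainingResults
    finetune: TrainingResults | None = None

    def finetune_on(self, cases, train: TrainConfig | None = None,
                    lr_multiplier: float | None = None) -> "SuperResolutionResults":
        self.finetune = finetune_asv(self.network, cases, train, lr_multiplier)
        return self

    def superresolve(self, lr_vol: LabelVolume, s_z: int) -> LabelVolume:
        return superresolve(self.network, lr_vol, s_z)

    def summary(self) -> str:
        parts = [self.pretrain.summary(),
                 f"trained scales: {self.network.config.scales}"]
        if self.finetune is not None:
            parts.append(self.finetune.summary())
        return "\n\n".join(parts)
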