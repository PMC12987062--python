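"""Stochastic degradation of clean label volumes.

This simulates how a clean, isotropic whole-heart label volume turns into
the kind of stack a routine cardiac MR acquisition yields:

1. *slice misalignment* — each 2D slice is independently displaced by a
   rigid in-plane transform (translation, optionally rotation), modelling
   breath-hold-to-breath-hold respiratory shift;
2. *label noise* — boundary dilations/erosions and small speckle blobs,
   modelling segmentation defects;
3. *through-plane downsampling* — only every ``z_factor``-th slice is kept,
   modelling thick-slice acquisition.

Every realized transform is logged in a :class:`DegradationRecord` so any
degradation can be re-applied exactly (to another volume of the same shape)
or audited.  A neutral configuration is the bit-exact identity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .io import LabelVolume

__all__ = [
    "DegradationConfig",
    "DegradationRecord",
    "slice_misalign",
    "downsample_z",
    "inject_label_noise",
    "degrade",
    "severity_preset",
    "SEVERITY_LEVELS",
]

SEVERITY_LEVELS = ("easy", "medium", "hard")


@dataclass(frozen=True)
class DegradationConfig:
    """Parameters of the stochastic degradation operator.

    Units: translations in voxels, rotation in degrees, radii in voxels.
    """

    translation_range: float = 3.0   # max |dx|, |dy| per slice
    rotation_range: float = 0.0      # max in-plane rotation per slice
    misalign_prob: float = 0.6       # probability a slice is displaced
    z_factor: int = 2                # keep every z_factor-th slice
    z_phase: int = 0                 # residue class of kept slices
    boundary_perturb_prob: float = 0.0   # per-slice probability
    boundary_perturb_radius: int = 1
    speckle_blob_rate: float = 0.0   # Poisson mean blobs per slice
    blob_radius: int = 1
    severity: str = "custom"

    def to_yaml(self, path) -> None:
        import yaml
        from dataclasses import asdict
        from pathlib import Path
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "DegradationConfig":
        import yaml
        from pathlib import Path
        return cls(**yaml.safe_load(Path(path).read_text()))

    def __post_init__(self):
        if self.translation_range < 0 or self.rotation_range < 0:
            raise ValueError("ranges must be >= 0")
        if not (0 <= self.misalign_prob <= 1 and 0 <= self.boundary_perturb_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.z_factor < 1:
            raise ValueError("z_factor must be >= 1")
        if not 0 <= self.z_phase < self.z_factor:
            raise ValueError("z_phase must lie in [0, z_factor)")
        if self.speckle_blob_rate < 0:
            raise ValueError("blob rate must be >= 0")


@dataclass
class DegradationRecord:
    """Realized per-slice transforms and noise events of one degradation."""

    slice_transforms: list[tuple[float, float, float]] = field(default_factory=list)
    kept_indices: list[int] = field(default_factory=list)
    noise_events: list[dict] = field(default_factory=list)
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DegradationRecord":
        d = json.loads(text)
        d["slice_transforms"] = [tuple(t) for t in d["slice_transforms"]]
        return cls(**d)

    def reapply_misalignment(self, vol: LabelVolume) -> LabelVolume:
        """Apply this record's slice transforms to another same-shape volume."""
        if len(self.slice_transforms) != vol.shape[0]:
            raise ValueError("record depth does not match volume depth")
        out = vol.voxels.copy()
        for s, (dx, dy, theta) in enumerate(self.slice_transforms):
            if dx == 0.0 and dy == 0.0 and theta == 0.0:
                continue
            out[s] = _rigid_slice(vol.voxels[s], dx, dy, theta)
        return LabelVolume(out, spacing=vol.spacing, class_names=vol.class_names)


def _rigid_slice(sl: np.ndarray, dx: float, dy: float, theta_deg: float) -> np.ndarray:
    """Rigid in-plane transform of one (y, x) slice.

    Content moves by ``(dy, dx)`` after rotating by ``theta_deg`` about the
    slice center; nearest-neighbour resampling keeps labels categorical, and
    content shifted past the border is replaced by background.
    """
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    rot_inv = np.array([[c, s], [-s, c]])
    center = (np.asarray(sl.shape, dtype=float) - 1.0) / 2.0
    shift = np.array([dy, dx], dtype=float)
    offset = center - rot_inv @ (center + shift)
    return ndimage.affine_transform(sl, rot_inv, offset=offset, order=0,
                                    mode="constant", cval=0,
                                    output=sl.dtype)


def slice_misalign(vol: LabelVolume, cfg: DegradationConfig,
                   rng: np.random.Generator) -> tuple[LabelVolume, DegradationRecord]:
    """Independently displace each slice with probability ``misalign_prob``."""
    record = DegradationRecord()
    out = vol.voxels.copy()
    for s in range(vol.shape[0]):
        # draws are consumed unconditionally so the record alone fixes the stream
        hit = rng.random() < cfg.misalign_prob
        dx = rng.uniform(-cfg.translation_range, cfg.translation_range)
        dy = rng.uniform(-cfg.translation_range, cfg.translation_range)
        theta = rng.uniform(-cfg.rotation_range, cfg.rotation_range)
        if not hit or (dx == 0.0 and dy == 0.0 and theta == 0.0):
            record.slice_transforms.append((0.0, 0.0, 0.0))
            continue
        record.slice_transforms.append((dx, dy, theta))
        out[s] = _rigid_slice(vol.voxels[s], dx, dy, theta)
    return (LabelVolume(out, spacing=vol.spacing, class_names=vol.class_names),
            record)


def downsample_z(vol: LabelVolume, z_factor: int, z_phase: int = 0) -> LabelVolume:
    """Keep slices with index congruent to ``z_phase`` modulo ``z_factor``.

    Output depth is ``ceil((D - z_phase) / z_factor)`` and the z spacing is
    multiplied by the factor.
    """
    if z_factor < 1:
        raise ValueError("z_factor must be >= 1")
    if not 0 <= z_phase < z_factor:
        raise ValueError("z_phase must lie in [0, z_factor)")
    if vol.shape[0] < z_factor:
        raise ValueError("volume depth smaller than z_factor")
    voxels = vol.voxels[z_phase::z_factor].copy()
    sz, sy, sx = vol.spacing
    return LabelVolume(voxels, spacing=(sz * z_factor, sy, sx),
                       class_names=vol.class_names)


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (yy ** 2 + xx ** 2) <= r ** 2


def inject_label_noise(vol: LabelVolume, cfg: DegradationConfig,
                       rng: np.random.Generator) -> tuple[LabelVolume, DegradationRecord]:
    """Segmentation-defect noise: boundary dilation/erosion within random
    sub-windows, plus Poisson speckle blobs flipped to wrong classes."""
    record = DegradationRecord()
    out = vol.voxels.copy()
    D, H, W = vol.shape
    n_classes = max(vol.n_classes, 2)
    disk = _disk(cfg.boundary_perturb_radius)
    blob = _disk(cfg.blob_radius)
    for s in range(D):
        if cfg.boundary_perturb_prob > 0 and rng.random() < cfg.boundary_perturb_prob:
            present = np.unique(out[s])
            present = present[present > 0]
            if present.size:
                c = int(rng.choice(present))
                op = "dilate" if rng.random() < 0.5 else "erode"
                r = cfg.boundary_perturb_radius
                win = 4 * r + 3
                cy = int(rng.integers(0, H))
                cx = int(rng.integers(0, W))
                y0, y1 = max(cy - win, 0), min(cy + win, H)
                x0, x1 = max(cx - win, 0), min(cx + win, W)
                # morphology runs on a radius-expanded context window so the
                # sub-window border cannot masquerade as a class boundary
                ey0, ey1 = max(y0 - r, 0), min(y1 + r, H)
                ex0, ex1 = max(x0 - r, 0), min(x1 + r, W)
                ctx = out[s, ey0:ey1, ex0:ex1]
                m = ctx == c
                if op == "dilate":
                    new = ndimage.binary_dilation(m, structure=disk)
                    changed = new & ~m
                else:
                    new = ndimage.binary_erosion(m, structure=disk,
                                                 border_value=1)
                    changed = m & ~new
                core = np.zeros_like(changed)
                core[y0 - ey0:y1 - ey0, x0 - ex0:x1 - ex0] = True
                changed &= core
                ctx[changed] = c if op == "dilate" else 0
                record.noise_events.append({
                    "kind": "boundary", "slice": s, "class": c, "op": op,
                    "window": [int(y0), int(y1), int(x0), int(x1)]})
        if cfg.speckle_blob_rate > 0:
            for _ in range(int(rng.poisson(cfg.speckle_blob_rate))):
                cy = int(rng.integers(0, H))
                cx = int(rng.integers(0, W))
                wrong = int(rng.integers(1, n_classes))
                r = cfg.blob_radius
                y0, y1 = max(cy - r, 0), min(cy + r + 1, H)
                x0, x1 = max(cx - r, 0), min(cx + r + 1, W)
                bm = blob[(y0 - cy + r):(y1 - cy + r), (x0 - cx + r):(x1 - cx + r)]
                out[s, y0:y1, x0:x1][bm] = wrong
                record.noise_events.append({
                    "kind": "speckle", "slice": s, "class": wrong,
                    "center": [cy, cx], "radius": r})
    return (LabelVolume(out, spacing=vol.spacing, class_names=vol.class_names),
            record)


def degrade(vol: LabelVolume, cfg: DegradationConfig,
            rng: np.random.Generator) -> tuple[LabelVolume, DegradationRecord]:
    """Full degradation: misalign -> label noise -> z-downsample.

    The order mimics acquisition: respiratory motion corrupts the slices,
    the (noisy) segmentation is made on them, and the stack is sparse in z.
    """
    misaligned, rec1 = slice_misalign(vol, cfg, rng)
    noisy, rec2 = inject_label_noise(misaligned, cfg, rng)
    down = downsample_z(noisy, cfg.z_factor, cfg.z_phase)
    record = DegradationRecord(
        slice_transforms=rec1.slice_transforms,
        kept_indices=list(range(cfg.z_phase, vol.shape[0], cfg.z_factor)),
        noise_events=rec2.noise_events)
    return down, record


#: Severity presets.  The magnitudes span sub-voxel respiratory shift (easy)
#: to gross misalignment with segmentation noise (hard); each field is
#: componentwise monotone non-decreasing in severity and z_factor is 2
#: throughout (every second slice kept).
_PRESETS = {
    "easy": dict(translation_range=1.0, rotation_range=0.0, misalign_prob=0.3,
                 boundary_perturb_prob=0.0, boundary_perturb_radius=1,
                 speckle_blob_rate=0.0, blob_radius=1),
    "medium": dict(translation_range=3.0, rotation_range=2.0, misalign_prob=0.6,
                   boundary_perturb_prob=0.2, boundary_perturb_radius=1,
                   speckle_blob_rate=0.2, blob_radius=1),
    "hard": dict(translation_range=6.0, rotation_range=5.0, misalign_prob=0.9,
                 boundary_perturb_prob=0.4, boundary_perturb_radius=2,
                 speckle_blob_rate=0.5, blob_radius=2),
}


def severity_preset(level: str) -> DegradationConfig:
    """Monotone easy/medium/hard degradation presets (z_factor fixed at 2)."""
    if level not in _PRESETS:
        raise ValueError(f"unknown severity level {level!r}; "
                         f"choose from {SEVERITY_LEVELS}")
    return DegradationConfig(z_factor=2, z_phase=0, severity=level,
                             **_PRESETS[level])
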