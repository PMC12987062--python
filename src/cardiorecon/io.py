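"""Containers and I/O for multi-class cardiac label volumes.

A :class:`LabelVolume` is an integer voxel grid in ``(z, y, x)`` axis order —
the through-plane (slice) axis is always axis 0 — together with the physical
voxel spacing ``(sz, sy, sx)`` in millimetres and an ordered class map.  The
default class map follows the whole-heart convention used throughout the
package: background, left ventricle (LV), right ventricle (RV), left atrium
(LA), right atrium (RA), myocardium (Myo), aorta (AO), pulmonary artery (PA).

Soft (per-class probability) fields live in :class:`ProbabilityVolume`,
shaped ``(C, D, H, W)`` with channels summing to 1 at every voxel.

Physical positions use voxel-center convention: the center of voxel ``i``
along an axis sits at ``i * spacing`` with the origin at the first center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import nibabel as nib
from scipy import ndimage

__all__ = [
    "DEFAULT_CLASS_NAMES",
    "LabelVolume",
    "ProbabilityVolume",
    "read_label_volume",
    "write_label_volume",
    "to_one_hot",
    "argmax_labels",
    "crop_or_pad",
    "upsample_z_repeat",
]

DEFAULT_CLASS_NAMES = ("background", "LV", "RV", "LA", "RA", "Myo", "AO", "PA")

#: the ventricle chambers (LV, RV) — the structures whose boundaries
#: respiratory motion distorts most; used by the recovery analyses.
#: The myocardium is a distinct thin-walled tissue and is reported
#: separately.
VENTRICULAR_CLASSES = (1, 2)


@dataclass
class LabelVolume:
    """Integer class-ID voxel grid with physical spacing.

    Parameters
    ----------
    voxels
        3D integer array, axis order ``(z/slice, y, x)``.
    spacing
        Voxel spacing ``(sz, sy, sx)`` in mm, all strictly positive.
    class_names
        Ordered names mapping class ID -> structure.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("label volume must be 3D (D, H, W)")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("label voxels must be integers")
        if self.voxels.min() < 0:
            raise ValueError("negative class IDs are invalid")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive numbers (mm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_classes(self) -> int:
        """Number of classes including background (max ID + 1)."""
        return int(self.voxels.max()) + 1

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.voxels.copy(), self.spacing, self.class_names)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LabelVolume):
            return NotImplemented
        return (self.voxels.shape == other.voxels.shape
                and np.array_equal(self.voxels, other.voxels)
                and np.allclose(self.spacing, other.spacing))


@dataclass
class ProbabilityVolume:
    """Per-class soft label field, ``(C, D, H, W)``, channels sum to 1."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 4:
            raise ValueError("probability volume must be 4D (C, D, H, W)")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    def validate(self, atol: float = 1e-6) -> None:
        sums = self.values.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=atol):
            raise ValueError("channel sums must equal 1 at every voxel")
        if self.values.min() < -atol or self.values.max() > 1 + atol:
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def n_classes(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape[1:]


def load_class_map(path) -> tuple[str, ...]:
    """Read an ordered class map from a YAML or JSON sidecar.

    Accepts either a list of names (index = class ID) or a mapping of
    class ID to name.
    """
    import json
    from pathlib import Path
    import yaml
    text = Path(path).read_text()
    data = (json.loads(text) if str(path).endswith(".json")
            else yaml.safe_load(text))
    if isinstance(data, dict):
        ids = sorted(int(k) for k in data)
        if ids != list(range(len(ids))):
            raise ValueError("class map IDs must be contiguous from 0")
        return tuple(str(data[k]) for k in sorted(data, key=int))
    return tuple(str(n) for n in data)


def read_label_volume(path, max_round_error: float = 1e-3) -> LabelVolume:
    """Load a NIfTI label volume.

    The on-disk NIfTI axis order ``(x, y, z)`` is transposed to the internal
    ``(z, y, x)`` convention and spacing is taken from the header zooms.
    Values within ``max_round_error`` of an integer are rounded; anything
    farther off raises, since fractional labels indicate a resampled (and
    therefore corrupted) label map.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    rounded = np.round(data)
    if np.abs(data - rounded).max() > max_round_error:
        raise ValueError("non-integer label values in file")
    zooms = img.header.get_zooms()[:3]  # (sx, sy, sz)
    voxels = np.ascontiguousarray(rounded.astype(np.int16).transpose(2, 1, 0))
    return LabelVolume(voxels, spacing=(zooms[2], zooms[1], zooms[0]))


def write_label_volume(vol: LabelVolume, path) -> None:
    """Write a NIfTI-1 file; ``read_label_volume`` round-trips exactly."""
    sz, sy, sx = vol.spacing
    affine = np.diag([sx, sy, sz, 1.0])
    data = np.ascontiguousarray(vol.voxels.transpose(2, 1, 0).astype(np.int16))
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, str(path))


def to_one_hot(vol: LabelVolume, n_classes: int | None = None) -> ProbabilityVolume:
    """One-hot encode a label volume into a ``(C, D, H, W)`` soft field."""
    if n_classes is None:
        n_classes = len(vol.class_names)
    vmax = int(vol.voxels.max())
    if vmax >= n_classes:
        raise ValueError(f"label {vmax} exceeds n_classes-1 = {n_classes - 1}")
    flat = np.eye(n_classes, dtype=np.float32)[vol.voxels.ravel()]
    values = flat.T.reshape((n_classes,) + vol.voxels.shape)
    return ProbabilityVolume(values, spacing=vol.spacing)


def argmax_labels(probs: ProbabilityVolume,
                  class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES) -> LabelVolume:
    """Per-voxel most probable class; ties go to the lowest class index."""
    labels = probs.values.argmax(axis=0).astype(np.int16)
    if len(class_names) < probs.n_classes:
        class_names = tuple(f"class_{c}" for c in range(probs.n_classes))
    return LabelVolume(labels, spacing=probs.spacing, class_names=class_names)


def crop_or_pad(vol: LabelVolume, target: tuple[int, int, int],
                center="centroid") -> LabelVolume:
    """Crop and/or pad to ``target`` shape about a center voxel.

    ``center="centroid"`` centers on the foreground center of mass rounded to
    the nearest voxel; otherwise ``center`` is an explicit ``(z, y, x)`` voxel
    coordinate.  Regions outside the input are filled with background (0).
    """
    target = tuple(int(t) for t in target)
    if any(t < 1 for t in target):
        raise ValueError("target dims must be >= 1")
    if isinstance(center, str):
        if center != "centroid":
            raise ValueError(f"unknown center mode {center!r}")
        fg = vol.voxels > 0
        if not fg.any():
            raise ValueError("cannot center on centroid of empty foreground")
        com = ndimage.center_of_mass(fg)
        center = tuple(int(np.round(c)) for c in com)
    center = tuple(int(c) for c in center)

    out = np.zeros(target, dtype=vol.voxels.dtype)
    src_slices, dst_slices = [], []
    for ax in range(3):
        start = center[ax] - target[ax] // 2
        s0 = max(start, 0)
        s1 = min(start + target[ax], vol.voxels.shape[ax])
        if s1 <= s0:
            # window entirely outside the input along this axis
            src_slices.append(slice(0, 0))
            dst_slices.append(slice(0, 0))
            continue
        src_slices.append(slice(s0, s1))
        dst_slices.append(slice(s0 - start, s1 - start))
    out[tuple(dst_slices)] = vol.voxels[tuple(src_slices)]
    return LabelVolume(out, spacing=vol.spacing, class_names=vol.class_names)


def resample_to_spacing(vol: LabelVolume,
                        new_spacing: tuple[float, float, float]) -> LabelVolume:
    """Nearest-neighbour resampling of a label volume onto a new voxel grid.

    The physical object is preserved (each output voxel takes the label of
    the nearest input voxel center); only the discretization changes.
    """
    if any(s <= 0 for s in new_spacing):
        raise ValueError("spacing must be positive")
    zoom = [o / n for o, n in zip(vol.spacing, new_spacing)]
    voxels = ndimage.zoom(vol.voxels, zoom, order=0, mode="nearest",
                          grid_mode=True)
    return LabelVolume(voxels, spacing=tuple(float(s) for s in new_spacing),
                       class_names=vol.class_names)


def upsample_z_repeat(vol: LabelVolume, factor: int) -> LabelVolume:
    """Nearest-neighbour slice repetition along the through-plane axis.

    The cheap clinical-baseline expansion of an anisotropic stack: each slice
    is repeated ``factor`` times and the z spacing divided accordingly.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    voxels = np.repeat(vol.voxels, factor, axis=0)
    sz, sy, sx = vol.spacing
    return LabelVolume(voxels, spacing=(sz / factor, sy, sx),
                       class_names=vol.class_names)
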