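"""Synthetic whole-heart label phantoms.

Generates 8-class label volumes with the whole-heart topology the
reconstruction pipeline is built for: an LV blood pool (class 1) fully
enclosed by a myocardial shell (class 5) except at a basal opening, RV / LA /
RA chambers (2, 3, 4) adjacent to but never overlapping the LV complex, and
curved aorta / pulmonary-artery tubes (6, 7) attached near the LV and RV
outflow regions.  Geometry is built from analytically defined ellipsoids and
tube polylines rasterized onto the voxel grid; no meshes.

Structures are placed sequentially with precedence LV/Myo -> RV -> LA/RA ->
AO/PA; later structures are carved against everything already placed, so the
enclosure invariant cannot be broken by a later chamber.  Each draw is
validated (all classes present, one 6-connected component per class, LV
enclosure) and resampled on failure, up to a bounded retry count.

These phantoms deliberately idealize anatomy: smooth quadric surfaces,
axis-aligned chambers, no trabeculation, papillary muscles, or valves.  They
exercise the geometry of the problem (nested shells, adjacency, anisotropic
grids), not patient realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .io import LabelVolume, DEFAULT_CLASS_NAMES, write_label_volume

__all__ = ["PhantomParams", "PhantomPlacementError", "generate_phantom",
           "generate_dataset"]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity

Range = tuple[float, float]


class PhantomPlacementError(RuntimeError):
    """Raised when no non-overlapping placement is found within the retry
    budget at the sampled structure scales."""


@dataclass(frozen=True)
class PhantomParams:
    """Ranges (in voxels) from which one phantom's geometry is sampled.

    ``chamber_scales`` maps structure name to per-axis ``(z, y, x)``
    semi-axis ranges.  Defaults target a 64 x 96 x 96 grid at (2, 1, 1) mm
    spacing — clinically anisotropic, desk-scale.
    """

    grid: tuple[int, int, int] = (64, 96, 96)
    spacing: tuple[float, float, float] = (2.0, 1.0, 1.0)
    chamber_scales: dict = field(default_factory=lambda: {
        "LV": ((9.0, 12.0), (14.0, 18.0), (14.0, 18.0)),
        "RV": ((7.0, 10.0), (11.0, 15.0), (11.0, 15.0)),
        "LA": ((5.0, 7.0), (9.0, 12.0), (9.0, 12.0)),
        "RA": ((5.0, 7.0), (9.0, 12.0), (9.0, 12.0)),
    })
    myo_thickness: tuple[int, int] = (2, 3)
    vessel_radius: Range = (2.5, 3.5)
    pose_jitter_deg: float = 10.0
    pose_jitter_vox: float = 3.0
    max_retries: int = 25

    def __post_init__(self):
        if len(self.grid) != 3 or any(int(g) < 4 for g in self.grid):
            raise ValueError("grid must be three dims of at least 4 voxels")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive numbers")
        for name, axes in self.chamber_scales.items():
            for lo, hi in axes:
                if not (0 < lo <= hi):
                    raise ValueError(f"bad scale range for {name}: ({lo}, {hi})")
        if self.myo_thickness[0] < 1 or self.myo_thickness[0] > self.myo_thickness[1]:
            raise ValueError("myo_thickness must be a range with lower bound >= 1")
        if not (0 < self.vessel_radius[0] <= self.vessel_radius[1]):
            raise ValueError("vessel_radius must be a positive range")

    @classmethod
    def desk_scale(cls) -> "PhantomParams":
        """Small 32 x 64 x 64 configuration for CPU-budget experiments."""
        return cls(
            grid=(32, 64, 64), spacing=(2.0, 1.0, 1.0),
            chamber_scales={
                "LV": ((5.0, 7.0), (9.0, 12.0), (9.0, 12.0)),
                "RV": ((4.0, 6.0), (8.0, 10.0), (8.0, 10.0)),
                "LA": ((3.0, 4.0), (6.0, 8.0), (6.0, 8.0)),
                "RA": ((3.0, 4.0), (6.0, 8.0), (6.0, 8.0)),
            },
            myo_thickness=(2, 2), vessel_radius=(2.0, 2.5),
            pose_jitter_deg=8.0, pose_jitter_vox=2.0)

    def volume_bounds(self) -> dict[int, tuple[float, float]]:
        """Loose analytic per-class voxel-count bounds implied by the ranges.

        Ellipsoid volume 4/3 pi abc at the range endpoints, widened by slack
        factors that absorb rasterization error and carving against
        previously placed structures (documented per class).
        """
        def ell(axes, lo):
            i = 0 if lo else 1
            return 4.0 / 3.0 * math.pi * math.prod(ax[i] for ax in axes)

        cs = self.chamber_scales
        t0, t1 = self.myo_thickness
        lv_lo, lv_hi = ell(cs["LV"], True), ell(cs["LV"], False)
        shell_lo = ell([(a + t0, b + t0) for a, b in cs["LV"]], True) - lv_lo
        shell_hi = ell([(a + t1, b + t1) for a, b in cs["LV"]], False) - lv_hi
        r0, r1 = self.vessel_radius
        ln = 0.45 * self.grid[0]
        bounds = {
            1: (0.80 * lv_lo, 1.20 * lv_hi),            # LV: rasterized intact
            5: (0.40 * shell_lo, 1.70 * shell_hi),      # Myo: basal cap removed
            2: (0.35 * ell(cs["RV"], True), 1.15 * ell(cs["RV"], False)),
            3: (0.30 * ell(cs["LA"], True), 1.15 * ell(cs["LA"], False)),
            4: (0.30 * ell(cs["RA"], True), 1.15 * ell(cs["RA"], False)),
            6: (0.25 * math.pi * r0 ** 2 * 0.5 * ln, 2.0 * math.pi * r1 ** 2 * 1.6 * ln),
            7: (0.25 * math.pi * r0 ** 2 * 0.5 * ln, 2.0 * math.pi * r1 ** 2 * 1.6 * ln),
        }
        return bounds


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    """Rasterize (p-c)/a within the unit ball onto the grid."""
    out = np.zeros(shape, dtype=bool)
    lo = [max(int(math.floor(c - a)), 0) for c, a in zip(center, semiaxes)]
    hi = [min(int(math.ceil(c + a)) + 1, s) for c, a, s in
          zip(center, semiaxes, shape)]
    if any(l >= h for l, h in zip(lo, hi)):
        return out
    zz, yy, xx = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                             indexing="ij")
    q = (((zz - center[0]) / semiaxes[0]) ** 2
         + ((yy - center[1]) / semiaxes[1]) ** 2
         + ((xx - center[2]) / semiaxes[2]) ** 2)
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = q <= 1.0
    return out


def _tube_mask(shape, points: np.ndarray, radius: float) -> np.ndarray:
    """Voxels within ``radius`` of a densely sampled polyline."""
    # densify the polyline so point-to-point distance approximates
    # point-to-curve distance well below the voxel scale
    dense = []
    for a, b in zip(points[:-1], points[1:]):
        n = max(int(np.linalg.norm(b - a) * 4), 2)
        dense.append(a + np.linspace(0, 1, n)[:, None] * (b - a))
    dense = np.vstack(dense)
    lo = np.maximum(np.floor(dense.min(axis=0) - radius).astype(int), 0)
    hi = np.minimum(np.ceil(dense.max(axis=0) + radius).astype(int) + 1, shape)
    out = np.zeros(shape, dtype=bool)
    if np.any(lo >= hi):
        return out
    zz, yy, xx = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                             indexing="ij")
    pts = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1).astype(float)
    d = cKDTree(dense).query(pts)[0]
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = (
        d.reshape(zz.shape) <= radius)
    return out


def _single_component(mask: np.ndarray) -> bool:
    _, n = ndimage.label(mask, structure=_STRUCT6)
    return n == 1


def _sample(rng, rg: Range) -> float:
    return float(rng.uniform(rg[0], rg[1]))


def _rot_z(vec, deg):
    t = math.radians(deg)
    z, y, x = vec
    return np.array([z, y * math.cos(t) - x * math.sin(t),
                     y * math.sin(t) + x * math.cos(t)])


def _build_once(params: PhantomParams, rng: np.random.Generator):
    D, H, W = params.grid
    cs = params.chamber_scales
    jit = params.pose_jitter_vox
    rot = float(rng.uniform(-params.pose_jitter_deg, params.pose_jitter_deg))
    c0 = (np.array([D, H, W], dtype=float) - 1) / 2.0
    c0 += rng.uniform(-jit, jit, size=3)

    a_lv = np.array([_sample(rng, r) for r in cs["LV"]])
    a_rv = np.array([_sample(rng, r) for r in cs["RV"]])
    a_la = np.array([_sample(rng, r) for r in cs["LA"]])
    a_ra = np.array([_sample(rng, r) for r in cs["RA"]])
    thick = int(rng.integers(params.myo_thickness[0], params.myo_thickness[1] + 1))
    r_ves = _sample(rng, params.vessel_radius)

    c_lv = c0 + _rot_z([-0.08 * D, 0.0, -0.13 * W], rot)
    z_open = c_lv[0] + 0.65 * a_lv[0]

    lv = _ellipsoid_mask(params.grid, c_lv, a_lv)
    if not lv.any():
        raise PhantomPlacementError("LV fell outside the grid")
    myo_full = ndimage.binary_dilation(lv, structure=_STRUCT6, iterations=thick)
    myo = myo_full & ~lv
    zz = np.arange(D)[:, None, None]
    myo &= np.broadcast_to(zz < z_open, myo.shape)  # basal opening

    occupied = lv | myo
    vol = np.zeros(params.grid, dtype=np.int16)
    vol[lv] = 1
    vol[myo] = 5

    c_rv = c_lv + _rot_z([0.03 * D, 0.05 * H,
                          a_lv[2] + thick + 0.55 * a_rv[2]], rot)
    rv = _ellipsoid_mask(params.grid, c_rv, a_rv) & ~occupied
    vol[rv] = 2
    occupied |= rv

    c_la = c_lv + _rot_z([0.65 * a_lv[0] + 0.8 * a_la[0], -0.35 * a_lv[1], 0.0], rot)
    la = _ellipsoid_mask(params.grid, c_la, a_la) & ~occupied
    vol[la] = 3
    occupied |= la

    c_ra = c_rv + _rot_z([0.65 * a_rv[0] + 0.8 * a_ra[0], -0.25 * a_rv[1], 0.0], rot)
    ra = _ellipsoid_mask(params.grid, c_ra, a_ra) & ~occupied
    vol[ra] = 4
    occupied |= ra

    # vessels: curved tubes rising from just above each ventricle's base
    def vessel(start, direction, bend, length):
        ts = np.linspace(0.0, 1.0, 8)[:, None]
        pts = (np.asarray(start)[None, :]
               + ts * length * np.asarray(direction)[None, :]
               + (ts ** 2) * np.asarray(bend)[None, :])
        return _tube_mask(params.grid, pts, r_ves)

    ao_start = np.array([z_open + 1.0, c_lv[1] + 0.25 * a_lv[1], c_lv[2]])
    ao_len = min(0.45 * D, D - 2 - ao_start[0])
    ao = vessel(ao_start, _rot_z([1.0, 0.12, 0.10], rot),
                _rot_z([0.0, -0.25 * a_lv[1], 0.0], rot), ao_len) & ~occupied
    vol[ao] = 6
    occupied |= ao

    pa_start = np.array([c_rv[0] + 0.6 * a_rv[0], c_rv[1], c_rv[2]])
    pa_len = min(0.45 * D, D - 2 - pa_start[0])
    pa = vessel(pa_start, _rot_z([1.0, -0.10, 0.15], rot),
                _rot_z([0.0, 0.25 * a_rv[1], 0.0], rot), pa_len) & ~occupied
    vol[pa] = 7

    info = {"z_open": float(z_open), "rotation_deg": rot,
            "centers": {"LV": c_lv.tolist(), "RV": c_rv.tolist(),
                        "LA": c_la.tolist(), "RA": c_ra.tolist()},
            "semiaxes": {"LV": a_lv.tolist(), "RV": a_rv.tolist(),
                         "LA": a_la.tolist(), "RA": a_ra.tolist()},
            "myo_thickness": thick, "vessel_radius": r_ves}
    return vol, info


def _validate(vol: np.ndarray, z_open: float) -> bool:
    for c in range(1, 8):
        mask = vol == c
        if not mask.any() or not _single_component(mask):
            return False
    # LV enclosure: every face of an LV voxel whose neighbour lies below the
    # basal opening plane must touch LV or Myo
    lv = vol == 1
    ok_neigh = lv | (vol == 5)
    D = vol.shape[0]
    for ax, step in ((0, 1), (0, -1), (1, 1), (1, -1), (2, 1), (2, -1)):
        shifted = np.full(vol.shape, False)
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        if step == 1:
            src[ax], dst[ax] = slice(1, None), slice(0, -1)
        else:
            src[ax], dst[ax] = slice(0, -1), slice(1, None)
        shifted[tuple(dst)] = ok_neigh[tuple(src)]
        exposed = lv & ~shifted
        zz = np.arange(D)[:, None, None]
        neigh_z = zz + (step if ax == 0 else 0)
        below = np.broadcast_to(neigh_z < z_open, vol.shape)
        if np.any(exposed & below):
            return False  # an LV face below the opening is uncovered
    return True


def generate_phantom(params: PhantomParams, rng: np.random.Generator,
                     return_info: bool = False):
    """Sample one valid whole-heart phantom.

    Deterministic for a given generator state.  Raises
    :class:`PhantomPlacementError` when no valid configuration is found
    within ``params.max_retries`` attempts.
    """
    last_err = None
    for _ in range(params.max_retries):
        try:
            vol, info = _build_once(params, rng)
        except PhantomPlacementError as err:
            last_err = err
            continue
        if _validate(vol, info["z_open"]):
            label_vol = LabelVolume(vol, spacing=params.spacing,
                                    class_names=DEFAULT_CLASS_NAMES)
            return (label_vol, info) if return_info else label_vol
    raise PhantomPlacementError(
        f"no valid placement in {params.max_retries} attempts: {last_err}")


def generate_dataset(n: int, params: PhantomParams, out_dir,
                     rng: np.random.Generator,
                     splits: dict[str, float] | None = None) -> pd.DataFrame:
    """Write ``n`` phantoms as NIfTI plus a manifest CSV.

    Each case gets an independent child seed drawn from ``rng`` (recorded in
    the manifest), so the same master seed reproduces the same dataset.
    Split assignment cycles deterministically through the requested
    fractions.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if splits is None:
        splits = {"pretrain": 0.6, "finetune": 0.2, "test": 0.2}
    from pathlib import Path
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    names = list(splits)
    counts = [int(round(splits[k] * n)) for k in names]
    while sum(counts) < n:
        counts[0] += 1
    while sum(counts) > n:
        counts[int(np.argmax(counts))] -= 1
    assignment = [k for k, c in zip(names, counts) for _ in range(c)]

    rows = []
    for i in range(n):
        seed = int(rng.integers(0, 2 ** 31 - 1))
        vol = generate_phantom(params, np.random.default_rng(seed))
        case_id = f"case_{i:04d}"
        path = out_dir / f"{case_id}.nii.gz"
        write_label_volume(vol, path)
        row = {"case_id": case_id, "seed": seed, "split": assignment[i],
               "path": str(path)}
        for c, name in enumerate(DEFAULT_CLASS_NAMES):
            if c == 0:
                continue
            row[f"n_{name}"] = int(np.count_nonzero(vol.voxels == c))
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
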