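"""Geometry-metric checks against closed forms and brute-force oracles."""

import numpy as np
import pytest

from cardiorecon.io import LabelVolume
from cardiorecon.metrics import (MetricsReport, assd,
                                 curvature_distance_correlation,
                                 curvature_variation_rate, dice_coefficient,
                                 evaluate_case, hd95,
                                 mean_curvature_intensity, surface_area,
                                 surface_distances)

# ---------------------------------------------------------------- oracles


def brute_surface_area(mask, spacing):
    """Count exposed faces by explicit neighbour enumeration."""
    sz, sy, sx = spacing
    areas = {0: sy * sx, 1: sz * sx, 2: sz * sy}
    total = 0.0
    idx = np.argwhere(mask)
    for z, y, x in idx:
        for ax, (dz, dy, dx_) in zip((0, 0, 1, 1, 2, 2),
                                     [(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                      (0, -1, 0), (0, 0, 1), (0, 0, -1)]):
            nz, ny, nx = z + dz, y + dy, x + dx_
            inside = (0 <= nz < mask.shape[0] and 0 <= ny < mask.shape[1]
                      and 0 <= nx < mask.shape[2])
            if not inside or not mask[nz, ny, nx]:
                total += areas[ax]
    return total


def brute_boundary(mask):
    out = np.zeros_like(mask)
    for z, y, x in np.argwhere(mask):
        for dz, dy, dx in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)]:
            nz, ny, nx = z + dz, y + dy, x + dx
            inside = (0 <= nz < mask.shape[0] and 0 <= ny < mask.shape[1]
                      and 0 <= nx < mask.shape[2])
            if not inside or not mask[nz, ny, nx]:
                out[z, y, x] = True
                break
    return out


def brute_surface_distances(a, b, spacing):
    sp = np.asarray(spacing)
    pa = np.argwhere(brute_boundary(a)) * sp
    pb = np.argwhere(brute_boundary(b)) * sp
    d_ab = [min(np.linalg.norm(p - q) for q in pb) for p in pa]
    d_ba = [min(np.linalg.norm(q - p) for p in pa) for q in pb]
    return np.array(d_ab + d_ba)


def random_mask(rng, shape, p=0.4):
    while True:
        m = rng.random(shape) < p
        if m.any():
            return m


# ------------------------------------------------------------------ tests


def test_surface_area_closed_forms():
    one = np.zeros((3, 3, 3), bool)
    one[1, 1, 1] = True
    assert surface_area(one, (1, 1, 1)) == pytest.approx(6.0)
    # anisotropic single voxel: 2 z-faces (sy*sx) + 2 y-faces (sz*sx)
    # + 2 x-faces (sz*sy) with spacing (0.5, 0.5, 2)
    assert surface_area(one, (0.5, 0.5, 2.0)) == pytest.approx(4.5)
    cube = np.ones((10, 10, 10), bool)
    assert surface_area(cube, (1, 1, 1)) == pytest.approx(600.0)


def test_kappa_closed_form_and_scaling():
    cube = np.ones((10, 10, 10), bool)
    k1 = mean_curvature_intensity(cube, (1, 1, 1))
    assert k1 == pytest.approx(0.6)
    k2 = mean_curvature_intensity(cube, (2, 2, 2))
    assert k2 == pytest.approx(k1 / 2, abs=1e-12)
    one = np.zeros((3, 3, 3), bool)
    one[1, 1, 1] = True
    assert mean_curvature_intensity(one, (1, 1, 1)) == pytest.approx(6.0)


def test_kappa_empty_mask_is_an_error():
    with pytest.raises(ValueError):
        mean_curvature_intensity(np.zeros((3, 3, 3), bool), (1, 1, 1))


def test_surface_area_matches_bruteforce_oracle(rng):
    for _ in range(25):
        shape = tuple(rng.integers(2, 8, size=3))
        spacing = tuple(rng.uniform(0.5, 3.0, size=3))
        m = random_mask(rng, shape)
        assert surface_area(m, spacing) == pytest.approx(
            brute_surface_area(m, spacing), rel=1e-9)


def test_isoperimetric_direction():
    """Among equal-volume shapes, the compact cube has the lowest kappa."""
    cube = np.zeros((10, 10, 10), bool)
    cube[1:5, 1:5, 1:5] = True  # 4x4x4 = 64 voxels
    rod = np.zeros((4, 10, 10), bool)
    rod[1, 1:9, 1:9] = True  # 64 voxels, flat slab
    assert (mean_curvature_intensity(cube, (1, 1, 1))
            < mean_curvature_intensity(rod, (1, 1, 1)))


def test_curvature_variation_rate():
    assert curvature_variation_rate(0.6, 0.6) == 0.0
    assert curvature_variation_rate(0.6, 0.3) == pytest.approx(0.5)
    assert curvature_variation_rate(0.6, 0.9) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        curvature_variation_rate(0.0, 0.5)


def test_dice_direct_counts():
    a = np.zeros((3, 4, 4), np.int16)
    b = np.zeros((3, 4, 4), np.int16)
    a.ravel()[:10] = 1
    b.ravel()[5:15] = 1
    per, mean = dice_coefficient(LabelVolume(a), LabelVolume(b))
    assert per[1] == pytest.approx(0.5)
    assert mean == pytest.approx(0.5)


def test_dice_identity_and_disjoint(random_volume):
    per, mean = dice_coefficient(random_volume, random_volume)
    assert all(v == 1.0 for v in per.values()) and mean == 1.0
    a = np.zeros((2, 3, 3), np.int16)
    b = np.zeros((2, 3, 3), np.int16)
    a[0, 0, 0] = 1
    b[1, 1, 1] = 1
    assert dice_coefficient(LabelVolume(a), LabelVolume(b))[1] == 0.0


def test_distances_identity_and_offset():
    m = np.zeros((8, 8, 8), bool)
    m[2:5, 2:5, 2:5] = True
    assert hd95(m, m, (1, 1, 1)) == 0.0
    assert assd(m, m, (1, 1, 1)) == 0.0
    a = np.zeros((8, 4, 4), bool)
    b = np.zeros((8, 4, 4), bool)
    a[1, 1, 1] = True
    b[4, 1, 1] = True
    assert hd95(a, b, (1, 1, 1)) == pytest.approx(3.0)
    assert assd(a, b, (1, 1, 1)) == pytest.approx(3.0)


def test_distances_match_bruteforce_oracle(rng):
    for _ in range(25):
        shape = tuple(rng.integers(3, 8, size=3))
        spacing = tuple(rng.uniform(0.5, 2.5, size=3))
        a = random_mask(rng, shape)
        b = random_mask(rng, shape)
        got = np.sort(surface_distances(a, b, spacing))
        want = np.sort(brute_surface_distances(a, b, spacing))
        np.testing.assert_allclose(got, want, atol=1e-9)
        assert hd95(a, b, spacing) == pytest.approx(
            np.percentile(want, 95), abs=1e-9)
        assert assd(a, b, spacing) == pytest.approx(want.mean(), abs=1e-9)


def test_distance_metrics_symmetric(rng):
    a = random_mask(rng, (6, 6, 6))
    b = random_mask(rng, (6, 6, 6))
    sp = (2.0, 1.0, 1.0)
    assert hd95(a, b, sp) == pytest.approx(hd95(b, a, sp))
    assert assd(a, b, sp) == pytest.approx(assd(b, a, sp))


def test_empty_mask_distance_is_an_error():
    m = np.zeros((3, 3, 3), bool)
    n = m.copy()
    n[0, 0, 0] = True
    with pytest.raises(ValueError):
        hd95(m, n, (1, 1, 1))


def test_class_permutation_invariance(rng):
    a = rng.integers(0, 4, size=(5, 6, 6)).astype(np.int16)
    b = rng.integers(0, 4, size=(5, 6, 6)).astype(np.int16)
    perm = {0: 0, 1: 3, 2: 1, 3: 2}
    ap = np.vectorize(perm.get)(a).astype(np.int16)
    bp = np.vectorize(perm.get)(b).astype(np.int16)
    _, m1 = dice_coefficient(LabelVolume(a), LabelVolume(b))
    _, m2 = dice_coefficient(LabelVolume(ap), LabelVolume(bp))
    assert m1 == pytest.approx(m2)


def test_correlation_exact_lines():
    reports = []
    for i, k in enumerate([0.1, 0.2, 0.3, 0.4]):
        r = MetricsReport(case_id=str(i))
        r.kappa_post = {1: k}
        r.hd95_mean = 2 * k
        r.assd_mean = -k
        reports.append(r)
    r_h, r_a, p_h, p_a = curvature_distance_correlation(reports)
    assert r_h == pytest.approx(1.0)
    assert r_a == pytest.approx(-1.0)


def test_evaluate_case_identity(desk_phantom):
    rep = evaluate_case(desk_phantom, desk_phantom, pre=desk_phantom,
                        case_id="c0", severity="easy")
    assert rep.dice_mean == pytest.approx(1.0)
    assert rep.hd95_mean == 0.0 and rep.assd_mean == 0.0
    assert rep.r_kappa_mean == pytest.approx(0.0)
    frame = rep.to_frame()
    assert list(frame.columns) == list(MetricsReport._COLUMNS)
    assert frame.iloc[-1]["class_id"] == "mean"
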