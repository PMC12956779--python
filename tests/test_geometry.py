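"""Unit tests for centerline extraction, straightening, scaling and TPS."""

import numpy as np
import pytest

from cordmorph import (LABELS, ScaleFactors, VoxelLabelVolume, apply_scale,
                       apply_tps, cord_extents, estimate_scale,
                       extract_centerline, fit_tps, straighten_volume)
from cordmorph.geometry import EmptySliceError, SingularLandmarksError


def _straight_cylinder(radius=1.0, length=12.0, spacing=0.1):
    n_xy = int(round(2 * (radius + 0.5) / spacing))
    n_z = int(round(length / spacing))
    x = (np.arange(n_xy) - (n_xy - 1) / 2) * spacing
    X, Y = np.meshgrid(x, x, indexing="ij")
    disk = (X**2 + Y**2) <= radius**2
    arr = np.zeros((n_xy, n_xy, n_z), dtype=np.int16)
    arr[disk] = LABELS["white_matter"]
    origin = (-(n_xy - 1) / 2 * spacing, -(n_xy - 1) / 2 * spacing, 0.0)
    return VoxelLabelVolume(arr, (spacing,) * 3, origin)


def test_centerline_of_straight_cylinder_is_axis():
    vol = _straight_cylinder()
    cl = extract_centerline(vol)
    assert np.abs(cl.points[:, :2]).max() < 0.05
    # arc length ~ cylinder length
    assert cl.arc_length[-1] == pytest.approx(12.0, abs=0.3)


def test_centerline_rejects_empty_volume():
    vol = _straight_cylinder()
    empty = vol.copy()
    empty.array[:] = 0
    with pytest.raises(EmptySliceError):
        extract_centerline(empty)


def test_straighten_straight_volume_is_near_identity():
    vol = _straight_cylinder()
    cl = extract_centerline(vol)
    out = straighten_volume(vol, cl)
    n_in = (vol.array > 0).sum()
    n_out = (out.array > 0).sum()
    assert abs(n_out - n_in) / n_in < 0.02


def test_scale_factors_validation_and_multipliers():
    f = ScaleFactors(10.0, 10.0, 45.0)
    assert f.multipliers() == pytest.approx((1.10, 1.10, 1.45))
    with pytest.raises(ValueError):
        ScaleFactors(-150.0, 0.0, 0.0)


def _tapered_cylinder(r0=1.2, r1=1.8, length=15.0, spacing=0.1):
    # varying radius so per-slice extents dither the voxel quantisation
    n_xy = int(round(2 * (r1 + 0.5) / spacing))
    n_z = int(round(length / spacing))
    x = (np.arange(n_xy) - (n_xy - 1) / 2) * spacing
    X, Y = np.meshgrid(x, x, indexing="ij")
    arr = np.zeros((n_xy, n_xy, n_z), dtype=np.int16)
    for k in range(n_z):
        r = r0 + (r1 - r0) * k / (n_z - 1)
        arr[:, :, k][(X**2 + Y**2) <= r**2] = LABELS["white_matter"]
    origin = (-(n_xy - 1) / 2 * spacing, -(n_xy - 1) / 2 * spacing, 0.0)
    return VoxelLabelVolume(arr, (spacing,) * 3, origin)


def test_apply_scale_then_estimate_round_trip():
    vol = _tapered_cylinder()
    ref = cord_extents(vol)
    from cordmorph import shrink_volume
    shrunk = shrink_volume(vol, (10.0, 10.0, 45.0))
    est = estimate_scale(shrunk, ref)
    assert est.ex == pytest.approx(10.0, abs=1.5)
    assert est.ey == pytest.approx(10.0, abs=1.5)
    assert est.ez == pytest.approx(45.0, abs=1.5)
    restored = apply_scale(shrunk, est)
    w, h, z = cord_extents(restored)
    assert w == pytest.approx(ref[0], rel=0.02)
    assert z == pytest.approx(ref[2], rel=0.02)


def test_tps_identity_is_exact():
    rng = np.random.default_rng(3)
    pts = rng.uniform(-3, 3, size=(12, 2))
    w = fit_tps(pts, pts)
    assert np.abs(w.transform(pts) - pts).max() < 1e-9
    probe = rng.uniform(-3, 3, size=(50, 2))
    assert np.abs(w.transform(probe) - probe).max() < 1e-9


def test_tps_interpolates_landmarks_exactly():
    rng = np.random.default_rng(4)
    src = rng.uniform(-3, 3, size=(10, 2))
    tgt = src + rng.normal(scale=0.3, size=src.shape)
    w = fit_tps(src, tgt)
    assert np.abs(w.transform(src) - tgt).max() < 1e-9


def test_tps_translation_is_global():
    rng = np.random.default_rng(5)
    src = rng.uniform(-3, 3, size=(8, 2))
    shift = np.array([0.7, -0.4])
    w = fit_tps(src, src + shift)
    probe = rng.uniform(-10, 10, size=(100, 2))
    assert np.abs(w.transform(probe) - (probe + shift)).max() < 1e-9


def test_tps_collinear_landmarks_rejected():
    src = np.column_stack([np.linspace(0, 1, 6), np.linspace(0, 2, 6)])
    with pytest.raises(SingularLandmarksError):
        fit_tps(src, src + 0.1)


def test_tps_regularization_smooths():
    rng = np.random.default_rng(6)
    src = rng.uniform(-3, 3, size=(10, 2))
    tgt = src + rng.normal(scale=0.3, size=src.shape)
    exact = fit_tps(src, tgt)
    smooth = fit_tps(src, tgt, regularization=10.0)
    res_exact = np.abs(exact.transform(src) - tgt).max()
    res_smooth = np.abs(smooth.transform(src) - tgt).max()
    assert res_exact < 1e-9 < res_smooth


def test_apply_tps_translates_volume():
    vol = _straight_cylinder(radius=1.0, length=6.0)
    src = np.array([[x, y] for x in (-2.0, 0.0, 2.0) for y in (-2.0, 0.0, 2.0)])
    warps = []
    for z in (1.0, 3.0, 5.0):
        w = fit_tps(src, src + np.array([0.3, 0.0]))
        w.plane_z = z
        warps.append(w)
    out = apply_tps(vol, warps)
    m0 = np.array(np.nonzero(vol.array > 0)).mean(axis=1)
    m1 = np.array(np.nonzero(out.array > 0)).mean(axis=1)
    shift_mm = (m1 - m0) * vol.spacing
    assert shift_mm == pytest.approx([0.3, 0.0, 0.0], abs=1e-6)
    assert (out.array > 0).sum() == (vol.array > 0).sum()
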