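"""Unit tests for contour extraction, lofting and mesh metrics."""

import math

import numpy as np
import pytest

from cordmorph import (LABELS, VoxelLabelVolume, extract_profiles,
                       loft_profiles, mesh_metrics)
from cordmorph.reconstruct import ProfileStack, TooShortError


def _cylinder(radius=2.0, length=10.0, spacing=0.1, taper=0.0):
    n_xy = int(round(2 * (radius + 0.5) / spacing))
    n_z = int(round(length / spacing))
    x = (np.arange(n_xy) - (n_xy - 1) / 2) * spacing
    X, Y = np.meshgrid(x, x, indexing="ij")
    arr = np.zeros((n_xy, n_xy, n_z), dtype=np.int16)
    for k in range(n_z):
        r = radius * (1.0 - taper * k / max(n_z - 1, 1))
        arr[:, :, k][(X**2 + Y**2) <= r**2] = LABELS["white_matter"]
    origin = (-(n_xy - 1) / 2 * spacing, -(n_xy - 1) / 2 * spacing, 0.0)
    return VoxelLabelVolume(arr, (spacing,) * 3, origin)


def test_profiles_shape_and_equal_arc():
    vol = _cylinder()
    stack = extract_profiles(vol, "white_matter", n_profiles=50, n_points=40)
    assert len(stack.contours) == 50
    zs = [c.z for c in stack.contours]
    assert np.all(np.diff(zs) > 0)
    for c in stack.contours[::10]:
        assert c.points.shape == (40, 2)
        # equal arc spacing: consecutive gaps nearly constant
        closed = np.vstack([c.points, c.points[:1]])
        gaps = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        assert gaps.std() / gaps.mean() < 0.05
        # counter-clockwise orientation (positive signed area)
        assert c.signed_area() > 0


def test_cylinder_volume_and_area():
    radius, length = 2.0, 10.0
    vol = _cylinder(radius, length)
    mesh = loft_profiles(extract_profiles(vol, "white_matter",
                                          n_profiles=100, n_points=64))
    m = mesh_metrics(mesh)
    assert m.volume == pytest.approx(math.pi * radius**2 * length, rel=0.02)
    lateral = 2 * math.pi * radius * length
    caps = 2 * math.pi * radius**2
    assert m.surface_area == pytest.approx(lateral + caps, rel=0.05)
    assert m.watertight
    assert m.euler_characteristic == 2


def test_frustum_volume():
    vol = _cylinder(radius=2.0, length=10.0, taper=0.5)  # r: 2.0 -> 1.0
    mesh = loft_profiles(extract_profiles(vol, "white_matter",
                                          n_profiles=100, n_points=64))
    m = mesh_metrics(mesh)
    r0, r1, h = 2.0, 1.0, 10.0
    analytic = math.pi * h / 3 * (r0**2 + r0 * r1 + r1**2)
    assert m.volume == pytest.approx(analytic, rel=0.02)
    assert m.watertight


def test_winding_gives_positive_volume():
    vol = _cylinder()
    mesh = loft_profiles(extract_profiles(vol, "white_matter",
                                          n_profiles=30, n_points=30))
    assert mesh_metrics(mesh).volume > 0


def test_profile_stack_validation():
    sq = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    from cordmorph.reconstruct import Contour
    with pytest.raises(ValueError):
        # z not strictly increasing
        ProfileStack([Contour(1.0, sq), Contour(1.0, sq)], n_points=4)
    with pytest.raises(TooShortError):
        ProfileStack([Contour(0.0, sq)], n_points=4)
    with pytest.raises(ValueError):
        # mismatched point counts
        ProfileStack([Contour(0.0, sq), Contour(1.0, sq[:3])], n_points=4)


def test_loft_union_envelope_labels(small_volume):
    # shell labels are lofted as filled envelopes (union of enclosed labels)
    stack = extract_profiles(small_volume,
                             ("white_matter", "gray_matter", "csf"),
                             n_profiles=40, n_points=40)
    m = mesh_metrics(loft_profiles(stack))
    env = np.isin(small_volume.array, (1, 2, 3))
    import scipy.ndimage as ndi
    filled = np.stack([ndi.binary_fill_holes(env[:, :, k])
                       for k in range(env.shape[2])], axis=-1)
    voxel_vol = filled.sum() * small_volume.voxel_volume()
    assert m.volume == pytest.approx(voxel_vol, rel=0.05)
    assert m.watertight
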