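"""Unit tests for the voxel volume container."""

import numpy as np
import pytest

from cordmorph import LABELS, VoxelLabelVolume, cord_extents, cord_mask, pad_volume


def _vol(shape=(4, 5, 6), spacing=(0.1, 0.2, 0.3), origin=(1.0, 2.0, 3.0)):
    return VoxelLabelVolume(np.zeros(shape, dtype=np.int16), spacing, origin)


def test_rejects_non_integer_dtype():
    with pytest.raises(TypeError):
        VoxelLabelVolume(np.zeros((2, 2, 2), dtype=float), (1, 1, 1))


def test_rejects_bad_rank_and_spacing():
    with pytest.raises(ValueError):
        VoxelLabelVolume(np.zeros((2, 2), dtype=np.int16), (1, 1, 1))
    with pytest.raises(ValueError):
        VoxelLabelVolume(np.zeros((2, 2, 2), dtype=np.int16), (1, 0, 1))


def test_index_world_round_trip():
    v = _vol()
    idx = np.array([[1, 2, 3], [0, 0, 0]], dtype=float)
    back = v.world_to_index(v.index_to_world(idx))
    assert np.allclose(back, idx)
    # world of voxel (0,0,0) is the origin (voxel-centre convention)
    assert np.allclose(v.index_to_world([0, 0, 0]), v.origin)


def test_z_slice_range_half_open():
    v = _vol(spacing=(1, 1, 1), origin=(0, 0, 0))
    sl = v.z_slice_range(1.0, 3.0)          # centres at 1 and 2, not 3
    assert (sl.start, sl.stop) == (1, 3)
    assert v.z_slice_range(100.0, 200.0) == slice(0, 0)


def test_voxel_volume_and_counts():
    v = _vol(spacing=(0.1, 0.1, 0.1))
    v.array[0, 0, :2] = LABELS["white_matter"]
    assert v.voxel_volume() == pytest.approx(1e-3)
    assert v.label_counts()[LABELS["white_matter"]] == 2


def test_pad_volume_preserves_world_positions():
    v = _vol(spacing=(0.1, 0.1, 0.1), origin=(0, 0, 0))
    v.array[2, 3, 4] = 1
    p = pad_volume(v, 0.25, axes=(0, 1))
    # padded by ceil(0.25/0.1)=3 voxels on each side of x and y
    assert p.shape == (4 + 6, 5 + 6, 6)
    assert p.array[5, 6, 4] == 1
    w_old = v.index_to_world([2, 3, 4])
    w_new = p.index_to_world([5, 6, 4])
    assert np.allclose(w_old, w_new)


def test_cord_mask_and_extents():
    v = _vol(shape=(10, 10, 4), spacing=(0.1, 0.1, 0.1))
    v.array[2:8, 3:7, 1:3] = LABELS["white_matter"]
    v.array[4:6, 4:6, 1:3] = LABELS["gray_matter"]
    assert cord_mask(v).sum() == 6 * 4 * 2
    w, h, z = cord_extents(v)
    assert w == pytest.approx(0.6)
    assert h == pytest.approx(0.4)
    assert z == pytest.approx(0.2)


def test_cord_extents_requires_cord():
    with pytest.raises(ValueError):
        cord_extents(_vol())
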