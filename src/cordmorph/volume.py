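"""Labeled voxel volumes.

The universal container passed between the phantom generator, the geometric
processing chain and the morphometry stage.  Axes follow the anatomical
convention used throughout the package:

* ``x`` — mediolateral (index 0),
* ``y`` — dorsoventral, dorsal = +y (index 1),
* ``z`` — rostrocaudal (index 2).

World coordinates are millimetres; ``world = origin + index * spacing`` with
0-based, voxel-centre indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: Fixed label vocabulary shared by every stage.
LABELS: dict[str, int] = {
    "background": 0,
    "white_matter": 1,
    "gray_matter": 2,
    "csf": 3,
    "dura": 4,
    "dorsal_rootlet": 5,
    "ventral_rootlet": 6,
    "drg": 7,
}

#: Labels forming the spinal cord proper (used for centrelines, extents...).
CORD_LABELS = (LABELS["white_matter"], LABELS["gray_matter"])


@dataclass
class VoxelLabelVolume:
    """3D integer label grid with physical spacing and origin."""

    array: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label_map: Mapping[str, int] = field(default_factory=lambda: dict(LABELS))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array)
        if self.array.ndim != 3:
            raise ValueError("label array must be 3D (x, y, z)")
        if not np.issubdtype(self.array.dtype, np.integer):
            raise TypeError("label array must have an integer dtype")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        self.origin = tuple(float(o) for o in self.origin)

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.array.shape

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        world = np.asarray(world, dtype=float)
        return (world - np.asarray(self.origin)) / np.asarray(self.spacing)

    def z_coords(self) -> np.ndarray:
        """World z of every slice centre."""
        return self.origin[2] + np.arange(self.shape[2]) * self.spacing[2]

    def z_slice_range(self, z_start: float, z_end: float) -> slice:
        """Slice object selecting voxels whose centre lies in [z_start, z_end)."""
        z = self.z_coords()
        inside = np.nonzero((z >= z_start) & (z < z_end))[0]
        if inside.size == 0:
            return slice(0, 0)
        return slice(int(inside[0]), int(inside[-1]) + 1)

    def voxel_volume(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def label_counts(self) -> dict[int, int]:
        values, counts = np.unique(self.array, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}

    def copy(self) -> "VoxelLabelVolume":
        return VoxelLabelVolume(
            array=self.array.copy(),
            spacing=self.spacing,
            origin=self.origin,
            label_map=dict(self.label_map),
            meta=dict(self.meta),
        )


def pad_volume(volume: VoxelLabelVolume, pad_mm: float,
               axes: tuple[int, ...] = (0,)) -> VoxelLabelVolume:
    """Pad the grid with background along the given axes (both directions).

    Used to give deformations headroom before they push structures past the
    grid boundary.
    """
    pads = [(0, 0)] * 3
    for ax in axes:
        n = int(np.ceil(pad_mm / volume.spacing[ax]))
        pads[ax] = (n, n)
    arr = np.pad(volume.array, pads, mode="constant")
    origin = list(volume.origin)
    for ax in axes:
        origin[ax] -= pads[ax][0] * volume.spacing[ax]
    out = volume.copy()
    out.array = arr
    out.origin = tuple(origin)
    return out


def cord_mask(volume: VoxelLabelVolume) -> np.ndarray:
    """Boolean mask of white + gray matter."""
    return np.isin(volume.array, CORD_LABELS)


def cord_extents(volume: VoxelLabelVolume) -> tuple[float, float, float]:
    """Bounding z-length and average cross-sectional width/height of the cord.

    Width (x) and height (y) are per-slice bounding extents of the cord
    labels, summarised by the mean over slices that contain cord; because
    the cord's width varies along its length, averaging dithers away the
    one-voxel quantisation of each slice's extent, which a median would
    retain.  The z extent is the bounding length.  All values in mm.
    """
    mask = cord_mask(volume)
    if not mask.any():
        raise ValueError("degenerate: no cord labels present")
    sx, sy, sz = volume.spacing
    zs = np.nonzero(mask.any(axis=(0, 1)))[0]
    z_extent = (zs[-1] - zs[0] + 1) * sz
    widths = []
    heights = []
    for k in zs:
        sl = mask[:, :, k]
        xs = np.nonzero(sl.any(axis=1))[0]
        ys = np.nonzero(sl.any(axis=0))[0]
        widths.append((xs[-1] - xs[0] + 1) * sx)
        heights.append((ys[-1] - ys[0] + 1) * sy)
    return float(np.mean(widths)), float(np.mean(heights)), float(z_extent)
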