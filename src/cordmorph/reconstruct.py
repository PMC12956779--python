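"""Simplified 3D reconstruction by contour lofting.

A labeled volume is reduced to a stack of fixed-size closed planar profiles
(one periodic spline per axial plane, resampled by equal arc length from a
dorsal seam) and lofted into a capped, watertight triangle mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import splev, splprep
from skimage import measure as skmeasure

from .volume import VoxelLabelVolume

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class MultiComponentSliceError(ValueError):
    """A sampled slice has more than one boundary loop for the label."""


class TooShortError(ValueError):
    """Fewer than two profile planes are available."""


class DegenerateContourError(ValueError):
    """A contour encloses (near-)zero area."""


@dataclass
class Contour:
    """Closed planar loop at one axial position.

    Points are ordered counterclockwise viewed from rostral, starting at the
    dorsal-most point (seam convention); the closing edge from the last
    point back to the first is implicit.
    """

    z: float
    points: np.ndarray  # (n, 2) in-plane mm, not repeated at the end

    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class ProfileStack:
    contours: list[Contour]
    n_points: int

    def __post_init__(self) -> None:
        if len(self.contours) < 2:
            raise TooShortError("too short: a profile stack needs >= 2 contours")
        zs = [c.z for c in self.contours]
        if not all(b > a for a, b in zip(zs, zs[1:])):
            raise ValueError("contour z values must be strictly increasing")
        if any(len(c.points) != self.n_points for c in self.contours):
            raise ValueError("all contours must share n_points")

    def to_table(self):
        """Long-form (z, point_index, x, y) array for CSV serialization."""
        rows = []
        for c in self.contours:
            for j, (x, y) in enumerate(c.points):
                rows.append((c.z, j, x, y))
        return np.asarray(rows)


@dataclass
class TriMesh:
    vertices: np.ndarray          # (V, 3) mm
    faces: np.ndarray             # (F, 3) int vertex indices
    provenance: str = ""
    meta: dict = field(default_factory=dict)


@dataclass
class MeshMetrics:
    volume: float
    surface_area: float
    watertight: bool
    n_faces: int
    euler_characteristic: int


# ---------------------------------------------------------------------------
# profile extraction
# ---------------------------------------------------------------------------

def _slice_contour(mask: np.ndarray, spacing, origin) -> np.ndarray:
    """Sub-voxel boundary loop of a single-component 2D mask (world mm)."""
    n_comp = ndimage.label(mask, structure=np.ones((3, 3)))[1]
    if n_comp != 1:
        raise MultiComponentSliceError(
            f"multi-component slice: {n_comp} boundary loops for the label")
    filled = ndimage.binary_fill_holes(mask)
    f = ndimage.gaussian_filter(filled.astype(float), 0.8)
    contours = skmeasure.find_contours(f, 0.5)
    if not contours:
        raise DegenerateContourError("degenerate contour: label too small to trace")
    best = max(contours, key=len)
    pts = np.asarray(origin)[None, :2] + best * np.asarray(spacing)[None, :2]
    if np.linalg.norm(pts[0] - pts[-1]) > 1e-9:
        pts = np.vstack([pts, pts[:1]])
    return pts


def _resample_closed(pts: np.ndarray, n_points: int) -> np.ndarray:
    """Equal-arc-length resampling of a closed loop from the dorsal-most
    point, counterclockwise; returns (n_points, 2) without the repeat."""
    closed = pts
    if np.linalg.norm(closed[0] - closed[-1]) > 1e-9:
        closed = np.vstack([closed, closed[:1]])
    # periodic interpolating spline through the traced boundary
    x, y = closed[:-1, 0], closed[:-1, 1]
    keep = np.ones(len(x), dtype=bool)
    keep[1:] = np.hypot(np.diff(x), np.diff(y)) > 1e-12
    x, y = x[keep], y[keep]
    tck, _ = splprep([x, y], per=True, s=0, k=min(3, len(x) - 1))
    dense_u = np.linspace(0.0, 1.0, 4096, endpoint=False)
    dx, dy = splev(dense_u, tck)
    dense = np.column_stack([dx, dy])

    # orientation: counterclockwise (positive shoelace area)
    area = 0.5 * float(np.sum(dense[:, 0] * np.roll(dense[:, 1], -1)
                              - np.roll(dense[:, 0], -1) * dense[:, 1]))
    if area < 0:
        dense = dense[::-1]
    # seam: dorsal-most point (max y)
    start = int(np.argmax(dense[:, 1]))
    dense = np.roll(dense, -start, axis=0)
    seg = np.linalg.norm(np.diff(dense, axis=0, append=dense[:1]), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    targets = np.arange(n_points) * total / n_points
    out_x = np.interp(targets, arc[:-1], dense[:, 0], period=None)
    out_y = np.interp(targets, arc[:-1], dense[:, 1], period=None)
    return np.column_stack([out_x, out_y])


def extract_profiles(volume: VoxelLabelVolume, label,
                     n_profiles: int = 200, n_points: int = 40) -> ProfileStack:
    """Evenly spaced axial profiles of one label as fixed-size closed loops.

    ``n_profiles`` planes span the label's z-extent with endpoints inset by
    half a step; each plane's sub-voxel boundary is fitted by a periodic
    spline and resampled to ``n_points`` by equal arc length starting at the
    dorsal-most point, counterclockwise.  ``label`` may be a single code or
    name, or a sequence of them (the union's outer envelope is traced, with
    interior holes filled).
    """
    if isinstance(label, (list, tuple, set, frozenset)):
        codes = [volume.label_map[x] if isinstance(x, str) else int(x)
                 for x in label]
    else:
        codes = [volume.label_map[label] if isinstance(label, str) else int(label)]
    mask3 = np.isin(volume.array, codes)
    occ = np.nonzero(mask3.any(axis=(0, 1)))[0]
    if occ.size < 2:
        raise TooShortError("too short: label spans fewer than 2 slices")
    sz = volume.spacing[2]
    z_lo = volume.origin[2] + occ[0] * sz - sz / 2
    z_hi = volume.origin[2] + occ[-1] * sz + sz / 2
    step = (z_hi - z_lo) / n_profiles
    zc = volume.z_coords()
    contours: list[Contour] = []
    for i in range(n_profiles):
        z = z_lo + (i + 0.5) * step
        k = int(np.argmin(np.abs(zc - z)))
        pts = _slice_contour(mask3[:, :, k], volume.spacing, volume.origin)
        contours.append(Contour(z=z, points=_resample_closed(pts, n_points)))
    return ProfileStack(contours=contours, n_points=n_points)


# ---------------------------------------------------------------------------
# lofting
# ---------------------------------------------------------------------------

def loft_profiles(stack: ProfileStack, provenance: str = "loft") -> TriMesh:
    """Skin the profile stack into a capped, watertight triangle mesh.

    Corresponding points (same index) of consecutive contours form quad
    strips split along the shorter diagonal; the end contours are closed by
    triangle fans about their centroids; faces are wound so normals point
    outward.
    """
    n = stack.n_points
    for c in stack.contours:
        if abs(c.signed_area()) < 1e-9:
            raise DegenerateContourError("degenerate contour: near-zero area")

    rings = []
    verts: list[np.ndarray] = []
    for c in stack.contours:
        base = len(verts)
        verts.extend(np.column_stack([c.points, np.full(n, c.z)]))
        rings.append(base)
    v_bottom = len(verts)
    verts.append(np.append(stack.contours[0].centroid(), stack.contours[0].z))
    v_top = len(verts)
    verts.append(np.append(stack.contours[-1].centroid(), stack.contours[-1].z))
    vertices = np.asarray(verts, dtype=np.float64)

    faces: list[tuple[int, int, int]] = []
    for r0, r1 in zip(rings[:-1], rings[1:]):
        for j in range(n):
            j1 = (j + 1) % n
            a, b = r0 + j, r0 + j1
            c_, d = r1 + j1, r1 + j
            if (np.linalg.norm(vertices[a] - vertices[c_])
                    <= np.linalg.norm(vertices[b] - vertices[d])):
                faces.append((a, b, c_))
                faces.append((a, c_, d))
            else:
                faces.append((a, b, d))
                faces.append((b, c_, d))
    r_bot, r_top = rings[0], rings[-1]
    for j in range(n):
        j1 = (j + 1) % n
        faces.append((v_bottom, r_bot + j1, r_bot + j))
        faces.append((v_top, r_top + j, r_top + j1))

    mesh = TriMesh(vertices=vertices, faces=np.asarray(faces, dtype=np.int64),
                   provenance=provenance)
    if mesh_metrics(mesh).volume < 0:
        mesh.faces = mesh.faces[:, ::-1]
    return mesh


def mesh_metrics(mesh: TriMesh) -> MeshMetrics:
    """Signed volume (divergence theorem), area, watertightness, topology."""
    v = mesh.vertices
    f = mesh.faces
    p0, p1, p2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    cross = np.cross(p1 - p0, p2 - p0)
    volume = float(np.einsum("ij,ij->i", p0, np.cross(p1, p2)).sum() / 6.0)
    area = float(0.5 * np.linalg.norm(cross, axis=1).sum())

    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    und = np.sort(edges, axis=1)
    _, counts = np.unique(und, axis=0, return_counts=True)
    watertight = bool(np.all(counts == 2))
    n_e = len(counts)
    euler = int(len(np.unique(f)) - n_e + len(f))
    return MeshMetrics(volume=volume, surface_area=area, watertight=watertight,
                       n_faces=int(len(f)), euler_characteristic=euler)
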