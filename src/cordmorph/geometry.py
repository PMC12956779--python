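"""Geometric processing chain: centreline extraction, curved-planar-reformat
straightening, anisotropic scale estimation/application and per-plane
thin-plate-spline landmark warping.

All label resampling is nearest-neighbour (labels are categorical) and no
operation may invent label values that were not in its input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import LSQUnivariateSpline, interp1d

from .volume import CORD_LABELS, VoxelLabelVolume, cord_mask


class EmptySliceError(ValueError):
    """Too many slices contain none of the selected labels."""


class DisconnectedError(ValueError):
    """The selected labels do not form one connected cord."""


class FrameFlipError(ValueError):
    """Consecutive centreline frames rotate by more than 45 degrees."""


class SingularLandmarksError(ValueError):
    """Collinear landmarks make the TPS system singular."""


# ---------------------------------------------------------------------------
# centreline
# ---------------------------------------------------------------------------

@dataclass
class Centerline:
    """Ordered 3D curve with arc-length parameterisation and
    rotation-minimising orthonormal frames (tangent, normal, binormal)."""

    points: np.ndarray      # (n, 3) world mm
    arc_length: np.ndarray  # (n,) cumulative mm, strictly increasing
    frames: np.ndarray      # (n, 3, 3): rows tangent, normal, binormal

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])


def _rmf_frames(points: np.ndarray) -> np.ndarray:
    """Rotation-minimising frames by the double-reflection method."""
    n = len(points)
    tangents = np.gradient(points, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    frames = np.empty((n, 3, 3))
    t0 = tangents[0]
    # initial normal: x-axis projected off the tangent (stable for cords
    # running along z); fall back to y-axis if degenerate
    ref = np.array([1.0, 0.0, 0.0])
    nrm = ref - np.dot(ref, t0) * t0
    if np.linalg.norm(nrm) < 1e-8:
        ref = np.array([0.0, 1.0, 0.0])
        nrm = ref - np.dot(ref, t0) * t0
    nrm /= np.linalg.norm(nrm)
    frames[0] = np.stack([t0, nrm, np.cross(t0, nrm)])
    for i in range(n - 1):
        ti, ni = frames[i, 0], frames[i, 1]
        v1 = points[i + 1] - points[i]
        c1 = v1 @ v1
        if c1 < 1e-16:
            frames[i + 1] = frames[i]
            continue
        nl = ni - (2.0 / c1) * (v1 @ ni) * v1
        tl = ti - (2.0 / c1) * (v1 @ ti) * v1
        v2 = tangents[i + 1] - tl
        c2 = v2 @ v2
        n_next = nl if c2 < 1e-16 else nl - (2.0 / c2) * (v2 @ nl) * v2
        n_next -= np.dot(n_next, tangents[i + 1]) * tangents[i + 1]
        n_next /= np.linalg.norm(n_next)
        frames[i + 1] = np.stack([tangents[i + 1], n_next,
                                  np.cross(tangents[i + 1], n_next)])
    return frames


def extract_centerline(volume: VoxelLabelVolume,
                       labels: tuple[int, ...] = CORD_LABELS,
                       step: float = 0.5,
                       smoothing_window: float = 5.0) -> Centerline:
    """Centreline of the selected labels.

    Per-slice centroids are smoothed by a least-squares cubic spline with
    knots every ``smoothing_window`` mm and resampled at uniform ``step`` mm
    arc-length intervals with rotation-minimising frames.
    """
    mask = np.isin(volume.array, labels)
    nz = volume.shape[2]
    zw = volume.z_coords()
    counts = mask.sum(axis=(0, 1))
    present = counts > 0
    if (~present).sum() > 0.05 * nz:
        raise EmptySliceError(
            f"empty slice: {(~present).sum()} of {nz} slices contain no selected label")
    n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3)))[0].max()
    if n_comp != 1:
        raise DisconnectedError(f"disconnected: cord splits into {n_comp} components")

    xs = volume.origin[0] + np.arange(volume.shape[0]) * volume.spacing[0]
    ys = volume.origin[1] + np.arange(volume.shape[1]) * volume.spacing[1]
    cx = np.zeros(nz)
    cy = np.zeros(nz)
    sums_x = (mask.sum(axis=1) * xs[:, None]).sum(axis=0)
    sums_y = (mask.sum(axis=0) * ys[:, None]).sum(axis=0)
    cx[present] = sums_x[present] / counts[present]
    cy[present] = sums_y[present] / counts[present]

    zv = zw[present]
    cxp, cyp = cx[present], cy[present]
    span = zv[-1] - zv[0]
    n_knots = max(0, int(span / smoothing_window) - 1)
    if n_knots > 0 and len(zv) > 8:
        knots = np.linspace(zv[0], zv[-1], n_knots + 2)[1:-1]
        fx = LSQUnivariateSpline(zv, cxp, knots, k=3)
        fy = LSQUnivariateSpline(zv, cyp, knots, k=3)
        sx, sy = fx(zv), fy(zv)
    else:
        sx, sy = cxp, cyp

    pts = np.column_stack([sx, sy, zv])
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arc[-1]
    s_new = np.arange(0.0, total + step / 2, step)
    s_new[-1] = min(s_new[-1], total)
    fi = interp1d(arc, pts, axis=0, kind="cubic" if len(pts) > 3 else "linear")
    pts_new = fi(s_new)
    frames = _rmf_frames(pts_new)
    return Centerline(points=pts_new, arc_length=s_new, frames=frames)


def straighten_volume(volume: VoxelLabelVolume, centerline: Centerline,
                      step: float | None = None) -> VoxelLabelVolume:
    """Curved planar reformat along the centreline.

    Planes orthogonal to the tangent are resampled at uniform arc-length
    steps using the rotation-minimising frames (normal -> output x,
    binormal -> output y); nearest-label interpolation.  The output z-extent
    equals the centreline arc length to within one step.
    """
    if step is None:
        step = volume.spacing[2]
    rot = _frame_angles(centerline.frames)
    if np.any(rot > math.radians(45.0)):
        raise FrameFlipError("frame flip: consecutive frames rotate by > 45 degrees")

    total = centerline.total_length
    s_out = np.arange(0.0, total + 1e-9, step)
    fi_p = interp1d(centerline.arc_length, centerline.points, axis=0,
                    kind="cubic" if len(centerline.points) > 3 else "linear",
                    fill_value="extrapolate")
    pts = fi_p(s_out)
    frames = _rmf_frames(pts)

    nx, ny, _ = volume.shape
    sx, sy, sz = volume.spacing
    gx = (np.arange(nx) - (nx - 1) / 2) * sx
    gy = (np.arange(ny) - (ny - 1) / 2) * sy
    GX, GY = np.meshgrid(gx, gy, indexing="ij")

    out = np.zeros((nx, ny, len(s_out)), dtype=volume.array.dtype)
    origin = np.asarray(volume.origin)
    spacing = np.asarray(volume.spacing)
    for j in range(len(s_out)):
        center = pts[j]
        nrm, binrm = frames[j, 1], frames[j, 2]
        world = (center[None, None, :]
                 + GX[..., None] * nrm[None, None, :]
                 + GY[..., None] * binrm[None, None, :])
        idx = (world - origin) / spacing
        coords = np.moveaxis(idx, -1, 0)
        # nearest-edge extension keeps the end planes complete when a
        # slightly tilted plane grazes the first/last source slice
        out[:, :, j] = ndimage.map_coordinates(volume.array, coords, order=0,
                                               mode="nearest")
    res = VoxelLabelVolume(
        array=out, spacing=(sx, sy, step),
        origin=(-(nx - 1) / 2 * sx, -(ny - 1) / 2 * sy, 0.0),
        label_map=dict(volume.label_map),
        meta={**volume.meta, "straightened": True},
    )
    return res


def _frame_angles(frames: np.ndarray) -> np.ndarray:
    """Rotation angle between consecutive frames."""
    r = np.einsum("nij,nkj->nik", frames[1:], frames[:-1])
    tr = np.clip((np.trace(r, axis1=1, axis2=2) - 1) / 2, -1.0, 1.0)
    return np.arccos(tr)


# ---------------------------------------------------------------------------
# anisotropic scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaleFactors:
    """Elongation percentages per axis; +45 means a factor of 1.45."""

    ex: float
    ey: float
    ez: float

    def __post_init__(self):
        if min(self.ex, self.ey, self.ez) <= -100.0:
            raise ValueError("elongation must be > -100%")

    def multipliers(self) -> tuple[float, float, float]:
        return (1 + self.ex / 100, 1 + self.ey / 100, 1 + self.ez / 100)


def _rescale(volume: VoxelLabelVolume, scales: tuple[float, float, float]
             ) -> VoxelLabelVolume:
    """Nearest-label resampling by a diagonal scaling about the volume centre.

    The grid is resized so physical extents scale by exactly the given
    multipliers (within one voxel); spacing is unchanged.
    """
    arr = volume.array
    shape = arr.shape
    new_shape = tuple(max(1, int(round(n * s))) for n, s in zip(shape, scales))
    grids = []
    for ax, (n_new, n_old, s) in enumerate(zip(new_shape, shape, scales)):
        c_new = (n_new - 1) / 2
        c_old = (n_old - 1) / 2
        grids.append((np.arange(n_new) - c_new) / s + c_old)
    coords = np.meshgrid(*grids, indexing="ij")
    out = ndimage.map_coordinates(arr, np.array(coords), order=0,
                                  mode="constant", cval=0)
    res = volume.copy()
    res.array = out.astype(arr.dtype)
    # keep the volume centre fixed in world coordinates
    origin = [
        volume.origin[ax] + ((shape[ax] - 1) / 2 - (new_shape[ax] - 1) / 2)
        * volume.spacing[ax]
        for ax in range(3)
    ]
    res.origin = tuple(origin)
    return res


def apply_scale(volume: VoxelLabelVolume, factors: ScaleFactors) -> VoxelLabelVolume:
    """Resample by the elongation factors about the volume centre."""
    f = factors if isinstance(factors, ScaleFactors) else ScaleFactors(*factors)
    return _rescale(volume, f.multipliers())


def estimate_scale(moving: VoxelLabelVolume,
                   reference_extents: tuple[float, float, float]) -> ScaleFactors:
    """Elongation percentages (ref/moving − 1)·100 per axis.

    Moving extents are the cord-label bounding length along z and the median
    per-slice cross-section width/height along x/y (see
    :func:`cordmorph.volume.cord_extents`).
    """
    from .volume import cord_extents

    rx, ry, rz = reference_extents
    if min(rx, ry, rz) <= 0:
        raise ValueError("degenerate: reference extents must be positive")
    mx, my, mz = cord_extents(moving)
    if min(mx, my, mz) <= 0:
        raise ValueError("degenerate: moving extents are zero")
    return ScaleFactors(ex=(rx / mx - 1) * 100, ey=(ry / my - 1) * 100,
                        ez=(rz / mz - 1) * 100)


# ---------------------------------------------------------------------------
# thin-plate splines
# ---------------------------------------------------------------------------

def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r² log r, continuous at 0 (U(0) = 0); evaluated from r²."""
    out = np.zeros_like(r2)
    pos = r2 > 0
    out[pos] = 0.5 * r2[pos] * np.log(r2[pos])
    return out


@dataclass
class TPSWarp:
    """2D thin-plate-spline map fitted to paired in-plane landmarks."""

    source: np.ndarray       # (n, 2) mm
    target: np.ndarray       # (n, 2) mm
    weights: np.ndarray      # (n, 2) non-affine coefficients
    affine: np.ndarray       # (3, 2): rows const, x, y
    plane_z: float = 0.0
    regularization: float = 0.0

    def transform(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = ((pts[:, None, :] - self.source[None, :, :]) ** 2).sum(-1)
        u = _tps_kernel(d2)
        ones = np.ones((len(pts), 1))
        basis = np.hstack([ones, pts])
        return basis @ self.affine + u @ self.weights

    def displacement(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.transform(pts) - pts

    def inverse(self) -> "TPSWarp":
        """Approximate inverse: TPS fitted with the pairs swapped (exact for
        affine maps, including translations)."""
        inv = fit_tps(self.target, self.source, self.regularization)
        inv.plane_z = self.plane_z
        return inv


def fit_tps(source: np.ndarray, target: np.ndarray,
            regularization: float = 0.0) -> TPSWarp:
    """Fit the standard 2D thin-plate spline mapping source -> target.

    With zero regularisation the warp interpolates every landmark exactly;
    collinear landmarks raise ``SingularLandmarksError``.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("source/target must be matching (n, 2) arrays")
    n = len(src)
    if n < 3:
        raise ValueError("at least 3 landmark pairs required")
    if regularization < 0:
        raise ValueError("regularization must be non-negative")
    # collinearity check on the source configuration
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise SingularLandmarksError("singular: landmarks are collinear")

    d2 = ((src[:, None, :] - src[None, :, :]) ** 2).sum(-1)
    K = _tps_kernel(d2) + regularization * np.eye(n)
    P = np.hstack([np.ones((n, 1)), src])
    A = np.zeros((n + 3, n + 3))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = tgt
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise SingularLandmarksError(f"singular TPS system: {exc}") from exc
    return TPSWarp(source=src.copy(), target=tgt.copy(),
                   weights=sol[:n], affine=sol[n:],
                   regularization=regularization)


def apply_tps(volume: VoxelLabelVolume, warps: list[TPSWarp]) -> VoxelLabelVolume:
    """Apply per-plane TPS warps by backward-mapped in-plane resampling.

    Each warp belongs to the axial plane nearest its ``plane_z``; slices
    between warp planes use a linear blend of the neighbouring inverse
    displacement fields, slices outside take the nearest.  z-coordinates are
    never mixed across slices.
    """
    if not warps:
        raise ValueError("no warps supplied")
    nx, ny, nz = volume.shape
    sx, sy, _ = volume.spacing
    gx = volume.origin[0] + np.arange(nx) * sx
    gy = volume.origin[1] + np.arange(ny) * sy
    GX, GY = np.meshgrid(gx, gy, indexing="ij")
    pts = np.column_stack([GX.ravel(), GY.ravel()])

    order = np.argsort([w.plane_z for w in warps])
    planes = np.array([warps[i].plane_z for i in order])
    disp_fields = []
    for i in order:
        inv = warps[i].inverse()
        disp_fields.append(inv.displacement(pts))  # (n_pix, 2)
    disp_fields = np.array(disp_fields)

    out = np.zeros_like(volume.array)
    zw = volume.z_coords()
    for k in range(nz):
        z = zw[k]
        if len(planes) == 1 or z <= planes[0]:
            d = disp_fields[0]
        elif z >= planes[-1]:
            d = disp_fields[-1]
        else:
            j = int(np.searchsorted(planes, z) - 1)
            t = (z - planes[j]) / (planes[j + 1] - planes[j])
            d = (1 - t) * disp_fields[j] + t * disp_fields[j + 1]
        src = pts + d
        ix = (src[:, 0] - volume.origin[0]) / sx
        iy = (src[:, 1] - volume.origin[1]) / sy
        out[:, :, k] = ndimage.map_coordinates(
            volume.array[:, :, k], np.array([ix, iy]), order=0,
            mode="constant", cval=0).reshape(nx, ny)
    res = volume.copy()
    res.array = out
    return res
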