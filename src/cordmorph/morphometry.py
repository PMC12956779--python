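"""Segmental morphometry of a straightened labeled volume.

Every public operation takes the volume plus a segment z-range (half-open
``[z_start, z_end)`` in world mm); :func:`measure_all` drives the whole
quantity set from a segment-boundary table and emits one tidy record per
(segment, quantity, side-or-view).

Measurement conventions
-----------------------
* the canonical per-segment measurement plane is the axial slice nearest the
  segment's mid-z;
* shell thicknesses are means of four sub-voxel ray chords per side, cast
  from the cord centroid at the cardinal direction ±5° and ±15°;
* perimeters are sub-voxel iso-contours of the Gaussian-smoothed mask;
* the midline is the cord cross-section centroid's x;
* horns are split at the per-side gray-matter dorsoventral midpoint, and
  the medial horn boundaries (D8/D9) exclude rows where gray matter runs
  continuously across the midline (the commissure).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure as skmeasure

from .volume import LABELS, VoxelLabelVolume, cord_mask

METHOD_VERSION = "cordmorph-0.1.0"

SIDE_ANGLES_DEG = {"right": 0.0, "dorsal": 90.0, "left": 180.0, "ventral": 270.0}
RAY_OFFSETS_DEG = (-15.0, -5.0, 5.0, 15.0)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class ShellMissingError(ValueError):
    """A thickness ray missed the requested shell label."""


class NoEntryZoneError(ValueError):
    """No rootlet of the requested side touches the cord in the segment."""


class EmptySilhouetteError(ValueError):
    """The projected cord silhouette is empty."""


class MissingGrayError(ValueError):
    """The cross-section slice contains no gray matter."""


class NoneFoundError(ValueError):
    """No component of the requested label exists."""


# ---------------------------------------------------------------------------
# slice helpers
# ---------------------------------------------------------------------------

def _mid_slice(volume: VoxelLabelVolume, z_range: tuple[float, float]) -> int:
    z_mid = 0.5 * (z_range[0] + z_range[1])
    return int(np.argmin(np.abs(volume.z_coords() - z_mid)))


def _world_axes(volume: VoxelLabelVolume) -> tuple[np.ndarray, np.ndarray]:
    xs = volume.origin[0] + np.arange(volume.shape[0]) * volume.spacing[0]
    ys = volume.origin[1] + np.arange(volume.shape[1]) * volume.spacing[1]
    return xs, ys


def _smoothed_perimeter(mask: np.ndarray, spacing: tuple[float, float],
                        sigma_vox: float = 1.4) -> float:
    """Perimeter of the longest sub-voxel iso-contour of a binary mask."""
    f = ndimage.gaussian_filter(mask.astype(float), sigma_vox)
    contours = skmeasure.find_contours(f, 0.5)
    if not contours:
        raise ValueError("no contour found")
    best = 0.0
    for c in contours:
        pts = c * np.asarray(spacing)[None, :]
        d = np.linalg.norm(np.diff(pts, axis=0, append=pts[:1]), axis=1)
        best = max(best, float(d.sum()))
    return best


# ---------------------------------------------------------------------------
# shell thickness
# ---------------------------------------------------------------------------

def radial_thickness(volume: VoxelLabelVolume, z_range: tuple[float, float],
                     shell_label: str, side: str) -> float:
    """Mean shell thickness (μm) on one side at the segment mid-slice.

    Four rays from the cord centroid at the cardinal direction ±5° and
    ±15°; per ray the thickness is the chord length through the shell
    label, marched at quarter-voxel steps.
    """
    if side not in SIDE_ANGLES_DEG:
        raise ValueError(f"unknown side {side!r}")
    code = volume.label_map[shell_label] if isinstance(shell_label, str) else int(shell_label)
    k = _mid_slice(volume, z_range)
    sl = volume.array[:, :, k]
    cm = np.isin(sl, (LABELS["white_matter"], LABELS["gray_matter"]))
    if not cm.any():
        raise ValueError("degenerate: no cord in slice")
    xs, ys = _world_axes(volume)
    ix, iy = np.nonzero(cm)
    cx, cy = float(xs[ix].mean()), float(ys[iy].mean())

    sx, sy = volume.spacing[0], volume.spacing[1]
    step = 0.25 * min(sx, sy)
    r_max = math.hypot(volume.shape[0] * sx, volume.shape[1] * sy)
    spans = []
    for off in RAY_OFFSETS_DEG:
        ang = math.radians(SIDE_ANGLES_DEG[side] + off)
        dx, dy = math.cos(ang), math.sin(ang)
        ts = np.arange(0.0, r_max, step)
        px = cx + ts * dx
        py = cy + ts * dy
        jx = np.round((px - volume.origin[0]) / sx).astype(int)
        jy = np.round((py - volume.origin[1]) / sy).astype(int)
        ok = (jx >= 0) & (jx < sl.shape[0]) & (jy >= 0) & (jy < sl.shape[1])
        labels_on_ray = np.full(len(ts), -1)
        labels_on_ray[ok] = sl[jx[ok], jy[ok]]
        hits = np.nonzero(labels_on_ray == code)[0]
        if hits.size == 0:
            raise ShellMissingError(
                f"shell missing: {shell_label} not hit on the {side} ray at {off:+g}°")
        spans.append((hits[-1] - hits[0] + 1) * step)
    return float(np.mean(spans) * 1000.0)


def dural_circumference(volume: VoxelLabelVolume,
                        z_range: tuple[float, float]) -> float:
    """Outer dura perimeter (mm) at the segment mid-slice (sub-voxel contour)."""
    k = _mid_slice(volume, z_range)
    sl = volume.array[:, :, k]
    mask = np.isin(sl, (LABELS["white_matter"], LABELS["gray_matter"],
                        LABELS["csf"], LABELS["dura"]))
    if not mask.any():
        raise ShellMissingError("shell missing: no dura-bounded region in slice")
    mask = ndimage.binary_fill_holes(mask)
    return _smoothed_perimeter(mask, volume.spacing[:2])


def csf_segment_volume(volume: VoxelLabelVolume,
                       z_range: tuple[float, float]) -> float:
    """CSF-label voxel count × voxel volume within the segment's z-range."""
    zsl = volume.z_slice_range(*z_range)
    n = int((volume.array[:, :, zsl] == LABELS["csf"]).sum())
    return n * volume.voxel_volume()


# ---------------------------------------------------------------------------
# dorsal root ganglia
# ---------------------------------------------------------------------------

def measure_drg(volume: VoxelLabelVolume,
                segment_table: pd.DataFrame) -> pd.DataFrame:
    """Per-component DRG dimensions assigned to segments.

    26-connected components of the DRG label; V = voxel count × voxel
    volume; L/W/T = max-minus-min projections on the component's principal
    axes (descending), plus one voxel.  Side is the component centroid's x
    relative to the volume's cord centroid.
    """
    mask = volume.array == LABELS["drg"]
    if not mask.any():
        raise NoneFoundError("none found: no DRG label in volume")
    lab, n_comp = ndimage.label(mask, structure=_STRUCT26)
    cm = cord_mask(volume)
    idx = np.nonzero(cm)
    x_mid = volume.origin[0] + float(idx[0].mean()) * volume.spacing[0]

    spacing = np.asarray(volume.spacing)
    rows = []
    for ci in range(1, n_comp + 1):
        coords = np.column_stack(np.nonzero(lab == ci)).astype(float)
        world = np.asarray(volume.origin) + coords * spacing
        centroid = world.mean(axis=0)
        centered = world - centroid
        if len(coords) < 4:
            axes = np.eye(3)
        else:
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            axes = vt
        extents = []
        for v in axes:
            proj = centered @ v
            extents.append(float(proj.max() - proj.min() + np.max(np.abs(v) * spacing)))
        extents.sort(reverse=True)
        seg = _segment_of(segment_table, centroid[2])
        rows.append({
            "segment": seg,
            "side": "right" if centroid[0] >= x_mid else "left",
            "L_DRG": extents[0],
            "W_DRG": extents[1],
            "T_DRG": extents[2],
            "V_DRG": len(coords) * volume.voxel_volume(),
        })
    return pd.DataFrame(rows)


def _segment_of(segment_table: pd.DataFrame, z: float) -> str:
    for _, r in segment_table.iterrows():
        if r["z_start_mm"] <= z < r["z_end_mm"]:
            return str(r["segment"])
    return "outside"


# ---------------------------------------------------------------------------
# rootlets
# ---------------------------------------------------------------------------

def _rootlet_code(side: str) -> int:
    if side == "dorsal":
        return LABELS["dorsal_rootlet"]
    if side == "ventral":
        return LABELS["ventral_rootlet"]
    raise ValueError(f"rootlet side must be dorsal or ventral, got {side!r}")


def _entry_voxels(volume: VoxelLabelVolume, z_range: tuple[float, float],
                  code: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index coordinates of rootlet voxels 26-adjacent to white matter,
    restricted to the segment's z-range (computed with a one-slice margin)."""
    zsl = volume.z_slice_range(*z_range)
    lo = max(zsl.start - 1, 0)
    hi = min(zsl.stop + 1, volume.shape[2])
    sub = volume.array[:, :, lo:hi]
    near_white = ndimage.binary_dilation(sub == LABELS["white_matter"],
                                         structure=_STRUCT26)
    entry = (sub == code) & near_white
    ix, iy, iz = np.nonzero(entry)
    keep = (iz + lo >= zsl.start) & (iz + lo < zsl.stop)
    return ix[keep], iy[keep], iz[keep] + lo


def rootlet_zone_metrics(volume: VoxelLabelVolume, z_range: tuple[float, float],
                         side: str,
                         next_z_range: tuple[float, float] | None = None
                         ) -> tuple[float, float, float]:
    """(W, L_REZ, L_RBZ) of one segment's rootlet entry zone.

    Entry voxels are rootlet voxels 26-adjacent to white matter.  W is the
    mediolateral distance between the medial edges of the left and right
    entry bands; L_REZ their rostrocaudal extent; L_RBZ the gap to the next
    segment's entry zone (0 when overlapping, NaN without a next segment).
    """
    code = _rootlet_code(side)
    ix, iy, iz = _entry_voxels(volume, z_range, code)
    if ix.size == 0:
        raise NoEntryZoneError(f"no entry zone: {side} rootlets absent in segment")
    sx, _, sz = volume.spacing
    zw = volume.origin[2] + iz * sz
    l_rez = float(zw.max() - zw.min() + sz)

    cm = cord_mask(volume)[:, :, volume.z_slice_range(*z_range)]
    x_mid = volume.origin[0] + float(np.nonzero(cm)[0].mean()) * sx
    xw = volume.origin[0] + ix * sx
    right = xw[xw > x_mid]
    left = xw[xw < x_mid]
    w = float(right.min() - left.max()) if right.size and left.size else float("nan")

    l_rbz = float("nan")
    if next_z_range is not None:
        jx, jy, jz = _entry_voxels(volume, next_z_range, code)
        if jx.size:
            gap = (volume.origin[2] + jz.min() * sz) - zw.max() - sz
            l_rbz = max(0.0, float(gap))
    return w, l_rez, l_rbz


def count_rootlets(volume: VoxelLabelVolume, z_range: tuple[float, float],
                   side: str) -> int:
    """Number of 26-connected rootlet components of one side touching a
    2-voxel shell around the cord surface within the segment's z-range."""
    code = _rootlet_code(side)
    zsl = volume.z_slice_range(*z_range)
    sub = volume.array[:, :, zsl]
    mask = sub == code
    if not mask.any():
        return 0
    lab, n_comp = ndimage.label(mask, structure=_STRUCT26)
    shell = ndimage.binary_dilation(
        np.isin(sub, (LABELS["white_matter"], LABELS["gray_matter"])),
        structure=_STRUCT26, iterations=2)
    touching = np.unique(lab[shell & (lab > 0)])
    return int(touching.size)


def rootlet_coverage(volume: VoxelLabelVolume, z_range: tuple[float, float],
                     view: str) -> float:
    """Projected rootlet coverage (%) of the cord silhouette for one view.

    Dorsal/ventral views project that side's rootlet label along y; lateral
    views project both rootlet labels of the viewed half along x (the far
    half is occluded by the cord).  The denominator is the cord silhouette
    within the segment's z-range; rootlet shadow pixels count whether they
    overlap or flank the silhouette band.
    """
    zsl = volume.z_slice_range(*z_range)
    sub = volume.array[:, :, zsl]
    cm = np.isin(sub, (LABELS["white_matter"], LABELS["gray_matter"]))
    if view in ("dorsal", "ventral"):
        rl = sub == _rootlet_code(view)
        sil = cm.any(axis=1)
        shadow = rl.any(axis=1)
    elif view in ("left", "right"):
        if not cm.any():
            raise EmptySilhouetteError("empty silhouette")
        x_mid_idx = float(np.nonzero(cm)[0].mean())
        rl = np.isin(sub, (LABELS["dorsal_rootlet"], LABELS["ventral_rootlet"]))
        half = np.zeros_like(rl)
        cols = np.arange(sub.shape[0])
        sel = cols > x_mid_idx if view == "right" else cols < x_mid_idx
        half[sel] = rl[sel]
        sil = cm.any(axis=0)
        shadow = half.any(axis=0)
    else:
        raise ValueError(f"unknown view {view!r}")
    n_sil = int(sil.sum())
    if n_sil == 0:
        raise EmptySilhouetteError("empty silhouette")
    return 100.0 * float(shadow.sum()) / n_sil


# ---------------------------------------------------------------------------
# cross-section metrics
# ---------------------------------------------------------------------------

def cross_section_metrics(volume: VoxelLabelVolume, z: float) -> dict:
    """D1–D9, A1, A2 and C1 at the axial slice nearest world z.

    D1/D2 are the cord's dorsoventral/mediolateral extents; depths D4, D6,
    D7 are measured from the dorsal cord surface to the ventral horn's
    ventral boundary, the dorsal horn's dorsal boundary and the ventral
    horn's dorsal boundary; widths D3/D9 (ventral horn) and D5/D8 (dorsal
    horn) are measured from the midline (cord centroid x).  Horns are split
    at the per-side gray dorsoventral midpoint; D8/D9 exclude commissural
    rows (gray running continuously across the midline).  A1 = gray area,
    A2 = white area (voxel counting); C1 = sub-voxel cord perimeter.
    """
    k = int(np.argmin(np.abs(volume.z_coords() - z)))
    sl = volume.array[:, :, k]
    white = sl == LABELS["white_matter"]
    gray = sl == LABELS["gray_matter"]
    cord = white | gray
    if not cord.any():
        raise MissingGrayError("missing gray matter: empty slice")
    if not gray.any():
        raise MissingGrayError("missing gray matter")
    sx, sy = volume.spacing[0], volume.spacing[1]
    xs, ys = _world_axes(volume)
    ix, iy = np.nonzero(cord)
    x_mid = float(xs[ix].mean())
    y_surf = float(ys[iy.max()]) + sy / 2

    out: dict = {
        "D1": float((iy.max() - iy.min() + 1) * sy),
        "D2": float((ix.max() - ix.min() + 1) * sx),
        "A1": float(gray.sum()) * sx * sy,
        "A2": float(white.sum()) * sx * sy,
        "C1": _smoothed_perimeter(cord, (sx, sy)),
    }

    X, Y = np.meshgrid(xs, ys, indexing="ij")
    # commissural rows: gray present within 1.5 voxels of the midline on
    # both sides (the bridge crossing x_mid)
    near_l = gray & (X < x_mid) & (X > x_mid - 1.5 * sx)
    near_r = gray & (X >= x_mid) & (X < x_mid + 1.5 * sx)
    comm_rows = near_l.any(axis=0) & near_r.any(axis=0)

    for quantity in ("D3", "D4", "D5", "D6", "D7", "D8", "D9"):
        out[quantity] = {}
    for side_name, side_mask in (("right", gray & (X > x_mid)),
                                 ("left", gray & (X < x_mid))):
        if not side_mask.any():
            raise MissingGrayError(f"missing gray matter on the {side_name} side")
        gy = Y[side_mask]
        y_top, y_bot = float(gy.max()), float(gy.min())
        y_mid_gray = 0.5 * (y_top + y_bot)
        out["D6"][side_name] = y_surf - (y_top + sy / 2)
        out["D4"][side_name] = y_surf - (y_bot - sy / 2)
        out["D7"][side_name] = y_surf - y_mid_gray
        dorsal_part = side_mask & (Y >= y_mid_gray)
        ventral_part = side_mask & (Y < y_mid_gray)
        no_comm = ~comm_rows[None, :]
        for part, lat_q, med_q in ((dorsal_part, "D5", "D8"),
                                   (ventral_part, "D3", "D9")):
            if not part.any():
                raise MissingGrayError(
                    f"missing gray matter: no {lat_q} horn on the {side_name} side")
            dist = np.abs(X[part] - x_mid)
            out[lat_q][side_name] = float(dist.max() + sx / 2)
            part_nc = part & no_comm
            if part_nc.any():
                dist_nc = np.abs(X[part_nc] - x_mid)
                out[med_q][side_name] = float(max(0.0, dist_nc.min() - sx / 2))
            else:
                out[med_q][side_name] = float("nan")
    return out


# ---------------------------------------------------------------------------
# the full table
# ---------------------------------------------------------------------------

def measure_all(volume: VoxelLabelVolume,
                segment_table: pd.DataFrame) -> pd.DataFrame:
    """Every metric for every segment/side/view as one tidy table.

    Failing metrics become missing-value records with the failure reason in
    the ``reason`` column rather than aborting the run.
    """
    rows: list[dict] = []

    def add(seg, quantity, side, value, units, reason=""):
        rows.append({"segment": seg, "quantity": quantity, "side_or_view": side,
                     "value": float(value), "units": units,
                     "method_version": METHOD_VERSION, "reason": reason})

    def guarded(seg, quantity, side, units, fn):
        try:
            add(seg, quantity, side, fn(), units)
        except (ValueError, KeyError) as exc:
            add(seg, quantity, side, float("nan"), units, reason=str(exc))

    segs = segment_table.reset_index(drop=True)
    try:
        drg = measure_drg(volume, segs)
    except NoneFoundError:
        drg = pd.DataFrame(columns=["segment", "side", "L_DRG", "W_DRG",
                                    "T_DRG", "V_DRG"])

    for i, r in segs.iterrows():
        seg = str(r["segment"])
        zr = (float(r["z_start_mm"]), float(r["z_end_mm"]))
        nxt = None
        if i + 1 < len(segs):
            rn = segs.iloc[i + 1]
            nxt = (float(rn["z_start_mm"]), float(rn["z_end_mm"]))
        z_mid = 0.5 * (zr[0] + zr[1])

        for side in SIDE_ANGLES_DEG:
            guarded(seg, "dura_thickness", side, "um",
                    lambda s=side: radial_thickness(volume, zr, "dura", s))
            guarded(seg, "csf_thickness", side, "um",
                    lambda s=side: radial_thickness(volume, zr, "csf", s))
        guarded(seg, "dura_circumference", "none", "mm",
                lambda: dural_circumference(volume, zr))
        guarded(seg, "csf_volume", "none", "mm3",
                lambda: csf_segment_volume(volume, zr))

        try:
            cs = cross_section_metrics(volume, z_mid)
            add(seg, "D1", "none", cs["D1"], "mm")
            add(seg, "D2", "none", cs["D2"], "mm")
            for q in ("D3", "D4", "D5", "D6", "D7", "D8", "D9"):
                for side in ("left", "right"):
                    add(seg, q, side, cs[q][side], "mm")
            add(seg, "A1", "none", cs["A1"], "mm2")
            add(seg, "A2", "none", cs["A2"], "mm2")
            add(seg, "C1", "none", cs["C1"], "mm")
        except (ValueError, KeyError) as exc:
            for q, side_list, units in (
                ("D1", ["none"], "mm"), ("D2", ["none"], "mm"),
                ("D3", ["left", "right"], "mm"), ("D4", ["left", "right"], "mm"),
                ("D5", ["left", "right"], "mm"), ("D6", ["left", "right"], "mm"),
                ("D7", ["left", "right"], "mm"), ("D8", ["left", "right"], "mm"),
                ("D9", ["left", "right"], "mm"),
                ("A1", ["none"], "mm2"), ("A2", ["none"], "mm2"),
                ("C1", ["none"], "mm"),
            ):
                for side in side_list:
                    add(seg, q, side, float("nan"), units, reason=str(exc))

        for side, w_q, rez_q, rbz_q in (("dorsal", "W_D", "L_DREZ", "L_DRBZ"),
                                        ("ventral", "W_V", "L_VREZ", "L_VRBZ")):
            add(seg, "n_rootlets", side,
                count_rootlets(volume, zr, side), "count")
            try:
                w, l_rez, l_rbz = rootlet_zone_metrics(volume, zr, side, nxt)
                add(seg, w_q, side, w, "mm")
                add(seg, rez_q, side, l_rez, "mm")
                if not math.isnan(l_rbz):
                    add(seg, rbz_q, side, l_rbz, "mm")
            except NoEntryZoneError as exc:
                for q in (w_q, rez_q):
                    add(seg, q, side, float("nan"), "mm", reason=str(exc))
        for view in SIDE_ANGLES_DEG:
            guarded(seg, "rootlet_proportion", view, "%",
                    lambda v=view: rootlet_coverage(volume, zr, v))

        for side in ("left", "right"):
            sel = drg[(drg["segment"] == seg) & (drg["side"] == side)]
            if len(sel):
                rec = sel.iloc[0]
                for q, units in (("L_DRG", "mm"), ("W_DRG", "mm"),
                                 ("T_DRG", "mm"), ("V_DRG", "mm3")):
                    add(seg, q, side, rec[q], units)

    return pd.DataFrame(rows)


def compare_to_truth(measured: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Join measured records to ground truth with absolute/relative errors."""
    m = measured.rename(columns={"value": "measured"})
    t = truth.rename(columns={"value": "truth"})[
        ["segment", "quantity", "side_or_view", "truth"]]
    merged = m.merge(t, on=["segment", "quantity", "side_or_view"], how="inner")
    merged["abs_error"] = (merged["measured"] - merged["truth"]).abs()
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["rel_error"] = merged["abs_error"] / merged["truth"].abs()
    return merged
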