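"""Synthetic labeled spinal-cord phantoms with recorded ground truth.

The generator emulates ex-vivo micro-CT segmentations of a feline spinal
cord from C3 to S2: an elliptical white-matter envelope with cervical and
lumbar enlargements, an H-shaped gray matter built from mirrored horn
polygons joined by a thin commissure bridge, a CSF annulus and a thin dura
shell with side-dependent thickness, straight cylindrical rootlet tubes
attached along dorsal/ventral entry zones, and ellipsoidal dorsal root
ganglia lateral to the dura.

Every generating parameter is recorded; after voxelisation a ground-truth
table holds the realized value of each quantity that the morphometry stage
later measures, so phantoms serve as a recovery oracle.

Deformation helpers (`bend_volume`, `shrink_volume`) produce bent and
shrunken variants used to exercise the straightening and scale-estimation
stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .volume import LABELS, VoxelLabelVolume

SIDES = ("dorsal", "ventral", "left", "right")

SEGMENT_NAMES = (
    ["C3", "C4", "C5", "C6", "C7", "C8"]
    + [f"T{i}" for i in range(1, 14)]
    + [f"L{i}" for i in range(1, 8)]
    + ["S1", "S2"]
)

#: Rootlet counts per segment for one animal (cervical/upper-thoracic block).
REFERENCE_DORSAL_COUNTS = {
    "C3": 28, "C4": 21, "C5": 24, "C6": 31, "C7": 37, "C8": 31,
    "T1": 19, "T2": 10, "T3": 11, "T4": 9, "T5": 8, "T6": 8,
    "T7": 11, "T8": 12,
}
REFERENCE_VENTRAL_COUNTS = {
    "C3": 19, "C4": 21, "C5": 25, "C6": 52, "C7": 55, "C8": 59,
    "T1": 32, "T2": 17, "T3": 11, "T4": 18, "T5": 20, "T6": 14,
    "T7": 20, "T8": 16,
}

#: Minimum clearance between rootlet tube surfaces (3 voxels at the default
#: 0.1 mm grid) and the derived z-lattice pitch.
ROOTLET_CLEARANCE_MM = 0.32
#: Half-width of the tube-free zone around each segment's mid-z measurement
#: plane (shell metrics are taken there and must not be punctured).
MID_EXCLUSION_MM = 0.45

BRIDGE_HALF_HEIGHT_MM = 0.2  # commissure bridge: fixed 0.4 mm total height
HORN_PLATEAU_FRACTION = 0.35
HORN_TIP_FRACTION = 0.3


class ResolutionError(ValueError):
    """A structure would be thinner than one voxel at the requested spacing."""


class OverlapError(ValueError):
    """Rootlet tubes cannot be placed at the requested count and clearance."""


class OutOfBoundsError(ValueError):
    """A deformation would push the cord outside the voxel grid."""


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass
class SegmentSpec:
    """Generating parameters of one spinal segment.

    Distances in mm, shell thicknesses in μm; ``z_range`` is the half-open
    rostrocaudal interval the segment occupies.
    """

    segment_id: str
    z_range: tuple[float, float]
    D1: float
    D2: float
    D3: float
    D4: float
    D5: float
    D6: float
    D7: float
    D8: float
    D9: float
    csf_gap: dict[str, float]          # per side, μm
    dura_thickness: dict[str, float]   # per side, μm
    n_dorsal_rootlets: int
    n_ventral_rootlets: int
    rootlet_radius: float
    L_DREZ: float
    L_VREZ: float
    L_DRBZ: float
    L_VRBZ: float
    W_D: float
    W_V: float
    drg_axes: tuple[float, float, float]  # (L, W, T) mm
    A1_target: float = float("nan")
    A2_target: float = float("nan")

    @property
    def mid_z(self) -> float:
        return 0.5 * (self.z_range[0] + self.z_range[1])

    @property
    def length(self) -> float:
        return self.z_range[1] - self.z_range[0]


@dataclass
class PhantomConfig:
    segments: list[SegmentSpec]
    spacing: float = 0.1
    seed: int = 0
    label_map: dict[str, int] = field(default_factory=lambda: dict(LABELS))

    def segment(self, name: str) -> SegmentSpec:
        for s in self.segments:
            if s.segment_id == name:
                return s
        raise KeyError(name)

    def segment_table(self) -> pd.DataFrame:
        """Segment boundary table (segment, z_start_mm, z_end_mm)."""
        return pd.DataFrame(
            {
                "segment": [s.segment_id for s in self.segments],
                "z_start_mm": [s.z_range[0] for s in self.segments],
                "z_end_mm": [s.z_range[1] for s in self.segments],
            }
        )


# ---------------------------------------------------------------------------
# default configuration
# ---------------------------------------------------------------------------

_D1 =[4.0, 4.1, 4.25, 4.4, 4.6, 4.5,
       3.8, 3.2, 2.9, 2.8, 2.8, 2.8, 2.8, 2.8, 2.8, 2.8, 2.8, 2.8, 2.9,
       3.0, 3.1, 3.3, 3.6, 3.9, 4.05, 3.8,
       2.6, 1.9]
_D2 = [5.2, 5.5, 5.9, 6.4, 6.3, 6.0,
       5.0, 4.2, 3.8, 3.6, 3.6, 3.6, 3.6, 3.6, 3.6, 3.6, 3.6, 3.7, 3.8,
       4.0, 4.2, 4.5, 4.9, 5.3, 5.5, 5.2,
       3.2, 2.3]
_LEN = [9.0] * 6 + [10.5] * 13 + [8.0] * 7 + [6.0, 6.0]
_DURA_MEAN = [112, 115, 118, 122, 123, 120,
              116, 112, 110, 108, 107, 106, 105, 104, 104, 103, 103, 102, 102,
              101, 100, 100, 100, 102, 105, 108,
              108, 106]
_CSF_MEAN = [150, 150, 148, 145, 145, 142,
             138, 130, 125, 120, 120, 120, 120, 120, 122, 124, 126, 128, 130,
             132, 134, 135, 135, 132, 130, 125,
             115, 110]
_WD = [2.2, 2.4, 2.7, 3.0, 3.0, 2.8,
       2.4, 1.9, 1.6, 1.5, 1.5, 1.5, 1.5, 1.5, 1.5, 1.6, 1.7, 1.8, 1.9,
       2.0, 2.1, 2.2, 2.3, 2.4, 2.5, 2.2,
       1.2, 0.6]
_WV = [2.5, 2.5, 2.5, 2.5, 2.5, 2.5,
       2.5, 2.4, 2.4, 2.4, 2.4, 2.4, 2.4, 2.4, 2.4, 2.4, 2.4, 2.4, 2.4,
       2.4, 2.4, 2.4, 2.4, 2.2, 2.0, 1.6,
       0.8, 0.6]
_LDREZ = [6.5, 6.0, 5.5, 5.0, 4.5, 4.0,
          3.5, 3.2, 3.5, 3.8, 4.2, 4.5, 5.0, 5.5, 5.8, 6.0, 6.2, 6.5, 6.5,
          6.5, 6.5, 6.0, 5.5, 5.0, 4.5, 4.0,
          3.5, 3.0]
_NDORS = [REFERENCE_DORSAL_COUNTS.get(n, 0) for n in SEGMENT_NAMES]
_NVENT = [REFERENCE_VENTRAL_COUNTS.get(n, 0) for n in SEGMENT_NAMES]
# defaults for segments not covered by the printed per-animal counts
_NDORS_DEF = {"T9": 11, "T10": 10, "T11": 10, "T12": 10, "T13": 11,
              "L1": 12, "L2": 13, "L3": 14, "L4": 16, "L5": 18, "L6": 20,
              "L7": 18, "S1": 8, "S2": 4}
_NVENT_DEF = {"T9": 14, "T10": 13, "T11": 13, "T12": 13, "T13": 14,
              "L1": 15, "L2": 16, "L3": 18, "L4": 20, "L5": 22, "L6": 24,
              "L7": 20, "S1": 8, "S2": 4}
_DRG_L = [2.2, 2.3, 2.45, 2.6, 2.7, 2.76,
          2.3, 1.9, 1.8, 1.8, 1.8, 1.8, 1.8, 1.8, 1.8, 1.8, 1.9, 2.0, 2.2,
          2.5, 2.8, 3.0, 3.2, 3.4, 3.5, 3.53,
          2.8, 2.2]
_DRG_W = [1.4, 1.5, 1.6, 1.7, 1.77, 1.7,
          1.4, 1.1, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.05, 1.1, 1.2,
          1.3, 1.4, 1.45, 1.5, 1.55, 1.56, 1.5,
          1.2, 1.0]
_DRG_T = [1.1, 1.15, 1.25, 1.3, 1.37, 1.3,
          1.1, 0.95, 0.9, 0.9, 0.9, 0.9, 0.9, 0.9, 0.9, 0.9, 0.9, 0.95, 1.0,
          1.05, 1.15, 1.2, 1.25, 1.3, 1.33, 1.3,
          1.05, 0.9]

# per-side offsets (μm) giving the ordering ventral > dorsal > right > left
_DURA_SIDE = {"ventral": 12.0, "dorsal": 4.0, "right": 2.0, "left": 0.0}
_CSF_SIDE = {"ventral": 10.0, "dorsal": 5.0, "right": 0.0, "left": 0.0}


def build_default_config(seed: int = 1, spacing: float = 0.1) -> PhantomConfig:
    """28-segment default phantom configuration (C3–S2).

    Parameter profiles follow the measured feline envelopes: cervical and
    lumbar enlargements in cord size and gray matter, thoracic minima,
    dura means of 100–123 μm with ventral > dorsal > lateral ordering, CSF
    gaps of 110–160 μm and per-animal rootlet counts for C3–T8.  The seed
    only jitters shell thicknesses by ±2 μm; all other parameters are
    deterministic.
    """
    rng = np.random.default_rng(seed)
    segments: list[SegmentSpec] = []
    z0 = 0.0
    for i, name in enumerate(SEGMENT_NAMES):
        z1 = z0 + _LEN[i]
        a = _D2[i] / 2.0
        d1 = _D1[i]
        dura = {
            s: float(np.clip(_DURA_MEAN[i] + _DURA_SIDE[s] + rng.uniform(-2, 2),
                             100.0, 200.0))
            for s in SIDES
        }
        csf = {
            s: float(np.clip(_CSF_MEAN[i] + _CSF_SIDE[s] + rng.uniform(-3, 3),
                             105.0, 300.0))
            for s in SIDES
        }
        l_drez = _LDREZ[i]
        l_vrez = min(l_drez + 2.0, _LEN[i] - 1.5)
        n_d = _NDORS[i] or _NDORS_DEF[name]
        n_v = _NVENT[i] or _NVENT_DEF[name]
        spec = SegmentSpec(
            segment_id=name,
            z_range=(z0, z1),
            D1=d1,
            D2=_D2[i],
            D3=0.55 * a,
            D4=0.82 * d1,
            D5=0.42 * a,
            D6=0.18 * d1,
            D7=0.50 * d1,   # horn junction fixed at the gray midheight
            D8=0.15 * a,
            D9=0.10 * a,
            csf_gap=csf,
            dura_thickness=dura,
            n_dorsal_rootlets=int(n_d),
            n_ventral_rootlets=int(n_v),
            rootlet_radius=0.1,
            L_DREZ=l_drez,
            L_VREZ=l_vrez,
            L_DRBZ=0.0,
            L_VRBZ=0.0,
            W_D=_WD[i],
            W_V=_WV[i],
            drg_axes=(_DRG_L[i], _DRG_W[i], _DRG_T[i]),
        )
        segments.append(spec)
        z0 = z1
    # informational between-zone gaps (realized values land in ground truth)
    for j in range(len(segments) - 1):
        s, nxt = segments[j], segments[j + 1]
        s.L_DRBZ = max(0.0, (nxt.mid_z - nxt.L_DREZ / 2) - (s.mid_z + s.L_DREZ / 2))
        s.L_VRBZ = max(0.0, (nxt.mid_z - nxt.L_VREZ / 2) - (s.mid_z + s.L_VREZ / 2))
    cfg = PhantomConfig(segments=segments, spacing=spacing, seed=seed)
    for s in cfg.segments:
        s.A1_target = _gray_area(s)
        s.A2_target = math.pi * (s.D2 / 2) * (s.D1 / 2) - s.A1_target
    validate_config(cfg)
    return cfg


def subset_config(config: PhantomConfig, names: list[str],
                  length: float | None = None) -> PhantomConfig:
    """Configuration restricted to the named segments, re-packed contiguously.

    ``length`` optionally overrides every retained segment's length (entry
    zones are clipped to fit).  Useful for building small, fast phantoms
    that keep the anatomical parameters of the chosen levels.
    """
    chosen = [config.segment(n) for n in names]
    out: list[SegmentSpec] = []
    z0 = 0.0
    for spec in chosen:
        seg_len = length if length is not None else spec.length
        s = replace(spec, z_range=(z0, z0 + seg_len),
                    csf_gap=dict(spec.csf_gap),
                    dura_thickness=dict(spec.dura_thickness))
        s.L_DREZ = min(s.L_DREZ, seg_len - 1.5)
        s.L_VREZ = min(s.L_VREZ, seg_len - 1.5)
        out.append(s)
        z0 += seg_len
    cfg = PhantomConfig(segments=out, spacing=config.spacing, seed=config.seed)
    validate_config(cfg)
    return cfg


def validate_config(config: PhantomConfig) -> None:
    if config.spacing <= 0:
        raise ValueError("spacing must be positive")
    prev_end = None
    for s in config.segments:
        if prev_end is not None and abs(s.z_range[0] - prev_end) > 1e-9:
            raise ValueError(f"segment z-ranges not contiguous at {s.segment_id}")
        prev_end = s.z_range[1]
        a, b = s.D2 / 2, s.D1 / 2
        for nm, v in (("D1", s.D1), ("D2", s.D2), ("D3", s.D3), ("D4", s.D4),
                      ("D5", s.D5), ("D6", s.D6), ("D7", s.D7), ("D8", s.D8),
                      ("D9", s.D9)):
            if v <= 0:
                raise ValueError(f"{s.segment_id}: {nm} must be > 0")
        if not (s.D8 < s.D5 and s.D9 < s.D3):
            raise ValueError(f"{s.segment_id}: medial boundaries must be medial")
        if not (s.D6 < s.D7 < s.D4 <= s.D1):
            raise ValueError(f"{s.segment_id}: horn depths must be ordered D6<D7<D4")
        # horn plateaus must clear the white-matter ellipse by >= 0.2 mm
        for depth_lo, depth_hi, x_lat in (
            (s.D6 + (1 - HORN_PLATEAU_FRACTION) * (s.D7 - s.D6), s.D7, s.D5),
            (s.D7, s.D7 + HORN_PLATEAU_FRACTION * (s.D4 - s.D7), s.D3),
        ):
            for depth in (depth_lo, depth_hi):
                y = b - depth
                half = a * math.sqrt(max(0.0, 1 - (y / b) ** 2))
                if half < x_lat + 0.15:
                    raise ValueError(
                        f"{s.segment_id}: gray horn would touch the white boundary")
        if s.L_DREZ > s.length or s.L_VREZ > s.length:
            raise ValueError(f"{s.segment_id}: entry zone longer than segment")
        for side in SIDES:
            if not (30.0 <= s.dura_thickness[side] <= 200.0):
                raise ValueError(f"{s.segment_id}: dura thickness out of range")


# ---------------------------------------------------------------------------
# analytic cross-section geometry (shared by the renderer and ground truth)
# ---------------------------------------------------------------------------

def _ellipse_radius(theta: np.ndarray, a: float, b: float) -> np.ndarray:
    """Polar radius of the ellipse x=a cosθ-parameterised boundary."""
    return (a * b) / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)


def _side_thickness(theta: np.ndarray, per_side: dict[str, float]) -> np.ndarray:
    """Smooth angular blend of the four per-side thicknesses (cos² weights)."""
    c, s = np.cos(theta), np.sin(theta)
    return (per_side["right"] * np.maximum(c, 0) ** 2
            + per_side["left"] * np.maximum(-c, 0) ** 2
            + per_side["dorsal"] * np.maximum(s, 0) ** 2
            + per_side["ventral"] * np.maximum(-s, 0) ** 2)


def _horn_interval(y: np.ndarray, y_base: float, y_tip: float,
                   x_med: float, x_lat: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Half-cord horn cross-section: [x_med, x_lat] plateau tapering to a tip.

    ``y_base`` is the junction end (full width), ``y_tip`` the tip end
    (width shrunk to HORN_TIP_FRACTION about the centreline).  Returns the
    medial/lateral bounds and a validity mask.
    """
    h = y_tip - y_base
    u = (y - y_base) / h
    valid = (u >= 0) & (u <= 1)
    f = np.where(u <= HORN_PLATEAU_FRACTION, 1.0,
                 1.0 - (1.0 - HORN_TIP_FRACTION)
                 * (u - HORN_PLATEAU_FRACTION) / (1.0 - HORN_PLATEAU_FRACTION))
    c = 0.5 * (x_med + x_lat)
    w = (x_lat - x_med) * np.clip(f, HORN_TIP_FRACTION, 1.0)
    return c - 0.5 * w, c + 0.5 * w, valid


def _bridge_reach(spec_like) -> float:
    return max(spec_like["D8"], spec_like["D9"]) + 0.15


def _section_params(spec: SegmentSpec) -> dict[str, float]:
    return {k: getattr(spec, k) for k in
            ("D1", "D2", "D3", "D4", "D5", "D6", "D7", "D8", "D9")}


def _gray_union_width(y: np.ndarray, p: dict[str, float]) -> np.ndarray:
    """Total gray width (both sides) at dorsoventral position(s) y."""
    b = p["D1"] / 2
    y_junction = b - p["D7"]
    y_top = b - p["D6"]
    y_bot = b - p["D4"]
    m_d, l_d, v_d = _horn_interval(y, y_junction, y_top, p["D8"], p["D5"])
    # ventral horn mirrored about the junction plane
    m_v, l_v, v_v = _horn_interval(2 * y_junction - y, y_junction,
                                   y_junction + (y_junction - y_bot),
                                   p["D9"], p["D3"])
    in_bridge = np.abs(y - y_junction) <= BRIDGE_HALF_HEIGHT_MM
    reach = _bridge_reach(p)
    # per-side union of the active horn interval and the bridge [0, reach]
    # (the bridge always merges with a horn: reach > D8, D9); doubled for
    # the two mirror-symmetric sides
    width_side = np.select(
        [v_d & in_bridge, v_v & in_bridge, v_d, v_v, in_bridge],
        [np.maximum(l_d, reach), np.maximum(l_v, reach),
         l_d - m_d, l_v - m_v,
         np.full_like(np.asarray(y, dtype=float), reach)],
        0.0)
    return 2.0 * width_side


def _gray_area(spec: SegmentSpec) -> float:
    """Analytic (fine-quadrature) gray-matter cross-section area, mm²."""
    p = _section_params(spec)
    b = p["D1"] / 2
    y = np.arange(b - p["D4"], b - p["D6"] + 1e-9, 5e-4)
    return float(np.trapezoid(_gray_union_width(y, p), y))


def _classify_section(X: np.ndarray, Y: np.ndarray, p: dict[str, float],
                      csf: dict[str, float], dura: dict[str, float]) -> np.ndarray:
    """Label a 2D cross-section grid (world mm coordinates)."""
    a, b = p["D2"] / 2, p["D1"] / 2
    lab = np.zeros(X.shape, dtype=np.uint8)
    r = np.hypot(X, Y)
    theta = np.arctan2(Y, X)
    r_e = _ellipse_radius(theta, a, b)
    inside = r <= r_e
    lab[inside] = LABELS["white_matter"]

    y_junction = b - p["D7"]
    y_top = b - p["D6"]
    y_bot = b - p["D4"]
    ax = np.abs(X)
    m_d, l_d, v_d = _horn_interval(Y, y_junction, y_top, p["D8"], p["D5"])
    m_v, l_v, v_v = _horn_interval(2 * y_junction - Y, y_junction,
                                   y_junction + (y_junction - y_bot),
                                   p["D9"], p["D3"])
    horn = (v_d & (ax >= m_d) & (ax <= l_d)) | (v_v & (ax >= m_v) & (ax <= l_v))
    bridge = (np.abs(Y - y_junction) <= BRIDGE_HALF_HEIGHT_MM) & (ax <= _bridge_reach(p))
    lab[inside & (horn | bridge)] = LABELS["gray_matter"]

    t_csf = _side_thickness(theta, csf) * 1e-3
    t_dura = _side_thickness(theta, dura) * 1e-3
    ring = ~inside
    lab[ring & (r <= r_e + t_csf)] = LABELS["csf"]
    lab[ring & (r > r_e + t_csf) & (r <= r_e + t_csf + t_dura)] = LABELS["dura"]
    return lab


# ---------------------------------------------------------------------------
# rootlet tube layout
# ---------------------------------------------------------------------------

@dataclass
class Tube:
    segment_id: str
    side: str                  # 'dorsal' | 'ventral'
    z: float
    phi: float                 # polar angle of the tube axis, radians
    p_in: tuple[float, float]  # in-plane inner endpoint (inside white matter)
    p_out: tuple[float, float]
    surface: tuple[float, float]  # where the axis crosses the cord boundary
    radius: float


def _interp_profiles(config: PhantomConfig):
    """Per-quantity linear interpolators over z (nodes at segment mid-z)."""
    mids = np.array([s.mid_z for s in config.segments])

    def interp(values):
        vals = np.asarray(values, dtype=float)

        def at(z):
            return np.interp(z, mids, vals)

        return at

    prof = {k: interp([getattr(s, k) for s in config.segments])
            for k in ("D1", "D2", "D3", "D4", "D5", "D6", "D7", "D8", "D9")}
    for side in SIDES:
        prof[f"csf_{side}"] = interp([s.csf_gap[side] for s in config.segments])
        prof[f"dura_{side}"] = interp([s.dura_thickness[side] for s in config.segments])
    return prof


def _params_at(prof, z: float) -> tuple[dict, dict, dict]:
    p = {k: float(prof[k](z)) for k in
         ("D1", "D2", "D3", "D4", "D5", "D6", "D7", "D8", "D9")}
    csf = {s: float(prof[f"csf_{s}"](z)) for s in SIDES}
    dura = {s: float(prof[f"dura_{s}"](z)) for s in SIDES}
    return p, csf, dura


def _z_slots(spec: SegmentSpec, zone_len: float, r_t: float, dz: float) -> list[float]:
    """Anchor z positions: two sub-zones around the protected mid plane."""
    zc = spec.mid_z
    z_lo, z_hi = zc - zone_len / 2 + r_t, zc + zone_len / 2 - r_t
    slots: list[float] = []
    for a0, a1 in ((z_lo, zc - MID_EXCLUSION_MM), (zc + MID_EXCLUSION_MM, z_hi)):
        span = a1 - a0
        if span < 0:
            continue
        m = int(span // dz) + 1
        slots.extend(np.linspace(a0, a1, m).tolist())
    return sorted(slots)


def _rootlet_layout(config: PhantomConfig) -> list[Tube]:
    """Place every rootlet tube, enforcing the clearance contract."""
    prof = _interp_profiles(config)
    tubes: list[Tube] = []
    for spec in config.segments:
        for side, n, width, zone in (
            ("dorsal", spec.n_dorsal_rootlets, spec.W_D, spec.L_DREZ),
            ("ventral", spec.n_ventral_rootlets, spec.W_V, spec.L_VREZ),
        ):
            if n <= 0:
                continue
            tubes.extend(_layout_side(config, prof, spec, side, n, width, zone))
    return tubes


def _layout_side(config, prof, spec: SegmentSpec, side: str, n: int,
                 width: float, zone: float) -> list[Tube]:
    r_t = spec.rootlet_radius
    dz = 2 * r_t + ROOTLET_CLEARANCE_MM
    y_sign = 1.0 if side == "dorsal" else -1.0
    slots_z = _z_slots(spec, zone, r_t, dz)
    if not slots_z:
        raise OverlapError(f"{spec.segment_id}/{side}: entry zone too short")

    p_mid, csf_mid, dura_mid = _params_at(prof, spec.mid_z)
    a, b = p_mid["D2"] / 2, p_mid["D1"] / 2
    x_half = min(width / 2, 0.9 * a)
    y_s = y_sign * b * math.sqrt(max(1e-9, 1 - (x_half / a) ** 2))
    phi_r = math.atan2(y_s, x_half)
    phi_l = math.atan2(y_s, -x_half)
    r_anchor = math.hypot(x_half, y_s)
    r_in = max(0.3, r_anchor - 0.25)
    need = 2 * r_t + ROOTLET_CLEARANCE_MM

    # angular gap between the left and right centre tracks (shorter way
    # around through the dorsal/ventral pole)
    gap = abs(_angdiff(phi_l, phi_r))
    merged = gap * r_in < need

    def make_tube(z: float, phi: float) -> Tube:
        p, csf, dura = _params_at(prof, z)
        az, bz = p["D2"] / 2, p["D1"] / 2
        r_surf = float(_ellipse_radius(np.array([phi]), az, bz)[0])
        t_out = (_side_thickness(np.array([phi]), csf)[0]
                 + _side_thickness(np.array([phi]), dura)[0]) * 1e-3
        r0 = max(0.25, r_surf - 0.25)
        r1 = r_surf + t_out + 1.2
        return Tube(
            segment_id=spec.segment_id, side=side, z=z, phi=phi,
            p_in=(r0 * math.cos(phi), r0 * math.sin(phi)),
            p_out=(r1 * math.cos(phi), r1 * math.sin(phi)),
            surface=(r_surf * math.cos(phi), r_surf * math.sin(phi)),
            radius=r_t,
        )

    if merged:
        # near-midline columns: a single z-lattice, anchors alternating sides
        if n > len(slots_z):
            raise OverlapError(
                f"{spec.segment_id}/{side}: {n} rootlets exceed capacity "
                f"{len(slots_z)} at the required clearance")
        picks = _spread_indices(len(slots_z), n)
        phis = [phi_r, phi_l]
        return [make_tube(slots_z[i], phis[j % 2]) for j, i in enumerate(picks)]

    # angular tracks around each half's centre line; the side tracks must
    # keep clear of the opposite half's tracks across the pole
    delta = max(math.radians(15.0), need / r_in)
    if delta <= math.radians(35.0) and (gap - 2 * delta) * r_in >= need:
        track_offsets = [0.0, delta, -delta]
    else:
        track_offsets = [0.0]

    out: list[Tube] = []
    for half_phi, n_half in ((phi_r, (n + 1) // 2), (phi_l, n // 2)):
        if n_half == 0:
            continue
        slots = [(z, half_phi + off) for z in slots_z for off in track_offsets]
        if n_half > len(slots):
            raise OverlapError(
                f"{spec.segment_id}/{side}: {n_half} rootlets per half exceed "
                f"capacity {len(slots)} at the required clearance")
        picks = _spread_indices(len(slots), n_half)
        out.extend(make_tube(*slots[i]) for i in picks)
    return out


def _angdiff(a: float, b: float) -> float:
    d = (a - b + math.pi) % (2 * math.pi) - math.pi
    return d


def _spread_indices(n_slots: int, n_pick: int) -> list[int]:
    idx = np.round(np.linspace(0, n_slots - 1, n_pick)).astype(int)
    if len(np.unique(idx)) != n_pick:  # extremely dense packing fallback
        idx = np.arange(n_pick)
    return idx.tolist()


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _grid_half_extents(config: PhantomConfig) -> tuple[float, float]:
    half_x = half_y = 0.0
    for s in config.segments:
        a, b = s.D2 / 2, s.D1 / 2
        shell = (max(s.csf_gap.values()) + max(s.dura_thickness.values())) * 1e-3
        half_y = max(half_y, b + shell + 1.2 + 0.5)
        drg_l, drg_w, drg_t = s.drg_axes
        half_x = max(half_x, a + shell + 0.7 + drg_w + 0.5, a + shell + 1.2 + 0.5)
        half_y = max(half_y, drg_t / 2 + 0.5)
    return half_x, half_y


def render_phantom(config: PhantomConfig) -> tuple[VoxelLabelVolume, pd.DataFrame]:
    """Voxelise the configuration; return the volume and its ground truth.

    Raises ``ResolutionError`` when a shell or tube would be thinner than a
    voxel, and ``OverlapError`` when rootlet tubes cannot keep the required
    clearance at the requested counts.
    """
    validate_config(config)
    sp = config.spacing
    for s in config.segments:
        if min(s.dura_thickness.values()) * 1e-3 < sp:
            raise ResolutionError(
                f"resolution too coarse: dura at {s.segment_id} thinner than one voxel")
        if min(s.csf_gap.values()) * 1e-3 < sp:
            raise ResolutionError(
                f"resolution too coarse: CSF at {s.segment_id} thinner than one voxel")
        if 2 * s.rootlet_radius < sp:
            raise ResolutionError(
                f"resolution too coarse: rootlets at {s.segment_id}")
        if min(s.drg_axes) < 2 * sp:
            raise ResolutionError(
                f"resolution too coarse: DRG at {s.segment_id}")

    half_x, half_y = _grid_half_extents(config)
    nx = 2 * int(math.ceil(half_x / sp)) + 1
    ny = 2 * int(math.ceil(half_y / sp)) + 1
    total_len = config.segments[-1].z_range[1] - config.segments[0].z_range[0]
    nz = int(round(total_len / sp))
    origin = (-(nx - 1) / 2 * sp, -(ny - 1) / 2 * sp,
              config.segments[0].z_range[0] + sp / 2)

    xs = origin[0] + np.arange(nx) * sp
    ys = origin[1] + np.arange(ny) * sp
    X, Y = np.meshgrid(xs, ys, indexing="ij")

    prof = _interp_profiles(config)
    z_slices = origin[2] + np.arange(nz) * sp
    arr = np.zeros((nx, ny, nz), dtype=np.uint8)
    for k, z in enumerate(z_slices):
        p, csf, dura = _params_at(prof, z)
        arr[:, :, k] = _classify_section(X, Y, p, csf, dura)

    tubes = _rootlet_layout(config)
    _raster_tubes(arr, tubes, origin, sp)
    _raster_drgs(arr, config, prof, origin, sp)

    vol = VoxelLabelVolume(array=arr, spacing=(sp, sp, sp), origin=origin,
                           label_map=dict(config.label_map),
                           meta={"seed": config.seed, "kind": "phantom"})
    truth = build_ground_truth(config, tubes)
    return vol, truth


def _raster_tubes(arr, tubes: list[Tube], origin, sp) -> None:
    nx, ny, nz = arr.shape
    overwritable = (LABELS["background"], LABELS["csf"], LABELS["dura"])
    for t in tubes:
        code = LABELS["dorsal_rootlet"] if t.side == "dorsal" else LABELS["ventral_rootlet"]
        k0 = int(math.ceil((t.z - t.radius - origin[2]) / sp))
        k1 = int(math.floor((t.z + t.radius - origin[2]) / sp))
        x0, y0 = t.p_in
        x1, y1 = t.p_out
        dx, dy = x1 - x0, y1 - y0
        seg_len2 = dx * dx + dy * dy
        lo_x = int((min(x0, x1) - t.radius - origin[0]) / sp)
        hi_x = int((max(x0, x1) + t.radius - origin[0]) / sp) + 1
        lo_y = int((min(y0, y1) - t.radius - origin[1]) / sp)
        hi_y = int((max(y0, y1) + t.radius - origin[1]) / sp) + 1
        lo_x, hi_x = max(lo_x, 0), min(hi_x, nx)
        lo_y, hi_y = max(lo_y, 0), min(hi_y, ny)
        if lo_x >= hi_x or lo_y >= hi_y:
            continue
        gx = origin[0] + np.arange(lo_x, hi_x) * sp
        gy = origin[1] + np.arange(lo_y, hi_y) * sp
        GX, GY = np.meshgrid(gx, gy, indexing="ij")
        s = np.clip(((GX - x0) * dx + (GY - y0) * dy) / seg_len2, 0.0, 1.0)
        d2 = (GX - (x0 + s * dx)) ** 2 + (GY - (y0 + s * dy)) ** 2
        for k in range(max(k0, 0), min(k1, nz - 1) + 1):
            zk = origin[2] + k * sp
            rho2 = t.radius ** 2 - (zk - t.z) ** 2
            if rho2 <= 0:
                continue
            hit = d2 <= rho2
            sub = arr[lo_x:hi_x, lo_y:hi_y, k]
            sub[hit & np.isin(sub, overwritable)] = code


def _drg_centers(config: PhantomConfig, prof) -> list[tuple[str, str, float, float, float]]:
    out = []
    for s in config.segments:
        p, csf, dura = _params_at(prof, s.mid_z)
        a = p["D2"] / 2
        shell = (csf["left"] + dura["left"]) * 1e-3
        drg_l, drg_w, drg_t = s.drg_axes
        cx = a + shell + 0.7 + drg_w / 2
        for side, sign in (("right", 1.0), ("left", -1.0)):
            out.append((s.segment_id, side, sign * cx, 0.0, s.mid_z))
    return out


def _raster_drgs(arr, config: PhantomConfig, prof, origin, sp) -> None:
    nx, ny, nz = arr.shape
    for seg_id, _side, cx, cy, cz in _drg_centers(config, prof):
        spec = config.segment(seg_id)
        drg_l, drg_w, drg_t = spec.drg_axes
        ax_x, ax_y, ax_z = drg_w / 2, drg_t / 2, drg_l / 2
        lo = [int((c - r - o) / s0) for c, r, o, s0 in
              ((cx, ax_x, origin[0], sp), (cy, ax_y, origin[1], sp), (cz, ax_z, origin[2], sp))]
        hi = [int((c + r - o) / s0) + 2 for c, r, o, s0 in
              ((cx, ax_x, origin[0], sp), (cy, ax_y, origin[1], sp), (cz, ax_z, origin[2], sp))]
        lo = [max(v, 0) for v in lo]
        hi = [min(h, n) for h, n in zip(hi, (nx, ny, nz))]
        if any(l >= h for l, h in zip(lo, hi)):
            continue
        gx = origin[0] + np.arange(lo[0], hi[0]) * sp
        gy = origin[1] + np.arange(lo[1], hi[1]) * sp
        gz = origin[2] + np.arange(lo[2], hi[2]) * sp
        GX, GY, GZ = np.meshgrid(gx, gy, gz, indexing="ij")
        inside = (((GX - cx) / ax_x) ** 2 + ((GY - cy) / ax_y) ** 2
                  + ((GZ - cz) / ax_z) ** 2) <= 1.0
        sub = arr[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub[inside & (sub == LABELS["background"])] = LABELS["drg"]


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def build_ground_truth(config: PhantomConfig, tubes: list[Tube]) -> pd.DataFrame:
    """Ground-truth table of realized per-segment quantities.

    Every value is computed from the generating geometry by an independent
    route (dense polygons, fine quadrature, the analytic tube layout), not
    from the voxel grid, so recovery tests compare two genuinely different
    measurement paths.
    """
    prof = _interp_profiles(config)
    rows: list[tuple] = []

    def add(seg, quantity, side, value, units):
        rows.append((seg, quantity, side, float(value), units))

    theta = np.linspace(0, 2 * math.pi, 4096, endpoint=False)
    by_seg_side: dict[tuple[str, str], list[Tube]] = {}
    for t in tubes:
        by_seg_side.setdefault((t.segment_id, t.side), []).append(t)

    for i, s in enumerate(config.segments):
        seg = s.segment_id
        p, csf, dura = _params_at(prof, s.mid_z)
        a, b = p["D2"] / 2, p["D1"] / 2
        for side in SIDES:
            add(seg, "dura_thickness", side, dura[side], "um")
            add(seg, "csf_thickness", side, csf[side], "um")
        r_e = _ellipse_radius(theta, a, b)
        t_csf = _side_thickness(theta, csf) * 1e-3
        t_dura = _side_thickness(theta, dura) * 1e-3
        r_out = r_e + t_csf + t_dura
        add(seg, "dura_circumference", "none", _polar_perimeter(theta, r_out), "mm")
        add(seg, "C1", "none", _polar_perimeter(theta, r_e), "mm")

        add(seg, "csf_volume", "none", _csf_volume_truth(config, prof, s, tubes), "mm3")

        area_gray = _gray_area(s)
        add(seg, "A1", "none", area_gray, "mm2")
        add(seg, "A2", "none", math.pi * a * b - area_gray, "mm2")

        add(seg, "D1", "none", s.D1, "mm")
        add(seg, "D2", "none", s.D2, "mm")
        for q in ("D3", "D4", "D5", "D6", "D7", "D8", "D9"):
            for side in ("left", "right"):
                add(seg, q, side, getattr(s, q), "mm")

        for side, n_conf, l_conf in (("dorsal", s.n_dorsal_rootlets, s.L_DREZ),
                                     ("ventral", s.n_ventral_rootlets, s.L_VREZ)):
            group = by_seg_side.get((seg, side), [])
            add(seg, "n_rootlets", side, len(group), "count")
            if group:
                zs = [t.z for t in group]
                r_t = group[0].radius
                add(seg, "L_DREZ" if side == "dorsal" else "L_VREZ", side,
                    (max(zs) - min(zs)) + 2 * r_t, "mm")
                # medial edge of each half's entry band: the tube's surface
                # crossing minus its in-plane half-width
                xs_right = [t.surface[0] - r_t * abs(math.sin(t.phi))
                            for t in group if t.surface[0] > 0]
                xs_left = [t.surface[0] + r_t * abs(math.sin(t.phi))
                           for t in group if t.surface[0] < 0]
                if xs_right and xs_left:
                    w = min(xs_right) - max(xs_left)
                    add(seg, "W_D" if side == "dorsal" else "W_V", side, w, "mm")
                if i + 1 < len(config.segments):
                    nxt = by_seg_side.get((config.segments[i + 1].segment_id, side), [])
                    if nxt:
                        gap = (min(t.z for t in nxt) - r_t) - (max(zs) + r_t)
                        add(seg, "L_DRBZ" if side == "dorsal" else "L_VRBZ",
                            side, max(0.0, gap), "mm")

        for view in SIDES:
            add(seg, "rootlet_proportion", view,
                _coverage_truth(config, prof, s, tubes, view), "%")

        drg_l, drg_w, drg_t = s.drg_axes
        for side in ("left", "right"):
            add(seg, "L_DRG", side, drg_l, "mm")
            add(seg, "W_DRG", side, drg_w, "mm")
            add(seg, "T_DRG", side, drg_t, "mm")
            add(seg, "V_DRG", side,
                4.0 / 3.0 * math.pi * (drg_l / 2) * (drg_w / 2) * (drg_t / 2), "mm3")

    return pd.DataFrame(rows, columns=["segment", "quantity", "side_or_view",
                                       "value", "units"])


def _polar_perimeter(theta: np.ndarray, r: np.ndarray) -> float:
    x, y = r * np.cos(theta), r * np.sin(theta)
    return float(np.sum(np.hypot(np.diff(x, append=x[:1]), np.diff(y, append=y[:1]))))


def _csf_volume_truth(config: PhantomConfig, prof, spec: SegmentSpec,
                      tubes: list[Tube]) -> float:
    """Quadrature CSF volume of one segment, minus rootlet punch-through."""
    sp = config.spacing
    theta = np.linspace(0, 2 * math.pi, 1440, endpoint=False)
    dth = theta[1] - theta[0]
    z0, z1 = spec.z_range
    zs = np.arange(z0 + sp / 2, z1, sp)
    vol = 0.0
    for z in zs:
        p, csf, _ = _params_at(prof, z)
        a, b = p["D2"] / 2, p["D1"] / 2
        r_e = _ellipse_radius(theta, a, b)
        t = _side_thickness(theta, csf) * 1e-3
        vol += 0.5 * np.sum((r_e + t) ** 2 - r_e ** 2) * dth * sp
    punch = 0.0
    for t in tubes:
        if z0 <= t.z < z1:
            p, csf, _ = _params_at(prof, t.z)
            tc = float(_side_thickness(np.array([t.phi]), csf)[0]) * 1e-3
            punch += math.pi * t.radius ** 2 * tc
    return vol - punch


def _coverage_truth(config: PhantomConfig, prof, spec: SegmentSpec,
                    tubes: list[Tube], view: str) -> float:
    """Analytic projected rootlet coverage (%) for one segment and view.

    Dorsal/ventral views project that side's rootlets along y; lateral views
    project both rootlet populations restricted to the viewed half along x.
    The silhouette band is the white-matter envelope's projected width; all
    rootlet shadow pixels inside the segment's z-range count (overlapping
    or flanking the band).
    """
    pitch = 0.02
    z0, z1 = spec.z_range
    zs = np.arange(z0 + pitch / 2, z1, pitch)
    if view in ("dorsal", "ventral"):
        group = [t for t in tubes if t.segment_id == spec.segment_id and t.side == view]
        axis = 0  # shadow coordinate is x
    else:
        sign = -1.0 if view == "left" else 1.0
        group = [t for t in tubes if t.segment_id == spec.segment_id
                 and sign * t.surface[0] > 0]
        axis = 1  # shadow coordinate is y

    half = np.empty_like(zs)
    for j, z in enumerate(zs):
        p, _, _ = _params_at(prof, z)
        half[j] = p["D2"] / 2 if axis == 0 else p["D1"] / 2
    band_area = float(np.sum(2 * half) * pitch)
    if not group:
        return 0.0

    # only the tube portion outside the cord casts a rootlet shadow (inside
    # the cord the tube voxels carry cord labels); in-plane half-width of a
    # radial tube projected on the shadow axis
    def perp(t: Tube) -> float:
        return t.radius * (abs(math.sin(t.phi)) if axis == 0 else abs(math.cos(t.phi)))

    u_min = min(min(t.surface[axis], t.p_out[axis]) for t in group) - 0.3
    u_max = max(max(t.surface[axis], t.p_out[axis]) for t in group) + 0.3
    us = np.arange(u_min, u_max, pitch)
    mask = np.zeros((len(us), len(zs)), dtype=bool)
    for t in group:
        u_s, u_o = t.surface[axis], t.p_out[axis]
        if u_s <= u_o:
            lo_u, hi_u = u_s - perp(t), u_o + t.radius
        else:
            lo_u, hi_u = u_o - t.radius, u_s + perp(t)
        sel_u = (us >= lo_u) & (us <= hi_u)
        sel_z = np.abs(zs - t.z) <= t.radius
        mask[np.ix_(sel_u, sel_z)] = True
    shadow_area = float(mask.sum()) * pitch * pitch
    return 100.0 * shadow_area / band_area


def truth_value(truth: pd.DataFrame, segment: str, quantity: str,
                side: str = "none") -> float:
    sel = truth[(truth["segment"] == segment) & (truth["quantity"] == quantity)
                & (truth["side_or_view"] == side)]
    if len(sel) != 1:
        raise KeyError(f"no unique truth record for {segment}/{quantity}/{side}")
    return float(sel["value"].iloc[0])


# ---------------------------------------------------------------------------
# CSF-volume matching
# ---------------------------------------------------------------------------

def match_csf_total(config: PhantomConfig, total_mm3: float) -> PhantomConfig:
    """Scale every segment's CSF gap so realized volumes sum to ``total_mm3``.

    The per-segment gap profile keeps its shape; a single multiplier is
    solved by bisection against the same quadrature used for ground truth.
    """
    base = [dict(s.csf_gap) for s in config.segments]

    def configured(mult: float) -> PhantomConfig:
        segs = []
        for s, g in zip(config.segments, base):
            segs.append(replace(s, csf_gap={k: v * mult for k, v in g.items()},
                                dura_thickness=dict(s.dura_thickness)))
        return PhantomConfig(segments=segs, spacing=config.spacing, seed=config.seed)

    def total(mult: float) -> float:
        cfg = configured(mult)
        prof = _interp_profiles(cfg)
        tubes = _rootlet_layout(cfg)
        return sum(_csf_volume_truth(cfg, prof, s, tubes) for s in cfg.segments)

    lo, hi = 0.5, 50.0
    t_lo, t_hi = total(lo), total(hi)
    if not (t_lo < total_mm3 < t_hi):
        raise ValueError("target CSF total outside the attainable range")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if total(mid) < total_mm3:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-7:
            break
    return configured(0.5 * (lo + hi))


# ---------------------------------------------------------------------------
# deformations
# ---------------------------------------------------------------------------

def bend_volume(volume: VoxelLabelVolume, amplitude: float,
                wavelength: float) -> VoxelLabelVolume:
    """Sinusoidal in-plane bend of the cord axis in the x–z plane.

    Backward-mapped nearest-label resampling: the slice at world z is
    shifted by ``amplitude * sin(2π z / wavelength)`` along x.  The true
    bent centreline is stored in the output's ``meta['true_centerline']``.
    Raises ``OutOfBoundsError`` if the displaced cord would leave the grid.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    arr = volume.array
    nx, ny, nz = arr.shape
    sx, _, sz = volume.spacing
    occupied = np.nonzero((arr != 0).any(axis=(1, 2)))[0]
    if occupied.size and abs(amplitude) > 0:
        margin_lo = occupied[0] * sx
        margin_hi = (nx - 1 - occupied[-1]) * sx
        if abs(amplitude) > min(margin_lo, margin_hi):
            raise OutOfBoundsError("out of bounds: bent cord exits the grid")

    zw = volume.z_coords()
    shifts = amplitude * np.sin(2 * math.pi * zw / wavelength)
    out = np.zeros_like(arr)
    for k in range(nz):
        sh = int(round(shifts[k] / sx))
        if sh == 0:
            out[:, :, k] = arr[:, :, k]
        elif sh > 0:
            out[sh:, :, k] = arr[:-sh, :, k]
        else:
            out[:sh, :, k] = arr[-sh:, :, k]
    res = volume.copy()
    res.array = out
    cx = volume.origin[0] + (nx - 1) / 2 * volume.spacing[0]
    cy = volume.origin[1] + (ny - 1) / 2 * volume.spacing[1]
    res.meta["true_centerline"] = np.column_stack(
        [cx + amplitude * np.sin(2 * math.pi * zw / wavelength),
         np.full(nz, cy), zw])
    res.meta["bend"] = {"amplitude": amplitude, "wavelength": wavelength}
    return res


def shrink_volume(volume: VoxelLabelVolume, factors) -> VoxelLabelVolume:
    """Simulate ex-vivo shrinkage: resample by the inverse of the given
    elongation percentages, so ``apply_scale`` with the same factors recovers
    the original dimensions within one voxel."""
    from .geometry import ScaleFactors, _rescale  # local import: no cycle at load

    f = ScaleFactors(*factors) if not isinstance(factors, ScaleFactors) else factors
    scales = tuple(1.0 / (1.0 + e / 100.0) for e in (f.ex, f.ey, f.ez))
    return _rescale(volume, scales)
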