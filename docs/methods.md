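# Methods

This document describes the synthetic anatomy, the measurement conventions
and the algorithms, including deliberate modeling decisions and their
rationale. Coordinates are world millimetres: x mediolateral, y
dorsoventral (dorsal = +y), z rostrocaudal; `world = origin + index ·
spacing` with voxel-centre indexing. Labels: 0 background, 1 white matter,
2 gray matter, 3 CSF, 4 dura, 5 dorsal rootlet, 6 ventral rootlet, 7 DRG.

## Phantom geometry

Each of the 28 segments C3–S2 is an axial profile extruded over its
z-range, with linear interpolation of dimensions between segment midpoints.

* **White matter** — ellipse with transverse diameter D2 and dorsoventral
  diameter D1.
* **Gray matter** — H-shape built from per-side dorsal and ventral horn
  intervals plus a central commissure bridge (0.4 mm tall). The horn
  geometry is parameterized by the lateral boundaries (D3 dorsal, D5
  ventral, medial edges D8/D9) and the depth landmarks D4, D6, D7 measured
  from the dorsal cord surface, with plateau and tip tapers so horn areas
  integrate to the analytic A1 target.
* **CSF and dura shells** — concentric shells outside the cord ellipse
  whose per-side thicknesses (dorsal/ventral/left/right) are blended
  angularly with cos² weights. Shell thicknesses carry a seeded ±2–3 µm
  per-segment jitter so repeated-measures statistics see variation;
  everything else is deterministic given the configuration.
* **Rootlets** — capsule tubes (hemispherical ends) from the cord surface
  through CSF and dura, laid out on angular tracks and z-lattices inside
  each segment's dorsal/ventral entry bands, with ≥0.32 mm surface-to-
  surface clearance (3 voxels at 0.1 mm) so connected-component counting is
  exact, and a ±0.45 mm tube-free window at each segment's mid-z so shell
  thickness measurements are taken on unpunctured rings.
* **DRG** — one ellipsoid per side per segment, lateral to the dura.

**Ground truth** is computed from the generating geometry, not from voxels:
areas by dense polygon integration, the CSF volume by angular quadrature of
the shell annulus minus the exact πr²·t cylinder punch-through of each
rootlet tube, rootlet-zone widths and coverage proportions from the tube
layout, perimeters by polar arc-length quadrature. This makes every
measurement's discretization error observable.

### Resolution guards

Rendering refuses configurations whose thinnest structure (dura ring,
rootlet tube diameter, horn widths) falls below one voxel, with an error
naming the offending segment.

## Measurement conventions

* **Shell thicknesses** (dura, CSF) — averaged 4-ray chord lengths along
  each cardinal direction (±5°, ±15° auxiliary rays), marched at
  quarter-voxel steps on the mid-slice of the segment.
* **Perimeters** (cord C1, dural circumference) — sub-voxel contours from a
  Gaussian-smoothed indicator (σ = 1.4 voxels) at iso-level 0.5. σ was
  calibrated on analytic ellipses: smaller σ retains staircase inflation
  (+0.9 % at σ = 0.8), σ ≈ 1.4–1.6 keeps |error| < 0.35 %.
* **Cross-section measures** — D1/D2 are bounding extents; D3–D9 are
  per-side distances with the midline at the cord centroid and half-voxel
  edge corrections (outer edges +s/2, medial edges −s/2). D8/D9 exclude the
  commissural rows (gray voxels within 1.5 voxels of the midline on both
  sides), matching their definition as horn medial boundaries.
* **A1/A2** — gray area and white area by voxel counting. The gray H-shape
  union is area-matched to the analytic target by construction.
* **Rootlet entry-zone metrics** — entry voxels are rootlet voxels
  26-adjacent to white matter. W (zone width) spans the medial entry edges;
  L_REZ/L_RBZ are longitudinal extents of the entry band and of the gap to
  the next segment's band.
* **Rootlet counts** — 26-connected components of the rootlet label
  touching the 2-voxel-dilated cord shell within the segment's z-range.
* **Coverage** — percentage of the segment's cord silhouette (dorsal,
  ventral or lateral view) shadowed by rootlet tubes; lateral views count
  both rootlet labels on the viewed half.
* **DRG dimensions** — per-component principal-axis extents (SVD), side
  assigned by centroid position relative to the cord.

Every record carries a method version; measurements that cannot be made
(e.g. a view without rootlets) are reported with a reason instead of a
number rather than silently dropped.

## Straightening and registration

* **Centerline** — per-slice cord centroids, smoothed by a least-squares
  cubic spline with knots every 5 mm, resampled at 0.5 mm arc length,
  with rotation-minimizing frames (double-reflection method) to avoid
  torsion-induced twist.
* **Straightening** — curved planar reformation: each output slice samples
  the plane normal to the centerline (nearest-neighbour interpolation to
  preserve labels; edge-value extension so end planes stay complete).
  A frame flip > 45° between steps aborts with an error.
* **Scale estimation** — elongation percentages `(ref/moving − 1) · 100`
  from cord extents. Width/height use the **mean** of per-slice bounding
  extents: because the cord's width varies along z, averaging dithers away
  the one-voxel quantization of each slice's extent (a median would retain
  it, quantizing a ~3 mm cord's estimate in ~3 % steps). Length is the
  bounding z extent.
* **Thin-plate splines** — exact 2D interpolation (kernel U(r) = r² log r)
  with optional ridge regularization; zero regularization reproduces
  landmarks to machine precision and pure translations globally. Collinear
  landmarks are rejected. Volumes are warped slice-wise by
  backward-mapped inverse displacement fields, linearly blended between
  landmark planes; z is never mixed across slices.

## Reconstruction (lofting)

Per-slice contours are extracted from the hole-filled silhouette of the
requested label set, resampled to equal arc length (periodic cubic spline,
counterclockwise, seam at the dorsal-most point), and lofted by index
correspondence with shorter-diagonal quad splitting and centroid-fan end
caps; winding is flipped if the signed volume is negative. Volume and area
come from the divergence theorem; watertightness requires zero boundary
edges and Euler characteristic 2.

**Envelope semantics.** Because contours trace the filled outer boundary,
the lofted "white-matter" solid is the cord envelope (the gray interior is
inside it), and the CSF and dura surfaces are lofted from the union of the
labels they enclose — necessary because rootlet tubes puncture the thin
CSF/dura rings, which are therefore not single closed contours by
themselves. Loft volumes must be compared against hole-filled voxel
silhouette volumes, not bare label counts. Deeply concave shapes (the
isolated gray H) lose a few percent of area to contour smoothing; convex
envelopes are recovered within ~1 %.

## Statistics

Friedman's test with the tie-corrected statistic; all-tied data give
χ² = 0, p = 1. The exact p-value is computed by full enumeration of
within-block rank permutations when (k!)ⁿ ≤ 10⁶ and otherwise by a fixed-
seed Monte-Carlo permutation test (10⁵ resamples, add-one correction), so
the permutation p is invariant under monotone transformations of the data.
Post-hoc pairwise comparisons use Dunn's test on rank sums with Bonferroni
correction over k(k−1)/2 pairs. Summaries use the sample (n−1) standard
deviation.

Note: with n = 4 blocks the χ² approximation is coarse (e.g. 4 concordant
blocks of k = 3: asymptotic p = 0.018, exact p = 0.0046); the asymptotic
value remains the default for comparability with standard software.

## Determinism

All artifacts are byte-stable across reruns with the same config and seed:
uncompressed NIfTI, binary STL with a fixed header, CSV with fixed column
order and 6-decimal floats, JSON with sorted keys and no timestamps. The
run manifest records the seed and configuration.
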