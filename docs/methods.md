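# Methods

## Problem and input

A single femur is given as an N×3 point cloud in millimetres with one
region label per point (0 = head, 1 = neck, 2 = shaft).  The coordinate
frame is arbitrary: every step below is built from centroids, fitted
primitives and angles, so the measurement is invariant to rigid motion
and, with mm-denominated thresholds scaled, to uniform scaling.  No
anatomical coordinate system, laterality handling or landmark detection
is required; left and right femurs give the same angle magnitude
because the construction is reflection-invariant.

## 3D measurement

1. **Head center.**  The head points are fit with a sphere by the
   linear least-squares scheme on mean-centered coordinates
   uᵢ = xᵢ − x̄ (and likewise v, w): the center solves the 3×3 normal
   equations with right-hand side ½·Σ qᵢ|qᵢ|², and the radius is the
   RMS point-to-center distance.  The fit is exact for exact sphere
   samples and refuses ill-conditioned systems (condition number
   > 1e12, e.g. coplanar inputs).
2. **Neck axis.**  The neck is too irregular for surface fitting, so
   its centroid is used; the neck axis runs from the neck centroid to
   the head-sphere center (orientation: neck → head).
3. **Shaft axis.**  The shaft is parameterized along its dominant
   principal direction, oriented proximal → distal using the head
   center as the proximal hint; axial position is normalized to [0, 1]
   over the labeled shaft's extent.  The axis joins the centroids of
   the [0.60, 0.70) and [0.70, 0.80) slabs — a region far enough from
   the lesser trochanter and from the distal bow to be nearly
   prismatic.  Slabs are half-open so adjacent slabs partition the
   shaft without double counting.
4. **Angle.**  NSA = arccos of the clamped dot product of the two unit
   directions, in degrees.  With the orientations above the value lands
   in the anatomical range (~110–150°) rather than its supplement; a
   result below 90° is flagged as a probable orientation fault instead
   of being silently replaced.

The two fitted axes rarely intersect; their closest-approach distance
(0 for coplanar axes) is reported as a diagnostic because it is the
main driver of 2D-vs-3D disagreement.

## 2D measurement

The anteroposterior radiograph is simulated by the plane through three
anatomical points: the head-sphere center, the neck centroid, and the
centroid of the distal 10% of the shaft.  Since the first two lie on
the neck axis and the third near the shaft axis, the plane
approximately contains both axes regardless of femoral anteversion —
the same role the internally rotated limb plays in a real AP
radiograph.  Every region is orthogonally projected onto the plane
(foot of perpendicular p′ = p − t·n with t the signed distance), and
in-plane coordinates are taken in a deterministic orthonormal basis.

The projected head center is found by a RANSAC circle fit.  The trial
count is S = ⌈log(1−P)/log(1−ρᴷ)⌉ with confidence P = 0.99, minimal
sample K = 3 and inlier ratio ρ floored at 0.2, recomputed adaptively
from the best consensus so far and capped at 1000 trials; inliers are
points within 1.0 mm of the hypothesized circle (≈1.6× a typical
0.625 mm CT voxel).  Ties on inlier count break by smaller mean inlier
residual, then by earlier trial, so a seeded run is bit-reproducible.
The winning consensus set is refit by the algebraic (Kåsa)
least-squares circle, alternated with inlier reselection while the
consensus improves.

Two head-fit inputs are supported.  The default (`head_fit="boundary"`)
first extracts the projected head's silhouette — the outermost point in
each of 72 azimuthal sectors about the projected head centroid, with
sector zero anchored to the head-to-neck direction so the extraction is
frame-independent — and fits the circle to that rim.  The alternative
(`head_fit="all"`) fits all projected head points directly.  The
projected head is a solid disc whose rim has a ~80° gap where the neck
attaches; with interior points included, the inlier-count objective is
nearly flat along the gap bisector and the fitted center can wander by
several tenths of a millimetre, which is the dominant error of the 2D
method.  The silhouette restores a sharp objective, and its residual
center error points mostly along the neck axis, where it barely affects
the angle; hence the boundary path is the default.  A final polish
refits the circle geometrically at shrinking inlier bands (1.0 → 0.2 ×
the threshold) to trim sector-maxima that sit inside the rim near the
gap edges.

The neck axis in-plane joins the fitted circle center to the projected
neck centroid.  Shaft-slab membership is computed on the 3D shaft
before projection: projection is affine, so the centroids of the
projected members equal the projections of the 3D slab centroids, and
the slab extent cannot depend on the plane.  The NSA is the same
arccos formula on the in-plane directions.

## Synthetic femur generator

The generator emulates reconstructed femoral surface clouds with three
primitives whose axes are known exactly:

- **shaft**: a cylinder (radius 14 mm, length 120 mm) whose axis runs
  from the origin down −z; an optional anterior bow displaces the
  centerline by a half-sine (default 0 mm — the proximal 60–80% of the
  diaphysis used by the shaft axis is nearly straight in adult femurs;
  bow is kept as a sensitivity parameter);
- **neck**: a mildly tapered frustum (base 1.15× the 14 mm neck radius)
  whose axis leaves the origin at exactly `nsa_true` to the shaft
  direction, rotated by `anteversion` about the shaft axis (a rotation
  that provably preserves the angle) and translated by `axis_offset`
  along the common perpendicular, so the two true axes are skew with
  exactly that closest-approach distance;
- **head**: a sphere (radius 22 mm, neck length 55 mm to its center)
  minus the spherical cap buried inside the neck.

Points are allocated to primitives proportionally to surface area
(~2048 total, matching common point-cloud segmentation input sizes) and
placed on a structured lattice: rings of equally spaced azimuths for
the tubes (each ring's azimuthal sum cancels exactly, so slab centroids
sit on the true axis in the noise-free limit) and a Fibonacci lattice
for the sphere.  Reconstructed meshes are structured surfaces rather
than i.i.d. random samples, which this emulates; the stochastic
component is isotropic Gaussian noise (default σ = 0.3125 mm, half a
typical 0.625 mm CT voxel) plus an optional fraction of
bounding-box-uniform outliers, both driven by the spec's seed.

What the generator does *not* model: trochanters, the calcar, cortical
thickness, condyles, segmentation-boundary ambiguity (its labels are
exact by construction) and population shape variation.  Recovery
results on synthetic femurs therefore validate the measurement
geometry, not the upstream segmentation; real-data accuracy depends on
segmentation quality in addition.

## Evaluation module

Segmentation agreement uses per-class Dice = 2TP/(2TP+FP+FN) and
IoU = TP/(TP+FP+FN) with macro means over classes present in either
input (absent classes score 1 by convention and are excluded from the
macro mean; micro-pooled variants are also exposed).  Angle comparison
uses error = |NSA_ref − NSA_cand| and accuracy = (1 − |Δ/NSA_ref|)·100%,
averaged over pairs, and a pooled-variance two-sample Student's t-test
(two-tailed, df = n₁+n₂−2).  The two-sample form is kept even though a
paired design would be more powerful, because it is the comparison used
in the clinical workflow this package mirrors; constant-sample
degeneracies return (0, 1) for equal means and (±∞, 0) otherwise.
Cross-entropy over per-point class probabilities (clipped at 1e-12) is
provided for probabilistic segmentations.  Inverse-distance-weighted
interpolation (weights 1/dᵖ, defaults p = 2, k = 3, exact-match branch
at d ≤ 1e-12 mm) supports propagating labels from a subsampled cloud.

## Numerical choices and degeneracies

- Planes are stored in unit-normal implicit form; construction rejects
  triples whose cross-product norm is ≤ 1e-9 × the edge-length product.
- The shaft parameterization rejects point sets whose top two principal
  spreads are within 5% (no dominant elongation) or whose axial span is
  ≤ 10 mm.
- `angle_between` clamps the cosine to [−1, 1]; axis directions are
  normalized at construction to ‖d‖ = 1 ± 1e-12.
- The RANSAC trial-count formula returns 1 when ρᴷ = 1; empty slabs
  raise an error carrying the slab bounds; clouds missing a region name
  the missing region.
- All sweep experiments record per-row failures and continue.

## Study sizes

The recovery and consistency studies use 50 and 20 synthetic femurs of
2048 points each, the offset sweep 11 femurs over 0–10 mm, and the
RANSAC robustness check 20 runs of 200 points — sizes at which every
reported mean is stable to well under its decision margin while the
full suite runs in seconds.  The offset sweep is run noise-free because
the offset's effect on the 2D–3D gap is deterministic projection
geometry; surface noise only blurs the trend without changing it.
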