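# Methods

This note documents how `femoromorph` measures the twelve proximal-femur
parameters, how the synthetic data are constructed, and where the genuinely
open design choices were made.  Units are millimetres and degrees
throughout.

## Anatomical frame

All parameters are expressed in a bone-intrinsic frame:

* **superior (si)** — direction of the femoral shaft axis, pointing from
  the condyles toward the head;
* **medial (ml)** — the posterior condylar line orthogonalised against si,
  signed so the femoral head lies on the positive side;
* **anterior (ap)** — the remaining orthogonal direction, signed so the
  posterior condyles lie behind the shaft axis.

The frontal plane is span(si, ml), the sagittal plane span(si, ap), the
transversal plane span(ml, ap); the origin is the most distal point.  Left
and right femurs both get medial-positive/anterior-positive axes (no
mirroring), which makes every reported parameter side-independent and lets
a cohort pool sides.  The side is recovered from the handedness of the
(ml, ap, si) triple: right-handed ⇒ right femur.  The construction of the
frontal plane from the posterior condylar line is a standard biomechanics
convention; source datasets measured in a scanner-table frame may differ
by a few degrees in ATA, which is one reason published anteversion values
vary widely.

## Estimators

**Shaft axis (FSA).**  Starting from the whole-mesh principal axis, the
pipeline iterates: project vertices on the current axis → select the
diaphysis band (default 50–80 % of bone length, measured from the distal
end) → cut cross-sections every `section_spacing_mm` (2 mm) → fit a
total-least-squares (first principal component) line through the section
area centroids → repeat until the direction changes by less than
`convergence_deg` (0.1°, at most 10 iterations; the synthetic bodies
converge in 3–5).  Sections whose area deviates more than 30 % from the
band median are discarded before the fit: they graze a trochanter boss or
the condylar mass, and their centroids are not diaphyseal.  The superior
orientation is decided by which end's extreme vertex lies farther off the
axis (the head apex sits at the femoral offset, ≥ ~28 mm; the condylar
undersides at ~23 mm) and is re-checked against the fitted head centre.

**Head sphere (FHC, FHD).**  Candidate vertices: the superior
`head_region_fraction` (25 %) of bone length, medial of the shaft axis,
excluding vertices within 1.1 shaft radii of the axis (the medial shaft
wall).  Fit: algebraic least-squares sphere (Coope's linear method) as a
seed, 200 RANSAC hypotheses from 4-point samples scored by the ±1 mm
inlier band, then algebraic least squares on the best inlier set with one
re-selection pass.  A fit is accepted only if more than half the candidate
region is inliers; the fraction is reported.  All randomness is seeded
(per-mesh hash by default, explicit seed in the pipeline).

**Neck axis (FNA).**  The initial direction is the head-centre offset from
the shaft axis raised by a population-typical neck elevation (~37° above
the transversal plane); a purely transversal initial direction would place
the first-pass section stations outside the bone for normal neck
obliquity.  Stations run from `1.05 × head radius` outward from the FHC,
spaced `neck_section_spacing_mm` (1.5 mm, refined ×2/×3 if a short neck
yields fewer than 4 stations).  Each station's section polygon is the one
containing the station point (nearest-centroid fallback within 0.6 head
radii), so the shaft body cannot leak into the fit.  Collection stops when
the section area exceeds `neck_area_flare` (1.15) times the smallest area
seen — the anatomical neck is the minimal-cross-section corridor, and the
trochanteric junction flares past it.  A TLS line through the centroids,
with residual outliers (> 3× median residual) trimmed once, is refit over
`neck_iterations` + 1 = 3 passes.  For a neck coaxial with the shaft the
offset vanishes and the shaft direction (head-ward) is used directly.

**Landmarks.**  Extreme vertices along an axis break ties by lowest vertex
index (within 1e-6 mm).  Condyle landmarks are the centroids of the
vertices within `condyle_cap_mm` (2 mm) of the posterior extreme of the
medial and lateral distal quarters — averaging suppresses the tessellation
jitter of a single extreme vertex on a smooth condyle.  The greater-
trochanter apex is the most superior vertex that is lateral of the shaft
axis, outside 1.15 head radii of the FHC and more than `neck_exclusion_mm`
(18 mm) from the neck axis; without the neck exclusion, varus necks with
high trochanters present neck-base vertices that out-rank the apex.  The
lesser-trochanter centre starts from vertices in the 75–90 % band whose
radial distance from the shaft axis exceeds the band median by
`protrusion_threshold_mm` (4 mm), on the medial side and away from head
and neck; the most protruding vertex seeds a 12 mm cluster, and the
best-fit sphere centre of the cluster (fallback: its centroid) is
reported — the boss centre, not its surface, is "the centre of the lesser
trochanter".

**Parameters.**  NSA is measured between the 3-D axes (not a frontal
projection; the definition names two axes with no projection wording —
`nsa_mode="frontal_projection"` switches the alternative).  ATA is the
signed angle of the neck direction projected into the transversal plane
against ml, anterior positive; it degenerates (error) within 2° of a
vertical neck.  OSH/NCDF/NCDS project both the point and the line into the
named plane before measuring the 2-D point-to-line distance.  GTH is
positive when the FHC is superior to the trochanter apex, a sign inferred
from the reference cohort's printed range (−7.4 … 21.8, mean +7.4).

**Repeats.**  `measure_femur` averages each scalar parameter over
`repeats` (default 6) runs that re-seed the stochastic stages (the RANSAC
head fit and everything downstream of the head centre); the deterministic
shaft-axis fit is shared.  Per-parameter repeat SDs are reported.  On
noise-free synthetic meshes the repeat spread is a few 1e-3 mm — not
exactly zero, because the ±1 mm inlier band's membership is seed-dependent
at its boundary on a tessellated surface.

## Synthetic data

**Cohorts.**  Parameter vectors are drawn from a latent standard
multivariate normal whose correlation matrix is the reference cohort's
12×12 inter-correlation matrix (repaired to the nearest positive-definite
matrix by eigenvalue clipping at 1e-6 and diagonal rescaling; the matrix
as published is already positive definite, so the repair is a no-op).
Columns are scaled to the reference means and SDs.  NCDF and NCDS are
folded: value = |latent|, with the latent mean solved numerically so the
folded mean hits the target (a folded normal cannot have mean/SD below
~1.32, so for NCDF the target SD of 1.22 is approximated at ~0.97 while
the mean 1.51 is exact).  This reproduces their right-skewed, non-normal
histograms while keeping the other ten columns Gaussian.  Rows violating
hard bounds (NSA, ATA ranges, positive lengths) are rejected and redrawn
with a warning, never clamped; at the default calibration rejections are
essentially absent.

**Meshes.**  A parameter vector is realised as the zero level-set of the
signed-distance union of analytic primitives — a shaft cylinder (straight
by default; an optional circular-arc anterior bow exercises the axis-fit
robustness tests), a neck frustum, the head sphere, a condylar block (two
spheres plus a bridging capsule whose posterior tangent points define the
knee line), and greater/lesser-trochanter bosses — polygonised by marching
cubes at `voxel_mm` = 1.2 (≈ 100 k faces, landmark accuracy well below the
voxel).  Marching cubes on a regular grid makes watertightness structural
rather than something to repair.  Head placement and the neck axis follow
the primary parameters (OSA, OSV, NSA, ATA, FHD, TFL, GTH, NCVD, NCHD):
the FHC is placed at distance OSA from the shaft axis at azimuth ATA and
height TFL − FHD/2, the neck direction comes from NSA/ATA, and the neck
axis is then offset from the FHC by the exact perpendicular vector whose
si/ap components are NCVD/NCHD.  A measured vector is over-determined, so
OSH, NCDF and NCDS are *derived* from the realised geometry
(OSH = OSA·cos ATA, closed forms for the projected neck distances) and
replace the sampled values, with the substitution logged; recovery tests
always compare against the realised ground truth, which the analytic
primitives reproduce to 1e-9.  Fixed structural constants (shaft radius
13.5, condyle radius 22, boss sizes) are anatomy-scale choices that do not
enter the realised parameters.  Optional seeded Gaussian vertex
displacement along normals emulates segmentation roughness.

**What the generator does not emulate.**  Real femurs have anteriorly
bowed, elliptical shafts, a fused head–neck junction without a crisp
frustum, cartilage-smoothed condyles, and CT segmentation artefacts
(holes, steps, leakage).  Passing the recovery suite therefore shows that
the estimators are correct on idealised geometry at realistic parameter
values and robust to tessellation and mild surface noise — not that they
are validated against manual measurements on clinical data.

## Statistics

Descriptives use the n−1 sample SD and the mid-value median.  Pearson
correlations use the product-moment formula; p-values come from
`t = r√((n−2)/(1−r²))` against a t distribution with n−2 df, two-sided,
with significance at α = 0.05 per pair and no multiple-testing correction
by default (a Bonferroni/FDR adjustment is available via
`adjust_pvalues`).  Zero-variance columns are flagged, not fatal.
Normality is assessed by Shapiro–Wilk at α = 0.05 — the reference analysis
judged histograms by eye, so the test choice is this package's own — with
Freedman–Diaconis histogram bins.  At n = 169 the test calls Gaussian
columns normal in ≈ 97 % of seeded runs and half-normal columns non-normal
in ≈ 100 %, which is the calibration the acceptance suite checks.

## Problem sizes and numerical choices

The validation suite measures single femurs at ~100 k faces (voxel 1.2 mm)
in ~1.5 s per repeat and samples calibration cohorts up to n = 1e5; the
end-to-end recovery check uses 20 sampled femurs, and correlation
recovery averages 50 cohorts of n = 169.  Geometry tolerances asserted in
tests: 1e-6 for closed-form oracles, 0.1° for exact-cylinder axis
recovery, ±1 mm / ±2 % / ±2° for mesh-based parameter recovery (the STL
float32 storage floor is ~1e-3 mm).  Degenerate inputs raise typed errors
(empty landmark regions name the landmark; non-spherical heads report the
inlier fraction; infeasible generator vectors name the violated relation).
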