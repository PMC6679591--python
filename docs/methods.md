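# Methods

## Problem setting and model

The input is a gravity-aligned point-cloud map of a forest plot, in metres,
as produced by an IMU-aided SLAM run of a mobile laser scanner. The goal is
a stem table: one row per tree with its position and diameter at breast
height (DBH, the trunk diameter 1.3 m above local ground, reported in cm).

The method rests on three geometric assumptions:

* the ground is, at plot scale, a single near-horizontal surface;
* individual trees are separated by more than the point-to-point spacing on
  any one tree, so fixed-radius connectivity isolates stems;
* a trunk cross-section near breast height is a circle, so the diameter of a
  robustly fitted circle is the DBH.

All coordinates are metres throughout the library; DBH converts to
centimetres only at reporting boundaries (`dbh_cm = 200 × radius_m`).

## Ground: RANSAC plane with a tilt gate

`fit_plane_ransac` draws `max_iterations` 3-point hypotheses, skips
collinear triples and any hypothesis whose normal deviates from vertical by
more than `max_tilt_deg` (default 15°) — without the gate, dense vertical
structure (stems, walls) can out-vote the ground. The consensus-maximal
hypothesis (ties: first found) is refined once by total least squares on its
inliers (centroid + smallest eigenvector of the scatter) and the inlier set
is recomputed once. Fits are deterministic per seed. Normals are
canonicalised to `normal_z > 0`.

Defaults: `dist_threshold` 0.05 m and `max_iterations` 1000, which by the
standard RANSAC trial-count formula gives ≥ 99 % success at 40 % outliers.
The *pipeline* uses a wider fit threshold (0.15 m) so that on undulating
terrain the consensus plane sits at the mean ground level rather than on one
undulation extreme, and a wider removal band (0.25 m ≈ undulation amplitude
+ 3σ noise + margin) so the whole ground surface is captured; the cost is
that the lowest ~0.25 m of each stem is classified ground, which is
irrelevant to slices at ≥ 1.0 m.

Heights above ground come either from the plane (signed distance) or from a
grid DTM: minimum z of the ground cloud per 0.5 m cell, empty cells filled
from the nearest occupied cell, bilinear interpolation between cell centres.
The DTM mode is the pipeline default because a global plane mis-places breast
height on undulating ground. Using the per-cell *minimum* makes the DTM
robust to stem-base points left in the ground class, at the price of a small
downward bias (≈ the noise minimum statistic, ~2 cm at σ = 1 cm), which
shifts slice heights by an amount whose effect on DBH is ≈ taper × 2 cm ≈
0.005 cm — negligible.

## Trees: Euclidean cluster extraction, exactly

Clusters are *defined* as connected components of the ≤ `tolerance`
adjacency graph; size-filtered afterwards. The implementation bins points
into cubic cells of side `tolerance/√3` (cell diagonal = tolerance, so
points sharing a cell are connected for free), then tests only cell pairs
within two cell indices per axis for a linking point pair, with union-find
merging, cheapest-pairs-first ordering and early exit. This is an exact
acceleration: the output equals the O(N²) definition on every input (the
test suite verifies equality against a dense-graph oracle).

Defaults: tolerance 0.5 m (well above stem-surface point spacing, well below
the 2 m minimum stem separation), `min_size` 100. Instances are ordered by
decreasing size with centroid-lexicographic tie-break, so ids are
reproducible.

## DBH: slicing, projection, robust circle

Slices are half-open (`[zmin, zmax)`) so the three standard intervals tile
1.0–1.4 m without double-counting. "Projection onto the lowest plane" is
plain (x, y) extraction — for a gravity-aligned cloud, projection onto any
horizontal plane has identical (x, y); the interval's lower bound merely
labels the plane.

`fit_circle_ransac` samples 3-point circumscribed circles, rejects radii
outside `radius_limits` (default 0.04–0.25 m, i.e. DBH 8–50 cm, a superset
of plausible plot stems), counts inliers within `dist_threshold` (default
0.01 m), and refines the consensus winner by *geometric* least squares
(minimising Σ(‖pᵢ−c‖−r)² over the consensus inliers) — geometric rather
than algebraic refinement because it is unbiased under radial noise. The
inlier set is recomputed once from the refined model; if refinement leaves
the admissible radius band the consensus model is kept. The unrefined
consensus model is retained on the result for inspection. Credibility is
`|inliers| / n` over the slice.

A slice with fewer than `min_points` (default 30) points reports
`too_few_points`; a slice admitting no in-band hypothesis reports
`no_model_in_radius_limits`; neither raises inside `estimate_dbh`.

With no reference data the deployment default interval is 1.0–1.1 m, the
interval that wins selection on real validation data (upper slices collect
branch clutter in real scans); with reference data all three intervals are
computed and the smallest-mean-absolute-error interval is selected (ties:
smaller RMSE, then the lower interval).

## Error statistics

Matching of instances to reference stems is globally greedy nearest-centroid
within 1 m, each side used at most once — a deterministic stand-in for the
implicit matching of a field survey. Mean absolute and mean relative errors
average *absolute* values; variances are sample variances (n−1) of the
absolute quantities, and because the convention for the relative-error
variance is genuinely ambiguous in the field literature, the variance of the
*signed* relative error is reported alongside. RMSE uses the signed errors.
The credibility–error association is Pearson's r (no rank statistic is
implied by a bare "correlation coefficient"). Zero-variance credibility
yields NaN with a warning.

## The synthetic plot

`ForestConfig` defaults emulate the validation plot the method targets:
71 stems on 35 m × 30 m (~130 m perimeter), DBH drawn from a scaled
Beta(a, b) on [11.75, 32.78] cm with concentration 6 chosen so the mean is
20.93 cm and the spread (~4 cm) is realistic for an even-aged stand; stem
centres rejection-sampled with ≥ 2 m spacing and a 1 m edge margin; stems
are tapered cylinders (radius loss 1 %/m of height, 8 m tall) sampled
proportionally to local circumference at 5000 points/m² of surface with
Gaussian *radial* noise (σ = 1 cm) — radial noise makes the distance to the
true axis unbiased, which is what a well-calibrated scanner produces after
SLAM registration. The recorded `dbh_cm` is the exact diameter 1.3 m above
local ground. Terrain is a sum of two low-frequency sinusoids with combined
amplitude 0.15 m, sampled at 800 points/m² — a ground-return density of the
same order as stem-surface density, as a scanner carried at chest height
produces; this also keeps the ground a large enough vote share (~30 %) for
plane consensus. The warning line is a horizontal loop of short dashes at
2 m height around the plot boundary: a thin tape is sampled sparsely by a
moving scanner, dashes near a stem merge into that tree's cluster (and stay
out of the 1.0–1.4 m slices), isolated dashes fall below `min_size`.

Degradation operators: `apply_occlusion` deletes a contiguous azimuthal run
containing a fraction of each stem's points (one-sided scanning);
`jitter_density` thins the whole cloud with an x-periodic keep probability
(platform shake). Both are deterministic per seed, and all generator streams
(placement, DBH, surfaces, ground, clutter) are independent, so changing a
density does not move the stems.

What the simulator does **not** model: branches and canopy, understory
vegetation, multi-return artefacts, registration drift, species-specific
bark roughness, or non-circular stem sections. Consequently the synthetic
errors (~0.2–0.3 cm mean absolute) are smaller than field-validation errors
(~0.4–0.7 cm): passing tests demonstrate the estimator chain is correct and
robust to the modelled error sources, not that field accuracy will match.

A consequence worth stating explicitly: with homogeneous radial noise and an
inlier threshold equal to 1σ, slice credibility is ≈ P(|ε| ≤ σ) ≈ 0.68 for
*every* clean slice, and azimuthal occlusion leaves it essentially unchanged
(measured: it rises by ~0.005, because refining on fewer arc points fits
them slightly better). Credibility flags *contaminated* slices — outliers
from branches or neighbouring objects — not occlusion; on clean synthetic
data its correlation with the error is weak (pooled |r| ≈ 0.12 across ten
plots).

## Numerical choices and edge cases

* RANSAC consensus counting is chunked over hypotheses; on clouds above
  10⁵ points the counting pass runs in float32 for cache efficiency, while
  winners, refinement and final inlier sets always use float64.
* Collinear triples (plane and circle) are detected by a 1e−12 cross-product
  / determinant floor and skipped.
* Circle refinement uses Levenberg–Marquardt warm-started at the consensus
  model, ≥ 3 inliers guaranteed by construction.
* Ties in consensus are broken first-found at fixed seed; cluster ordering
  and instance ids are deterministic; per-interval fit seeds are derived
  from the pipeline seed and the instance id.
* Empty slices, empty clouds, degenerate polygons, grid cells without ground
  points and unmatched trees all take defined non-exception paths (statuses,
  empty results, nearest-cell fallback, unmatched lists).

## Problem sizes used in validation

The bundled tests validate oracle equivalence on instances up to N = 2000
(clustering) and N = 500 (robust fits), and run the full pipeline on five
default 71-stem plots (~2.6 M points each) plus one occluded plot; the
simulator's density defaults were chosen so such a plot generates in about a
second and a full pipeline run completes in tens of seconds.
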