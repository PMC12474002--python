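# Methods

This note documents the models and procedures implemented in `orchard3d`,
the parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Scene model and frames

The target system is a trellised orchard row photographed from one side
with a hand-held RGB-D camera: a single tree fills the foreground
(roughly 1.5 m wide and ~2 m tall in the dormant state), a grass band of
about 0.4 m covers the scene bottom, a horizontal support wire crosses the
row, and clutter (the neighboring row, terrain) sits well behind the tree.

Two frames are used.  *Camera frame*: right-handed, Z = depth away from
the camera, Y = down in the image — the native frame of depth-sensor
clouds and of `render_view`.  *Upright frame*: Y up, Z still the (positive)
depth direction.  `reorient(P, rot_z, rot_y)` applies `R_y·R_z`; a 180°
rotation about Z maps the camera frame to the upright frame, which is the
default in the pipeline configuration.  The rotation angles are
acquisition-rig specific and therefore configurable rather than inferred.

## Synthetic orchard generator

`build_tree` samples points uniformly on the lateral surfaces of straight
cylinders: a vertical trunk (default 2 m × 0.05 m radius) and
`n_branches` (default 30) branches of radius 0.015 m attached between 50%
and 95% of the trunk height, pointing upward at 20–80° elevation, with
lengths 0.3–0.9 m clipped so tips stay inside the 0.75 m lateral row
envelope.  Surface density defaults to 6000 points/m², giving ~14 k tree
points — comparable, after 2 cm voxelization, to what a 640×480 depth
sensor yields at 2–3 m range.  The `prunable_fraction` (default 0.3) of
branches ranked longest-and-most-vertical are flagged prunable: in this
training system the pruner removes the long vertical water shoots, and
that prominence is what a downstream predictor exploits.

`build_scene` adds grass, wire and background.  Grass blade tops sit at
`grass_height · Beta(1, 3)` above the ground plane plus ~1 cm Gaussian
jitter: density decays toward the blade tips as in a real sward, the band
still spans ≈ `grass_height`, and a dominant near-horizontal plane exists
at its base — which is what makes RANSAC plane fitting meaningful.  A
uniform-height band would leave the dominant plane's position arbitrary
within the band.  The wire is a thin jittered line at 0.8 m; background
clutter is a uniform slab 2.5–4 m behind the tree.  Both are "free"
structures: no quantitative field description exists, so their geometry
is chosen qualitatively and they are tagged per point for oracle use.

`render_view` is frustum selection plus Gaussian depth noise (default
σ = 3 mm) and Bernoulli dropout (default 10%); occlusion is deliberately
not simulated, since no pipeline stage reasons about it.  The returned
view keeps its ground-truth pose and the indices of the selected scene
points, so registration accuracy can be scored exactly.

`simulate_pruning` removes every prunable branch.  Removed points closer
than a 5 cm *cut collar* to the retained geometry are dropped from the pre
cloud entirely: a pruning cut leaves the branch collar on the tree, and a
depth sensor cannot resolve the junction region anyway, so the removed
structure is geometrically separated from the survivor.  This keeps the
τ = 0.03 m change-detection ground truth well-posed (a removed point that
sits 1 mm from surviving wood is unlabelable by any distance rule).  The
pre cloud is always an exact partition into surviving and truth-marked
points.

What passing tests on this generator do *not* show: robustness to real
sensor artifacts (quantization bands, edge bleeding, sunlight washout),
to occlusion-induced holes, to wind deformation between views, or to
neighboring-tree interpenetration.  Those effects are the dominant error
sources in the field; the synthetic results are a correctness check of
the algorithms, not a forecast of field accuracy.

## Grass removal

Parameters (meters unless noted): thickness limit 1.5; candidate band
0.6 above the cloud's lowest point; extended band 0.7; plane distance
0.35; angle limit 35°; minimum inliers 30; RANSAC inlier distance 0.02
with 1000 three-point hypotheses.  The 0.6 m band is the measured ~0.4 m
grass height plus margin for camera tilt; the thickness gate encodes that
a lone tree is only ~1.5 m deep, so anything thicker must contain grass
or background.

The iterative segmentation peels the best RANSAC plane off the band,
discards it (but still removes its inliers) when tilted more than 35°
from the vertical axis, and stops when fewer than 30 supporting points
remain.  The plane angle uses |n_y|, making the arbitrary RANSAC normal
sign irrelevant.  The dominant (most-populated) kept plane is taken as
the grass surface; on ties the first-detected plane wins, which is
deterministic under a fixed seed.  RANSAC hypotheses are refit by PCA on
their consensus set before the final inlier count.

If no plane survives the filters, a depth heuristic removes bottom-band
points lying beyond the deepest upper-region point — terrain visible
under the tree but belonging to the background.  Separately,
`cull_background` removes points more than 1.5 m behind the cloud's
nearest point; the nearest point is the anchor because the tree is by
construction the closest structure in these captures.

Points at or above the extended band are never removed, so the canopy is
structurally untouchable; the price is that the lowest ~0.35 m of trunk
can be lost with the grass, which is irrelevant for branch-level work.

## Registration

The downsampling voxel is 0.02 m — the standard compromise for this scene
scale (finer voxels slow the solver and destabilize correspondences;
coarser ones starve it of geometry).  FPFH radii are unstated in any
field protocol and default to 2× voxel (normals) and 5× voxel (features),
standard practice scaled to the resolution.  Normals come from
neighborhood PCA and are oriented away from the cloud centroid — an
orientation rule that is equivariant under rigid motion, which keeps the
descriptors pose-invariant.  A point with no neighbors inside the feature
radius keeps a zero descriptor.

Matching is one-directional: each source descriptor takes its Euclidean
nearest target descriptor.  On sparse self-similar branch geometry most
matches are wrong; robustness is the solver's job, not the matcher's.

The robust estimator minimizes a truncated-least-squares objective with
`noise_bound` 0.02 m (= voxel size) via graduated non-convexity:
closed-form per-pair weights, weighted Kabsch refits, and annealing of
the convexity parameter by `gnc_factor` 1.4 for at most 100 sweeps or
until the weighted cost moves by less than 1e−12; a final plain Kabsch
over the inlier set polishes the pose.  Rotation and translation are
estimated jointly.  When the plain least-squares fit already has every
residual within the bound, the TLS and LS optima coincide and the Kabsch
solution is returned directly — this is why outlier-free inputs reproduce
the Kabsch oracle exactly.  Scale is fixed at 1 (calibrated sensor);
`cbar` scales the inlier threshold and stays at 1.  The solver always
returns a proper rigid transform; with ≥ 30% inliers of ≥ 3 non-collinear
pairs it recovers poses to well under 2° / 0.04 m (measured: median
0.07° / 1.1 mm at 50% outliers, σ = 5 mm noise).

Four views are accumulated sequentially against the first view's frame;
transforms are estimated on the downsampled clouds and applied to the
full-resolution sources, and no deduplication is performed, so the merged
count is exactly the sum of the view counts.  Degenerate weight
configurations during annealing keep the previous estimate rather than
failing.  No automatic success classification is built into the module —
the package reports diagnostics (correspondence count, inlier count, mean
inlier residual) and, in the synthetic pipeline, scores each registration
against the known ground-truth pose (< 2° and < 0.04 m counts as
success); on field data that judgment is the operator's.

## Annotation

τ = 0.03 m, strictly greater-than, on nearest-neighbor distances from the
full-resolution pre model to the aligned post model.  The pre/post
registration reuses the single-pair machinery at voxel 0.02 m.  Labels are
attached to the pre model; the merged overlap cloud is exported separately
with positives painted yellow.  Structures present in only one session
(occlusion holes, moved clutter) become false labels by construction —
that is inherent to change detection and is left to downstream filtering.

## Dataset variants

Ten variants per model: the original; a centered copy rescaled so the
farthest point sits at radius 1 (the normalization convention of
point-based segmentation networks); and eight voxelizations of the
normalized copy at 0.0025–0.02 (units follow the normalized cloud).
Voxel labels are the majority vote of member points with ties resolved to
*pruned* — favoring positives preserves thin pruned branches at coarse
resolutions, where a branch shell shares voxels with empty space more
often than with non-pruned wood.  Point sampling draws exactly `npoints`
indices uniformly **with replacement** regardless of cloud size, so the
draw distribution is identical whether a cloud is up- or down-sampled; a
no-replacement variant exists behind a separate function.  Splits shuffle
the sorted model names with a seeded generator and cut at
floor(0.7 n) / floor(0.1 n) / remainder — 101 models give 70/10/21.

## Evaluation

The positive class is 1 = pruned.  Any 0/0 ratio is defined as 0 so that
averages over many trees (some with no positives) remain finite.
Percentages are computed with exact decimal arithmetic and rounded
half-up to one decimal; half-up (not banker's) is asserted at an exact
.x5 boundary in the tests.

## Determinism and problem sizes

Every stochastic step takes an explicit seed; the pipeline forks one
global seed into per-tree, per-stage seeds via `numpy.random.SeedSequence`
spawn keys, so reruns are bit-identical down to the written PLY/CSV/JSON
bytes (manifests deliberately exclude timing).  The packaged demo
configuration runs three trees at 4000 points/m² and 24 branches — about
a minute per run on one CPU — and the test suite's heavier experiments
use 12–24-branch trees at 1800–4000 points/m²; these sizes were chosen as
the smallest at which every stage still operates in its intended regime
(thousands of downsampled points per view, hundreds of points per
branch).

## Known limitations

* Grass removal assumes the tree is the nearest structure and grass is
  the lowest; elevated captures without visible grass rely solely on the
  thickness gate.
* FPFH on thin cylinders is weakly discriminative; registration succeeds
  through outlier-robustness, and very low-overlap view pairs can still
  fail (the pipeline records such failures per tree rather than hiding
  them).
* Change-detection annotation cannot distinguish pruned wood from
  session-to-session occlusion differences.
* The wire and background generators are qualitative stand-ins; no
  attempt is made to model their field statistics.
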