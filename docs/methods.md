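# Methods

`bonereg` implements and evaluates an expert-supervised rigid registration
workflow for serial imaging of bones (distal femur / proximal tibia scale):
a triangulated bone model built from one image set is positioned in another
image set using sparse, manually placed "attraction points", and the result
is judged against fiducial-based and whole-model reference registrations
with two surface metrics.

## Registration model

### Rigid coherent point drift (CPD)

The moving point set (surface samples of the bone model) is treated as the
centroids of an isotropic Gaussian mixture with shared variance `sigma^2`
and a uniform outlier component of weight `w`; the fixed set (attraction
points) is the observed data. EM alternates:

* E-step: responsibilities `P[m, n] = exp(-||x_n - T(y_m)||^2 / 2 sigma^2)`
  normalised over centroids plus the outlier constant
  `(2 pi sigma^2)^{3/2} w M / ((1 - w) N)`;
* M-step: closed-form rotation from the SVD of the P-weighted
  cross-covariance with a determinant-sign correction (never a reflection),
  translation from the weighted centroids, then the `sigma^2` update. A
  similarity scale can be estimated but is fixed at 1 by default: the same
  physical bone is repositioned between acquisitions, in millimetres.

Direction matters and is a deliberate choice: mesh samples are the MOVING
centroids, attraction points the FIXED data. Attraction points are a sparse
subset of the surface; in this direction every data point finds nearby
centroids and uncovered surface regions simply receive low responsibility,
which is what makes partial-tissue registration work.

Initialisation: `R = I`, centroid-to-centroid translation (skippable via
`pre_align=False` when points cover only part of the tissue and the data
centroid is biased), `sigma^2` from the mean pairwise dispersion.
Convergence: relative `sigma^2` change below 1e-8 or 150 iterations
(library defaults; the study harness uses 1e-6 / 50, see below).
Non-convergence flags the result, it does not raise.

On `sigma^2` monotonicity: EM guarantees that the mixture negative
log-likelihood never increases (exposed via `track_likelihood`, and tested),
but `sigma^2` itself is only empirically non-increasing. On matched
instances (data = transformed copies of the samples, with or without noise)
it decreases monotonically in every run we test; on partial/subset
instances it can wobble upward by a fraction of a percent near convergence
while the likelihood still improves.

### Point-to-surface polish

Sampled-centroid CPD bottoms out at a discretisation floor: once `sigma^2`
collapses below the vertex spacing, each data point locks to its nearest
centroid, and the recovery error saturates at roughly half a degree for a
2000-vertex sampling of a 70 mm bone - regardless of how clean the points
are. Registration routes that know the model surface
(`register_model_to_points`, `register_model_to_model`) therefore finish
with a short point-to-plane Gauss-Newton stage against exact
closest-points-on-triangles of the continuous surface (at most 30
iterations, stopping when the pose increment falls below 1e-12). With
noiseless points on a displaced copy this recovers the transform to machine
precision; with noisy points the estimate approaches the least-squares
optimum of the continuous surface fit, scaling as `noise / sqrt(n)`. CPD
supplies the robust wide-basin alignment, the polish the final accuracy.

### Gold standards

* Fiducial (gold): corresponding-point least squares (Kabsch) over matched
  marker pairs, SVD with determinant correction; exact on noiseless pairs.
* Whole-model (substitution gold): CPD plus polish between farthest-point
  samples of the two full models. Note that this route quasi-minimises the
  reported surface distance itself, so on synthetic data its MAD can sit a
  few thousandths of a millimetre below the true-pose (fiducial) MAD; the
  two are equivalent at the 0.01 mm reporting precision.

## Metrics

* MAD (mm): symmetric mean absolute surface distance. Area-weighted seeded
  samples of each surface (10 000 per surface by default) are measured
  against the other surface with exact point-to-nearest-triangle distances
  (KD-tree pruned with a circumradius bound that preserves exactness); the
  two directional means are averaged. The same seed drives both directions,
  so the metric is exactly symmetric in its arguments.
* Dice: both closed meshes are voxelised on one shared isotropic grid
  covering the padded union bounding box (0.5 mm voxels, 2-voxel padding by
  default - commensurate with clinical knee CT/MRI voxels of 0.3-0.5 mm);
  `2|A&B| / (|A| + |B|)`. A voxel belongs to a mesh iff its center is
  inside, decided by x-ray column parity with a deterministic micro-jitter
  re-test for rays that graze an edge/vertex or centers that sit on a
  crossing, so axis-aligned grids stay deterministic.

## Contour lofting

Segmentations are per-slice closed B-splines (uniform periodic knots, cubic
by default; open contours use clamped uniform knots). Lofting resamples
every contour to a common count at approximately arc-length-uniform
spacing, removes the cyclic offset between consecutive rings that minimises
the summed squared distances (twist prevention), stitches with alternating
triangle pairs, and caps the ends with centroid fans; winding is corrected
so the enclosed volume is positive. Branching anatomy (two contours on one
slice) is out of scope and rejected. The upstream contouring literature
does not print knot or meshing conventions; these are package choices.

## Synthetic study conditions

The original imaging data are unavailable, so evaluation runs on generated
cases with known ground truth:

* Bone-like meshes: radial deformations of an icosphere (star-shaped by
  construction, hence always closed/manifold): a tapered shaft with two
  condylar lobes ("femur", ~70 mm), a shaft with widened flattened plateau
  ("tibia"), and plain ellipsoids for analytic checks; plus a seeded smooth
  radial modulation (RMS 1.5% of size) for inter-case variety.
* Repositioning between acquisitions: rotation uniform up to 15 degrees
  about a random axis and translation up to 20 mm - repositioning-scale
  motion; the source study does not report its distribution.
* Interoperator segmentation difference: vertices of the target-frame model
  displaced along normals by a smooth correlated field (64 surface-anchored
  Gaussian kernels), RMS 0.3 mm with 10 mm correlation length, sized so the
  gold-standard MAD floor lands near the interoperator floor reported for
  real CT segmentations (~0.3-0.4 mm) - a calibration choice, not a
  measured fact. The field's best-fit infinitesimal rigid component
  (area-weighted) is projected out: both operators contour the same image,
  so segmentations cannot disagree by a net pose.
* Operator point placement: area-weighted uniform surface samples displaced
  by isotropic Gaussian localisation noise, 0.3 mm in the same-protocol
  (CT-CT) regime and 0.6 mm plus a 0.2 mm signed normal bias in the
  cross-modality regime - bracketing the 0.3-0.5 mm voxel sizes of the
  emulated acquisitions; real operator error is not quantified in the
  source study. A `partial` region option restricts placement to the distal
  40% of the surface area.
* Five fiducials per bone, placed strictly inside (radial 0.55 shrink of
  farthest-point-sampled vertices, verified by a point-in-mesh test) and
  mapped exactly by the true transform.

What the generator does NOT emulate: real image intensities and
segmentation algorithms, operator-specific systematic styles, anatomy
beyond a smooth genus-0 approximation, joint-level multi-bone constraints.
Passing tests therefore demonstrate correctness and qualitative behaviour
of the method (error vs point count, method ordering, floors set by
segmentation disagreement), not clinical-accuracy claims on real knees.

## Study designs

* Point-count study: per case, 10 registrations at each of 32, 64, 128,
  256, 512, 1024 randomly subsampled attraction points; 10 cases per bone
  kind gives 600 records per kind. Consecutive counts are compared with
  two-sided Wilcoxon rank-sum tests, Bonferroni-corrected within each
  bone-and-metric family (family size 5); because repeats cluster within
  cases, p-values are reported both pooled and on per-case medians.
* Method comparison: expert-supervised at 128 points (the plateau onset,
  matching the source protocol's ideal count) vs fiducial gold standard vs
  substitution gold standard, paired per case, Wilcoxon signed-rank tests
  against the gold baseline. The cross-modality variant drops the fiducial
  method and uses the higher-noise operator regime.
* Summaries are median (Q1, Q3) with linear-interpolation quartiles, stated
  in the output metadata.

Statistical wrappers follow the classical conventions: rank-sum exact by
enumeration when the combined sample is at most 20 without ties, otherwise
a tie-corrected normal approximation without continuity correction (so
identical samples give p = 1 exactly); signed-rank drops zero differences,
exact up to 15 untied magnitudes.

## Problem sizes and numerical choices

Study harness defaults (chosen as the package's standard desk-scale
configuration): coarse bone meshes (icosphere subdivision 3, 1280 faces),
500 CPD centroids, CPD tolerance 1e-6 with at most 50 iterations (the
polish stage sets final accuracy), 1500 MAD samples per surface and 1 mm
Dice voxels per record. Standalone metric calls default to 10 000 samples
and 0.5 mm voxels. Whole-study runs are bit-reproducible from a single
master seed via hierarchical `SeedSequence` derivation.

Degenerate inputs: collinear point sets, fewer than 4 attraction points or
3 fiducial pairs, open meshes for volumetric operations, non-monotone
contour stacks, and oversized perturbation amplitudes (enclosed-volume
change beyond 20%) are rejected with specific errors. Farthest-point
sampling breaks distance ties toward the lowest vertex index;
registration failures inside a study are flagged rows, not aborts.

## Known limitations

* Rotation about a bone's near-cylindrical shaft axis is a soft mode:
  tangential sliding costs little surface distance, so pose errors around
  that axis (a degree or so under 0.3 mm correlated segmentation noise) are
  larger than MAD/Dice alone suggest. Fiducials do not share this blind
  spot, which is exactly why the fiducial route is the gold standard.
* The substitution gold standard optimises the evaluation metric itself;
  its MAD is a hair optimistic relative to the true pose (see above).
* Lofting assumes one closed contour per slice; condylar branches must be
  modelled as separate stacks.
* `sigma^2` is reported per iteration for diagnostics but is not a
  guaranteed-monotone quantity (the likelihood is).
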