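# Methods

`mvquant` implements the non-learned computational core of a 4D
transesophageal-echo (TEE) mitral-valve assessment pipeline: it turns
labelled valve volumes (anterior leaflet = 1, posterior leaflet = 2,
annulus = 3) into calibrated geometric measurements, and provides the
segmentation objectives and metrics a trainer would plug a network into.
This note records the models, the numerical choices, and what the synthetic
phantom does and does not establish.

## Annulus reconstruction from sparse control points

A clinician marks a handful of points along the mitral annulus in 3D; the
reconstruction is:

1. **B-spline fit** (`scipy.interpolate.splprep`, cubic, smoothing 0), so
   the curve interpolates every control point. The annulus is fitted as a
   *closed periodic* curve by default — anatomically it is a ring — with an
   open mode for partial traces. Duplicate consecutive points and counts
   below 4 are rejected; configurations scipy itself cannot fit raise a
   fit error.
2. **Dense sampling** at 100 equally spaced parameter values.
3. **Tube voxelization**, radius 1.5 mm: a voxel belongs to the tube iff
   its center is within the radius of the sampled polyline, computed by
   exact point-to-segment distance. This is grid-independent and monotone
   in the radius; rasterization-stencil approaches are an implementation
   detail we deliberately avoid. A radius below half the voxel spacing
   triggers a disconnection warning.
4. **Component post-processing**: among 26-connected components with at
   least 25% of the largest component's voxels, keep the one with the
   highest mean world z (the atrial side in our convention); everything
   else is treated as spurious. The size gate prevents a high speck from
   displacing the real ring; both candidates are logged.

Where the tube overlaps existing leaflet labels, the leaflets win: they
are the thin structures of interest, while the tube radius is a modelling
artifact.

## Per-frame valve geometry

For each frame: the annulus label is skeletonized by 3D morphological
thinning (`skimage.morphology.skeletonize`); skeleton voxels are ordered by
a nearest-neighbour walk that starts at the point with minimal first world
coordinate (ties: second, then third coordinate, then lowest voxel index)
and refuses steps that reverse the previous direction (dot product < 0);
when no forward candidate exists the nearest point is taken and a backtrack
event is logged. The path is closed when the endpoint returns to within
twice the median step of the start.

The valve plane is the PCA plane of the ordered points: centroid = mean,
normal = eigenvector with the smallest covariance eigenvalue; the in-plane
basis spans the two leading eigenvectors as a right-handed triad. The
normal is flipped so the leaflet centroid lies on its negative
(ventricular) side, making signed quantities reproducible. Collinear point
sets (second eigenvalue ≈ 0) are rejected.

### Projection and area calibration

Labelled voxel centers are projected orthogonally onto the plane and
rasterized. The raster axes are aligned with the projections of the two
grid axes least parallel to the normal, and the default pixel size along
each raster axis is 1.1× the pitch of the projected voxel lattice along
that axis. Rationale:

* at pixel ≈ pitch, projected voxel centers map essentially one-to-one
  onto pixels, so pixel-count areas (count × pixel area) are unbiased at
  any obliquity — this is the "pixel sizes adjusted for the projection
  angle" calibration, realized exactly;
* the 10% head-room guarantees consecutive centers can never skip a
  pixel, which removes moiré aliasing between the lattice and the raster
  (without it, sub-degree plane-fit noise modulated per-structure areas by
  ±8%);
* supersampled rasters with voxel-*footprint* splatting were measured to
  bias areas by up to 25% at 30° tilt (a cube's silhouette exceeds its
  cross-section) and are not used for areas.

An explicit pixel size overrides both pitches with an isotropic value; if
it is finer than the voxel spacing, each voxel body is sampled with a
sub-grid so thin sheets stay hole-free.

### Effective orifice area (EA)

The projected annulus ring bounds the search region. If the ring does not
already enclose a region it is morphologically closed with a disc of
radius 3× the tube radius (logged); a ring that still encloses nothing
raises an open-ring error carrying a gap estimate. The flood fill grows
4-connected from the ring centroid (relocated to the nearest free pixel if
it lands on a structure) over pixels not occupied by any structure, and
EA = filled pixels × pixel area. A fully obstructed orifice yields 0.

Inside the frame pipeline the EA raster uses half the minimum voxel
spacing (with voxel-body supersampling): the orifice boundary is an *edge*
measurement, and at 0.5 mm voxels a 2 mm orifice radius needs sub-voxel
edge resolution to stay within a few percent. Coverage holes in the
structures do not leak because only the seed's 4-connected component is
counted. Structure areas are always reported from the pitch-calibrated
raster.

## Temporal analysis and validation

The EA curve runs the frame pipeline over a sequence; frames that fail
(missing annulus, uncloseable ring) become logged gaps, not crashes. The
maximum-opening (mid-diastolic) frame is the argmax of EA, ties resolved
to the earliest frame. Frames are treated as uniformly spaced in index;
timestamps, when present in the source, can be joined downstream.

`compare_measurements` implements the paired-validation statistics:
Pearson correlation (scipy) and Bland–Altman mean difference with 95%
limits of agreement (mean ± 1.96 × sample SD of predicted − reference),
optionally stratified at the median of the pair means. Series with zero
variance raise an undefined-correlation error rather than returning NaN.

## Segmentation objectives

Plain-numpy implementations on (C, H, W) arrays, C = 11 (six scallops
a1–a3/p1–p3, chordae, annulus, two papillary muscles, background):

* generalized Dice loss averaged over the set C′ of classes *present* in
  the ground truth: `1 − (1/|C′|) Σ_c (2Σ p·g + ε)/(Σp + Σg + ε)`,
  ε = 1e-6;
* focal loss over *all* classes, focusing parameter γ = 2, probabilities
  clipped at 1e-7 before the log; γ = 0 reduces exactly to mean
  cross-entropy;
* combined objective = arithmetic mean of the two;
* deep supervision: combined loss at the output scale plus, unweighted, at
  each auxiliary scale, each against a nearest-neighbour-downsampled
  ground truth (source index = floor(output index × scale); the result is
  strictly one-hot at every scale). A 256 input with factors 2/4/8 gives
  the 128/64/32 auxiliary pyramid.

Evaluation metrics per class: Dice, precision, recall, false-positive
rate from the binarized confusion matrix. Conventions for degenerate
cases: empty-vs-empty Dice = 1; empty denominators give 0 with an
`undefined` flag so aggregation can treat absent structures explicitly.
The `eval-seg` command reports per-image mean ± SD per class.

## The synthetic phantom

The phantom provides analytic ground truth for every stage: annulus ring =
tube of radius 1.5 mm around the saddle curve
(R cos φ, R sin φ, h cos 2φ) — the cos 2φ modulation gives the textbook
two-high/two-low saddle; two leaflet sheets (1 mm thick by default) span
from the ring inward to a frame-dependent orifice radius following the
cosine opening schedule r(k) = r_min + (r_max − r_min)(1 − cos 2πk/n)/2,
so EA(k) = π r(k)² in closed form and the peak falls at mid-cycle. The
whole object can be rigidly tilted relative to the grid. Defaults: R = 14
mm, saddle 2 mm, orifice 2→10 mm over 16 frames, 96³ grid at 0.5 mm —
a normal-sized adult mitral valve at clinical 4D-TEE resolution.

Two deliberate modelling choices:

* **Leaflet droop.** The leaflet surface is offset below the annular
  saddle by a linearly increasing droop (tube radius + thickness at the
  ring). This mimics ventricular leaflet billowing and keeps the sheets
  clear of the tube label; without it the annulus label swallows the
  attachment band and the projected leaflet area loses ~24% of the
  analytic annular band π(R² − r²).
* **Label precedence.** Where the tube and a sheet touch, the annulus
  label wins in the phantom (the ring must stay closed for
  skeletonization); in reconstruction the opposite precedence applies, as
  described above.

What the phantom does *not* emulate: speckle and B-mode texture,
segmentation errors, dropout, regurgitant jets, prolapse/flail
morphologies, non-circular orifices, annular motion within a frame.
Passing the phantom checks therefore establishes the correctness and
calibration of the geometry code, not robustness to imperfect upstream
segmentations.

## Study sizes and tolerances

The shipped checks use: the 16-frame default phantom (EA recovered within
7% per frame; measured ≤ 5.1%); 10 randomized phantoms (R ∈ [10, 14] mm,
r_min ∈ [1.5, 3], r_max ∈ [0.55R, 0.7R], saddle ∈ [0, 2] mm, tilt ∈
[0°, 25°], 4 frames each) for the recovered-vs-analytic EA correlation
(r ≥ 0.99; measured ≈ 0.9997); annulus reconstruction at 0.4 mm spacing
(Dice ≥ 0.8; measured ≈ 0.996); rotation invariance at 30° (areas and EA
within 5%; measured ≤ 4.5%). These sizes keep a full run on one CPU in a
few minutes while leaving every tolerance comfortably exercised.

## Known limitations

* The centerline ordering is greedy; pathological skeletons (touching
  rings, large spurs) can produce logged backtracks and an open path. The
  PCA plane is permutation-invariant, so measurements degrade gracefully.
* The open-ring gap estimate is only available when the ring fragments
  into multiple components; a single open arc reports NaN.
* Coordinate conventions (RAS/LPS) are carried as tags, not converted;
  mixing conventions between markups and volumes is the caller's
  responsibility (`--coords` overrides the tag).
* DICOM ingestion is out of scope; NIfTI and NRRD are the supported
  volume formats.
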