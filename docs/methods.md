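# Methods

This note records the models, parameter choices and numerical decisions behind
`fasc3d`, and what the synthetic phantoms do and do not establish about real
histology.

## Problem setting

Serial histological cross-sections of peripheral nerve are thin (5 μm) and far
apart (250 μm), so a block of 9–17 sections observes ~2% of the tissue; the
rest must be interpolated. Sections are acquired independently, so each slice
carries an arbitrary rigid/affine placement on its slide. Fascicles appear as
roughly elliptical profiles that wander, branch and merge along the nerve.
H&E staining gives low fascicle/epineurium contrast; anti-neurofilament IHC
stains fascicles dark on a light ground.

## Preprocessing

H&E slices pass through five stages; IHC slices are only converted to
grayscale (BT.601 luma).

* **Edge-gated local contrast** (`edge_threshold` 0.3, `enhancement` 0.6).
  Detail is the residual of a Gaussian blur (σ = 16 px), amplified by
  `enhancement` under a soft gate built from pixels whose Sobel gradient
  exceeds `edge_threshold` × the image maximum (gate smoothed with σ = 8 px,
  normalized to peak 1). The detail and gate scales are deliberately
  comparable to the smallest supported fascicle diameter (14 px): thinner
  boundary overshoots would be removed again by the morphological stage below,
  leaving no net contrast gain.
* **Unsharp sharpening**: `img + amount·(img − gaussian(img, σ=1))`, per
  channel.
* **Perona–Malik anisotropic diffusion**: 5 iterations, exponential conduction
  `g = exp(−(|∇|/κ)²)`, κ = 0.1 (10% of the unit intensity range — a standard
  choice; exposed in `PreprocessParams`), 4-neighbour conservative scheme with
  Neumann boundaries and time step 0.2. The scheme preserves the global mean
  and never increases variance.
* **Opening- and closing-by-reconstruction** with a disk of radius 7 px:
  removes structures thinner than the disk while preserving the contours of
  anything at least 14 px across. This radius is the origin of the package's
  minimum fascicle size.

Whether sharpening precedes or follows the contrast boost is essentially
interchangeable; the implemented order is contrast → sharpen → gray →
diffusion → morphology.

## Registration

Pairwise, consecutive slices, on preprocessed images; mean-squares metric
(both images share a stain, so mono-modal), SimpleITK gradient descent with
per-iteration learning-rate estimation, 20% random metric sampling (seeded;
the "stochastic" in SGD), 100 iterations per step. Four steps with nested
transform families — translation @25%, rigid @50%, similarity @75% (H&E) or
@100% (IHC), full affine @100% — each seeded exactly from the previous step's
transform (nesting makes the decomposition exact). Down-sampled images carry
spacing 1/scale so all parameters live in full-resolution pixel units.

Two robustness details:

* **Rigid multi-start.** With near-symmetric fascicle layouts, rotations of
  around ±10° can fall into a wrong-sign local minimum (a mirrored blob
  correspondence that still lowers the metric). The rigid step therefore
  starts from candidate angles {−10, −5, 0, 5, 10}° and keeps the converged
  result with the lowest full-image metric. This is deterministic and costs
  under a second per pair.
* **Background fill.** Resampling exposes out-of-domain regions; they are
  filled with the median of the image's border ring (width 2% of the minimum
  dimension), never with black, so they cannot attract the next registration.

Per-slice transforms to the block reference (slice 0) are compositions of the
pairwise transforms; each slice is resampled once from its original through
the composed transform, avoiding accumulated interpolation blur. Quality is
MSE on the 0–255 intensity scale (so deltas are magnitude-comparable across
images) and SSIM with standard constants, both computed on full-resolution
preprocessed grayscale images.

A caveat the evaluation harness makes visible: content-based registration
aligns *fascicles*, so if the anatomy itself drifts along z the recovered
transforms legitimately differ from the slide-placement transforms — the
reconstruction is "straightened". Parameter-recovery statements therefore hold
for frame perturbations of fixed anatomy; with wandering anatomy the relevant
measure is reconstruction IOU, not transform error.

## Detection

The built-in detector is the phase-coded circle Hough transform. Edge pixels
(gradient magnitude ≥ 10% of maximum) vote along their gradient direction —
inward for dark-on-light objects — at every candidate radius, with complex
weight `exp(i·φ(r)) / (2πr)` where `φ(r)` maps radius log-linearly onto
[0, 2π). All radii share one 2D complex accumulator; the 1/(2πr)
normalization makes a clean full circle peak at ≈ 1 regardless of size.
After a σ = 1 Gaussian consolidation, peaks above `1 − sensitivity`
(sensitivity default 0.88) become detections; the radius is decoded from the
accumulator phase at the peak. Side lobes around strong circles are removed
by two suppression rules: box IOU > `max_overlap` against a stronger kept
detection, and center-inside-a-kept-circle. Each circle is reported as its
tight bounding box with the clipped peak strength as score.

Scoring: greedy matching in descending IOU (ties: higher score, then
row-major origin), each ground-truth box used at most once, true positive at
IOU ≥ 0.5; precision/recall are defined as 0 when their denominator is 0.
Neural detectors integrate through the `external` method, which reads the
boxes-JSON schema; training such a detector is out of scope.

## Segmentation

**H&E.** Detection boxes become filled ellipses centered on the box with
semi-axes `(w/2, h/2) × init_margin` (margin 1.1, so conservative boxes never
clip tissue). The slice is re-preprocessed with the registration chain, the
exterior of the ellipses is replaced by the background estimate, and a
morphological Chan–Vese contour evolves from the ellipse union. Each sweep
applies region competition between interior mean c₁ and exterior mean c₂ with
an inward bias:

    shrink where (I − c₁)² + b ≥ (I − c₂)²,  b = contraction_bias · max((c₁−c₂)², 4·10⁻⁴)

followed by `round(2 · smooth_factor)` alternating sup-inf/inf-sup curvature
passes. Scaling the bias by the squared class separation makes
"contraction bias 0.5" mean the same thing at any image contrast; the small
floor keeps the contour contracting (rather than stalling on floating-point
ties) in featureless regions, which is what makes an empty box collapse to an
empty mask. Evolution stops when the relative mask change stays below 10⁻³
for 5 consecutive sweeps, or at 500 iterations. The result is clipped to the
initial ellipses, so the outside-in contract `pred ⊆ init` holds by
construction.

**IHC.** A 256-bin Otsu threshold (between-class variance maximizer, ties to
the lowest level; implemented at the histogram level with an exhaustive-search
oracle in the tests), dark side as foreground (configurable), closing with a
disk of radius 3, interior hole filling. Comparators: whole-slice Otsu and
whole-slice intensity K-means (k = 2, scikit-learn, seed 0, lowest-mean
cluster as foreground). Comparators run on whole slices, not inside detection
circles.

## Reconstruction

Order of operations: in-plane downscale → hole fixing → per-slice watershed
splitting → pairwise interpolation → 3D labeling.

* **Downscale** 0.25 (nearest-neighbour on masks). Working at reduced
  resolution keeps volumes tractable; all IOU comparisons happen on matching
  grids.
* **Hole fixing** operates on per-pixel z-columns: any run of background
  bounded by foreground above and below (any gap length) is filled; leading
  and trailing runs are untouched. This is deliberately per-pixel, not
  per-object — object tracking would require a correspondence model the data
  does not support. The operation is idempotent and monotone.
* **Watershed splitting** of each slice: Euclidean distance transform,
  σ = 1 smoothing, h-maxima (h = 1) markers, watershed on the negated
  distance constrained to the mask. Components larger than 2× the 97.5th
  percentile of first-pass areas are eroded (disk radius 3) and
  re-watershedded — a second pass that is rarely needed but catches deep
  merges. Finally every original foreground pixel takes its nearest label
  ("dilate-back"), so the union of labels equals the input mask exactly.
  Inside `reconstruct_block` the one-pixel boundary between adjacent labels
  is cleared before stacking so split fascicles remain separate objects in 3D.
* **Shape interpolation**: signed distance maps `d = EDT(outside) −
  EDT(inside)` (an empty mask maps to a uniform large positive field);
  intermediate k of n is `{(1−t)·d_a + t·d_b < 0}`, t = k/(n+1). At t = 0 and
  t = 1 this reproduces the inputs exactly under the inside-negative
  convention. Overlapping cross-sections morph smoothly; disjoint ones shrink
  to extinction instead of bridging. `n_intermediate` defaults to 4 — the
  physical thickness/spacing ratio would be 50, but 4 interpolated layers at
  downscale 0.25 give a voxel aspect (z/xy) of 50/16 ≈ 3, a reasonable
  compromise that is configurable.
* **Labeling**: 26-connected 3D components of the stitched stack; identities
  follow branches and merges. Per-slice watershed (rather than a 3D
  watershed) was chosen because splitting is a 2D phenomenon of merged
  cross-sections; hole fixing runs first so splitting sees completed shapes.
* **Extrusion baseline**: the first slice's labeled mask replicated across
  the full output grid — exact for prismatic anatomy, blind to branching.

## Evaluation

The gold standard is the reconstruction built from manual registration +
manual segmentation (with phantoms: the generator's truth). The matrix
compares fully automatic, MRAS, ARMS and EX models to it by 3D IOU of
binarized foregrounds (a single number per model, insensitive to label
numbering), optionally resampling in-plane by nearest neighbour. A per-layer
IOU profile is attached as a diagnostic **extension of this package**: a
depressed but z-uniform profile indicates a global displacement of the whole
fascicle group (a registration frame issue) rather than reconstruction
failure.

IOU conventions: two empty masks score 1.0, empty vs non-empty 0.0 — this
keeps per-slice aggregation NaN-free. Boxes are 0-based, half-open; all JSON
artifacts carry an explicit convention field.

## Synthetic phantoms

The generator emulates the data geometry the pipeline targets: 512² slices
(12 per block by default), 5 μm thickness / 250 μm spacing, several
non-overlapping elliptical fascicle tubes (radius ≥ 7 px, aspect ≤ 1.4) whose
centers follow a bounded random walk, branch events that split a tube into
two children which coincide at the branch slice and separate linearly,
IHC-like rendering (fascicles 0.2, ground 0.9) or HE-like rendering (0.55 vs
0.7 plus σ = 4 px smooth texture of amplitude 0.04, pink-tinted RGB), i.i.d.
Gaussian pixel noise (default SD 0.02), per-slice uniform random affine
misalignment with the true transforms recorded (slice 0 is the unperturbed
reference, so the automatic and original frames coincide), and slice-level
fascicle dropout. All along-z shape variation scales with `centerline_wander`,
so a zero-wander spec produces exactly prismatic tubes. The dense truth
volume is rendered analytically on the reconstruction output grid, so model
comparisons need no resampling.

Dropout is treated as an *observation* failure: dropped fascicles are absent
from the rendering, per-slice masks and boxes, but present in the anatomical
truth volume — recovering them is precisely what hole fixing is for.

**What phantom results do not show.** The appearance model is two intensity
levels plus noise/texture: no stain variability, vascular structures,
processing artifacts, tissue deformation or non-affine warping. Detection and
segmentation scores on phantoms are therefore upper bounds on real-data
behaviour; the pipeline-logic claims (metric correctness, parameter recovery,
interpolation geometry, hole-fixing/watershed behaviour, the ordering of the
evaluation matrix) are the transferable results. On real H&E histology the
classical circle detector is known to be much weaker than a trained detector
— which is why the detector interface is pluggable.

## Problem sizes

The test suite and acceptance script use 256–512 px slices, blocks of 2–12
slices, 20 registration pairs, and reconstruction at downscale 0.25 with 4
intermediate layers; the whole suite runs in under two minutes on one CPU and
the acceptance script in about one.

## Known limitations

Chained pairwise registration accumulates stochastic sampling jitter
(~0.3 px per pair); groupwise registration would remove this but is out of
scope. Non-linear registration, cross-block stitching, surface meshing and
semantic-segmentation detectors are likewise out of scope. Fascicles below
14 px in diameter are outside the design envelope of both the morphological
preprocessing and the detector defaults.
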