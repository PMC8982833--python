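# Methods

## Problem and data model

The package targets pulmonary tumor segmentation from thoracic CT when
voxel-wise ("strong") annotations are scarce but per-slice axial bounding
boxes ("weak") are plentiful. All volumes are carried as `VolumeGrid`
objects: a 3D array with voxel spacing (mm), origin, and a fixed internal
axis convention — right-handed, third array axis axial — to which NIfTI
input is reoriented (closest-canonical RAS) on load. Indexing is 0-based;
box bounds are inclusive on both ends; masks binarize on load with a
`> 0` threshold, since tumor-vs-background is the only label dichotomy.

A weak annotation is the set of tight 2D boxes around each in-slice
4-connected foreground component, one box per component rather than one
per slice, so multifocal or concave lesions are not inflated into a
single cover box. Note one consequence: rasterizing boxes and re-deriving
them is the identity only while per-slice boxes of distinct components
stay disjoint; overlapping boxes merge into their cover box. Tumor-like
annotations satisfy the disjointness premise; adversarial voxel noise
need not.

## Preprocessing

Pipeline order is clip → z-score → resample → crop.

- **Clip** to [−1024, 1000] HU.
- **Z-score** per volume (population statistics over all voxels,
  `ε = 1e−8` std guard). Per-volume rather than dataset-global statistics
  are the dominant CT convention and need no dataset pass. A `normalized`
  flag on the grid makes double normalization an error.
- **Resample** to 1 × 1 × 1.5 mm (trilinear for images, nearest-neighbour
  for labels, origin preserved; output shape `round(shape·spacing/target)`).
  Label grids never pass through an interpolation that could produce
  non-binary values.
- **Teacher crop**: a fixed patch (full scale 128³; desk scale 32³)
  centred on the area-weighted centroid of the rasterized weak
  annotation — the only tumor locator available in the weak regime. Near
  borders the window shifts inward; only when the volume is smaller than
  the patch is it padded, with the normalized value of the clip floor
  (z-scored −1024), i.e. air.
- **Student crop**: the volume is split into two crops, one per lung,
  from the two largest 26-connected lung-mask components: bounding box
  plus margin (default 8 voxels; desk scale 4), clamped to the grid, each
  axis rounded up to a multiple of 2^levels = 16 so the student's
  downsampling path divides evenly. Crop records allow stitching
  predictions back; overlap conflicts resolve by logical OR.

Lung masks are an input (produced externally, e.g. by the `lungmask`
tool, or by the phantom generator); the package does not segment lungs.

## Architectures

Three U-Net variants share one block vocabulary: two 3×3×3 convolutions
per level, each followed by instance normalization and PReLU; stride-2
3×3×3 convolutions for downsampling (no pooling); stride-2 2×2×2
transposed convolutions for upsampling; skip connections by channel
concatenation; 1×1×1 convolution + sigmoid per output head. Channel
widths double per level from `base_width` (16 at full scale; 2–4 in
tests). Instance rather than batch normalization because the physical
batch is one, which makes batch statistics degenerate; no affine terms,
since the adjacent PReLU slopes and convolution biases absorb scale and
shift.

- **Guided teacher** — 3 downsamplings, 2 input channels (image +
  guidance), one head; 128³ → 16³ at the bottleneck.
- **SO student** — 4 downsamplings, image-only input, one head.
- **DO student** — the SO student plus a second decoder branch sharing
  the encoder *and* its skip connections, whose head regresses the
  axial-box rasterization of the target mask; losses weighted 1:1. The
  branch exists to sharpen localization.

Guidance enters as a second input channel: either the filled box
rasterization (`box`) or one centroid voxel per 26-connected component
(`point`). The point encoding is deliberately minimal so box-vs-point is
a pure information-content comparison.

The implementation runs on `thoraseg.autograd`, a reverse-mode autodiff
engine written for exactly these operations. Convolutions are computed as
k³ shifted GEMMs over the padded input (contiguous memory traffic rather
than an im2col transpose); every backward pass is verified against
central finite differences in the test suite.

## Training scheme

Phase 1 trains the teacher on the strong set: per case, derive the weak
annotation from the strong label, rasterize it as the guidance channel,
predict, take the Dice loss against the strong label. Phase 2 applies
the teacher to each weak case (patch centred on the box centroid,
binarize at 0.5, place back into the full grid, resample to the original
grid); cases with no boxes cannot be located and are skipped with a
warning. Pseudo-masks are *not* clipped to the guidance boxes: the
teacher may legitimately correct sloppy boxes. Phase 3 trains the
student on the union of strong and pseudo-strong cases, per lung half;
with the pseudo set empty the identical code path is the supervised
baseline.

Optimization: Adam (lr 1e−4 full scale), physical batch 1 with gradients
averaged over a virtual batch of 8 — averaging rather than summing keeps
the effective learning rate independent of the accumulation count.
Dice-loss smoothing ε = 1e−5. Up to 350 epochs at full scale; the
checkpoint with the lowest validation loss (mean Dice loss over
validation cases) is kept. Any non-finite loss aborts with a diagnostic.

Sampling: tumor volumes are binned into quartiles of the training
distribution and each case replicated ⌈max_bin/own_bin⌉ times, so rare
sizes are upsampled to within one replication unit of the largest bin.
Volume rather than diameter was chosen as the binning statistic. Splits
are patient-level: 15 % of patients to test, 15 % of the remainder to
validation (the within-remainder ratio is a package default), all scans
of a patient co-assigned, reproducible by seed.

## Evaluation

- **DSC** = 100 · 2|P∩G| / (|P|+|G|); 100 when both masks are empty, and
  a case with an empty prediction against a non-empty truth scores 0 and
  stays in the aggregate.
- **Object matching**: 26-connected components on both sides; a GT
  object is detected iff ≥ 25 % of *its own* volume is covered by the
  prediction, a predicted object is a true positive iff ≥ 25 % of its
  volume lies on the truth (the ≥ is inclusive). Per-side normalization
  keeps recall and precision duals; τ is configurable, and both are
  non-increasing in τ.
- **DSC-TP**: DSC restricted to the union of detected GT objects vs the
  union of TP predicted objects — segmentation quality decoupled from
  detection failures; undefined (and excluded from aggregates) when
  nothing was detected.
- **Tumor size**: volume from the voxel count; diameter as the mean of
  the longest and shortest diameter on the axial slice of maximal
  in-plane area — longest = max pairwise distance between voxel centres
  in world space, shortest = minimal width of the point cloud over
  in-plane directions (rotating-calipers). The minimal-width reading was
  chosen because it reproduces the clinical intuition on elongated
  lesions (a 20×10 rectangle reads ~long diagonal, short side), whereas
  "extent perpendicular to the longest diameter" would exceed the short
  side.

`segment_case` chains the whole inference path — clip, z-score,
resample, per-lung crops, per-half prediction, 0.5 binarization,
stitching, nearest-neighbour resampling back — returning a mask aligned
with the raw input.

## Phantom generator

`generate_phantom` emulates only the features the method's mechanics
depend on: an air background at −1024 HU, an elliptical body at ~0 HU,
two disjoint lung ellipsoids at ~−700 HU, and one or more tumor blobs at
~40 HU placed inside the lungs, with additive Gaussian noise (sd 20 HU)
on the image only; masks are exact. Blobs are spheres perturbed by
low-order random radial harmonics — with perfect spheres, boxes and
masks would carry identical information and the teacher's task would be
trivial. Sizes come from a radius range (default 4–9 mm) or from a
(mean, sd) diameter target for calibrating cohorts to a published size
distribution. With zero noise, tumor voxels are strictly
threshold-separable from lung voxels, which guarantees the overfit
fixtures are learnable.

What the phantoms do **not** model: anatomy (airways, vessels,
mediastinum), partial-volume effects, annotation noise, inter-scanner
intensity variation, or tumors abutting the chest wall. Passing the
desk-scale tests therefore demonstrates that the machinery and the
qualitative teacher-student effect work, not that any particular DSC
transfers to clinical CT.

## Desk-scale study conditions

All tests and `scripts/acceptance.py` run on 64³ phantoms at
(1, 1, 1.5) mm with: teacher base_width 4 on 32³ patches, student
base_width 2 on lung halves (margin 4), Adam lr 1e−2, teacher 60 epochs
at virtual batch 1, student 8 epochs at virtual batch 4; the scarce
scenario uses 4 strong + 40 weak training phantoms, 2 validation and 10
held-out phantoms. The toy learning rate is larger than the full-scale
1e−4 because Adam's per-step displacement is of order lr and a few
hundred steps must move tiny networks much further relative to their
size. These sizes are the package's chosen desk-scale conditions; the
full-scale defaults remain on the config objects.

## Known limitations

- The numpy engine is CPU-only and sized for desk-scale runs; full-scale
  (128³, base_width 16, hundreds of cases) training is out of its reach.
- The box- vs point-guidance convergence gap is small at memorization
  scale (a handful of phantoms): both teachers can largely fit the
  images themselves, so the information advantage of boxes shows up far
  more weakly than in generalization-scale comparisons.
- DICOM series, multi-class labels, PET/MRI payloads, 3D bounding boxes,
  iterative teacher-student co-training and surface-distance metrics are
  out of scope.
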