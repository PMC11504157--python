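# Methods

`tkvnet` measures total kidney volume (TKV) from T2-weighted abdominal MRI
by a semi-automated pipeline: polygon-annotated training data, a 2D U-Net
segmenter trained with a Dice loss, morphological inpainting of the
predicted masks, and volumetry from DICOM geometry tags. This note records
the model, its assumptions, the parameters that matter, and what the
synthetic phantoms do and do not demonstrate.

## Problem and pipeline

In autosomal dominant polycystic kidney disease (ADPKD), TKV — the summed
volume of both kidneys — is the standard imaging surrogate for disease
severity and progression. The reference measurement is manual planimetry:
an expert traces both kidneys on every slice, and

TKV = Σ_slices (foreground pixel count × pixel-spacing row × pixel-spacing
col) × Δ,

with the through-plane step Δ taken from the DICOM tags. The pipeline
replaces the manual tracing with a learned per-slice segmentation:

1. **Geometry extraction** (`geometry_io`): PixelSpacing, SliceThickness,
   SpacingBetweenSlices, Rows, Columns, and orientation are read from the
   series; slices are ordered by ImagePositionPatient projected on the
   slice normal (InstanceNumber as fallback). Missing
   SpacingBetweenSlices is recorded as absent, never silently defaulted.
2. **Annotation → mask** (`dataset`): Labelme-style polygon outlines of
   the left and right kidney are rasterized with a pixel-centre rule (a
   pixel is foreground iff its centre is inside or on the boundary of a
   polygon) and merged into a single foreground class; laterality is
   recovered after segmentation, not predicted by the network.
3. **Segmentation** (`segmentation`): a 2D U-Net maps each slice,
   resampled to a square model grid and scaled to [0, 1] by division by
   255, to a per-pixel kidney probability.
4. **Inpainting** (`postprocess`): threshold at 128/255 (probability 0.5),
   fill enclosed holes, remove small speckle, split components into
   patient-left/right by centroid against the image midline.
5. **Volumetry** (`volumetry`): planimetric volume per side and their sum;
   a mid-slice estimator is provided as a comparator.
6. **Agreement** (`evaluation`): Dice and Jaccard from per-subject pooled
   voxel counts, agreement tables (mean ± sample SD of differences), and
   Bland–Altman bias with 95% limits of agreement.

## Network and training

The U-Net is the classic contracting/expansive architecture: per level two
3×3 same-padding convolutions with ReLU, 2×2 max-pooling on the way down,
2×2 transposed-convolution upsampling with skip concatenation on the way
up, dropout (rate 0.2) once at the deepest encoder output, and a 1×1
convolution with sigmoid head. Weights use He initialization. Defaults:
depth 4, 32 base filters (doubling per level), 256×256 single-channel
input. The forward and backward passes, the optimizer, and the schedule
are implemented directly on NumPy arrays (im2col convolutions, analytic
gradients); the gradient implementation is checked against finite
differences in the test suite.

Training minimizes a soft Dice loss, `1 − (2Σpt+ε)/(Σp+Σt+ε)` with
ε = 1e-6, computed per sample and averaged over the batch; with binary
predictions and ε→0 this is exactly `1 − DSC`. The optimizer is Adam
(β₁ = 0.9, β₂ = 0.999) with a warm-up exponential-decay schedule: linear
ramp from 0 to the peak rate over the warm-up, then geometric decay,
continuous at the junction. Defaults: batch size 10, up to 500 epochs,
peak 1e-3, 5 warm-up epochs, decay 0.9 per epoch — proportions sized for
an epoch of roughly a hundred optimizer steps (the ~1200-image clinical
training set). For few-slice datasets `small_data_train_config` raises the
peak to 3e-3 and flattens the decay to 0.99 per epoch, because with one or
two steps per epoch the default schedule decays the learning rate long
before convergence.

Each epoch draws a fresh random augmentation of every training pair —
rotation U(−5°, +5°), shift U(−10%, +10%) of each dimension, zoom
U(0.9, 1.1), no flips — applied identically to image (bilinear) and mask
(nearest-neighbour, re-binarized), background filled with 0. Validation
Dice is computed every epoch on un-augmented pairs at a 0.5 threshold,
slice-wise mean, with empty-vs-empty slices scoring 1. Early stopping
monitors validation Dice (patience 20, min_delta 1e-4) and restores the
best-epoch weights.

An 80:20 train/validation split is the default, image-wise
(`split_train_val`, floor(n·0.8) in train; 1483 images → 1186/297). A
patient-wise split (`split_by_patient`) is provided and is the better
choice when multiple subjects are available, since an image-wise split
lets neighbouring slices of one subject leak across the partition.

## Volumetry choices

- **Through-plane step**: the volume product uses SliceThickness by
  default (`spacing_mode="thickness"`); SpacingBetweenSlices is offered as
  an alternative because acquisitions with inter-slice gaps make the two
  differ. When the tags disagree by more than 5% a warning is logged. For
  contiguous acquisitions (and all phantoms) the two coincide.
- **Mid-slice comparator**: per kidney, area of the middle kidney-bearing
  slice × number of kidney-bearing slices × Δ, lower-median index for an
  even count; no ellipsoid correction factor is applied, so on an
  ellipsoid the estimator converges to 1.5× the true volume
  (π·a·b·2c vs 4/3·π·a·b·c) — the acceptance script reports this ratio.
- **Laterality**: component centroid against the vertical image midline,
  radiological convention (image-left = patient-right); a centroid exactly
  on the midline goes to patient-left. A side flip between adjacent slices
  is logged as a warning, not corrected.
- **Inpainting order** is fixed: binarize → fill holes (4-connected
  background) → despeckle (8-connected components, default minimum
  25 px). Filling before despeckling preserves ring-shaped (hollow)
  predictions; the complementary 4/8 connectivity pair avoids the usual
  topological paradoxes. The despeckle floor of 25 px at the native grid
  is far below any kidney cross-section at typical in-plane spacings.
- Slices with no kidney contribute zero volume rather than erroring
  (apex/base slices are legitimately empty).

## Synthetic phantoms

`phantom` generates MRI-like cases with exact ground truth: two
non-overlapping ellipsoidal kidneys (optionally containing brighter
spherical cysts, which count as kidney, as cysts do clinically for TKV),
dark background, additive Gaussian noise, full geometry metadata, and
analytic volumes 4/3·π·a·b·c per side. The default case is a 64×64×20
stack at 4 mm in-plane / 8 mm through-plane with two ~245 mL kidneys —
ADPKD-scale organs in a small grid so that CPU training completes in
minutes. Exported cases round-trip the whole pipeline: DICOM series,
Labelme JSON polygons traced from the truth masks (0.5-level contours, so
rasterization recovers the mask nearly exactly), and a ground-truth CSV.

What the phantoms demonstrate: that every stage — I/O, rasterization,
training, inpainting, lateralization, volumetry, agreement statistics —
is individually and jointly correct, with volumetric error against the
analytic ellipsoid below discretization level (≈0.1% at 1 mm isotropic
sampling) and end-to-end TKV recovery within a few percent after training
a small U-Net (depth 2, 8 base filters, 64×64 grid, ≈20 slices, 50
epochs) to validation Dice ≥ 0.95.

What they do not demonstrate: performance on patient MRI. Phantom
kidneys are high-contrast convex ellipsoids on an empty background; real
ADPKD kidneys are low-contrast, irregular, surrounded by other organs
(spleen, liver) with similar signal, and deformed by cysts. The clinical
results this pipeline design is based on — test-set Dice of 0.89 (axial) /
0.82 (coronal), per-patient TKV ground truths, Bland–Altman bias of a few
percent, early stopping near epoch 105/103 of a 500-epoch budget — were
obtained on a 40-participant hospital cohort whose images are not
deposited, and cannot be recomputed here; the bundled example agreement
cohort (`example_data`) carries only the per-subject volume pairs, which
is why the agreement arithmetic, but not the segmentation scores, is
reproduced exactly. The Bland–Altman convention behind the published bias
values is not recoverable from the volume pairs under any standard
denominator, so the package computes and reports all three conventions
(pairwise mean, reference, prediction) side by side instead of asserting
one.

## Numerical details

- Resampling: bilinear for images and probability maps,
  nearest-neighbour for masks; non-square slices are resized
  anisotropically to the model grid (no letterboxing), making the inverse
  map a plain resize. Output-pixel centres map to input coordinates as
  `(i + 0.5)·scale − 0.5` with edge clamping.
- Binarization boundary: grayscale 127 → 0, 128 → 1; probabilities
  0.5 → 1. Integer-valued grayscale maps and their /255 copies binarize
  identically.
- RescaleSlope/Intercept, when present in the DICOM, are applied before
  the /255 normalization so intensities are on the stored-value scale the
  annotators saw.
- All randomness (phantom rendering, splits, augmentation draws, weight
  init, dropout, batch shuffling) flows from explicit integer seeds;
  repeated runs are bit-identical.
- Degenerate inputs: empty annotation lists give empty masks; empty mask
  stacks give 0 mL; empty-vs-empty overlap scores 1 (applied per subject,
  where it cannot trigger for a kidney-bearing series); dropout 0 and
  zero-magnitude augmentation are exact identities.

## Problem sizes in the checks

The test suite and the acceptance script use the small default phantom
(20 slices, 64×64) for the end-to-end run, two seeds allowed with the
better run kept, and a 1 mm isotropic 280×100×110 phantom for the
volumetry oracle. These sizes were chosen as the smallest at which the
claims they support are stable.

## Known limitations

- 2D slice-wise segmentation only; no 3D context (a 3D U-Net was
  deliberately not taken on cost grounds).
- Single foreground class; laterality by midline centroid fails for
  midline-crossing morphology (e.g. horseshoe kidney).
- The NumPy training loop is single-threaded BLAS-bound and sized for
  small studies, not for GPU-scale replication of a 500-epoch run on
  thousands of 256×256 slices.
- Multi-frame DICOM and compressed transfer syntaxes beyond what pydicom
  decodes natively are out of scope; no MR sequence parameter
  interpretation is attempted.
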