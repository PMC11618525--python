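# Methods

This note documents the models and procedures implemented in
`radiomarker`, the parameter choices that matter, what the synthetic
phantoms do and do not emulate, and the known limitations.

## Frames, ROIs and intensity conventions

All operators work on a single 2-D grayscale slice (`ImageFrame`) with
8-bit intensity semantics (float values in [0, 255]) and physical pixel
spacing in mm. Coordinates are row-major and 0-based; ROI boxes are
half-open (`rows = [row0, row0 + height)`), at least 8×8 pixels, and must
lie fully inside the frame. DICOM reads apply RescaleSlope/Intercept;
data already inside [0, 255] passes through unchanged (this keeps 8-bit
fixture round-trips exact), while out-of-range data (e.g. 16-bit stores)
is min–max scaled per slice. Min–max per slice is a stand-in for an
unknown clinical window/level; it is the one place where absolute
intensities of clinical data become implementation-defined. General
resampling is bilinear; bicubic interpolation is reserved for the
contrast marker, where it is part of the pipeline definition.

## Intensity normalization

`normalize` applies the affine z-score remap

    out = (in − mean_in) / sd_in · sqrt(target_variance) + target_mean

then clamps to [clip_low, clip_high] (defaults 0, 255). Defaults
`target_mean = 108.0`, `target_variance = 2400.0` follow the values
fitted upstream to a large corpus of sagittal T1/T2 spine MRI; they are
package defaults, overridable via `NormalizationParams` or the config
file, and are not re-estimated here. The affine form makes the transform
idempotent and invariant to any positive global affine change of the
input — both exact as long as clamping does not bite. Zero-variance
input is an error.

The acceptance test image for the normalization contract is Gaussian
noise (mean 80, sd 20) truncated at ±1.8σ: with the default targets the
remapped sample then provably stays inside [0, 255], so the "no clipping
triggered" premise of the contract genuinely holds and the output
moments equal the targets to float precision. An untruncated Gaussian of
that size would clip ~1.5% of pixels at 0 and depress the output
variance by ~3%.

## Arcela complexity

    Ar = Σ_ROI |∇I| / (N · 255)

where ∇I is the Sobel gradient scaled to central-difference units
(kernel sum 8) and N the ROI pixel count. With this scaling a single
unit step edge contributes its full contrast exactly once across the two
adjacent pixels, so the score reads as "total object boundary per unit
area, in units of the 8-bit range": 0 for a constant window, and within
[0, 1] for realistic vertebral windows. Reflect padding avoids a
spurious boundary term at the crop edge. The score is invariant under
intensity inversion and, combined with normalization, under global
affine intensity changes. Because the exact historical formula of this
operator is not published, scores are comparable only within this
implementation; frames of a temporal sequence are resampled to the
sequence's minimum pixel spacing first so boundary sums are compared at
one physical resolution.

## Caldera detection

The reference intensity is the **median** of the disc ROI (robust to
disc edge pixels). Classes are defined relative to it with a relative
ISO half-width `iso_tolerance = 0.10` ("approximately equal" is not
quantified in the clinical literature; 10% is this package's documented
tolerance): BLACK thresholds sweep [0, 0.9·ref), WHITE (1.1·ref, 255],
ISO sweeps the band half-width up to 0.1·ref. The sweep step is 2
intensity units (8-bit data; halving the step changes phantom results
only in the last digit).

Per threshold: binarize → binary opening (3×3) → 8-connected components
→ per-component ellipse fit by second-order image moments (centroid +
covariance eigendecomposition) → filters → retained area. A component is
retained when

- pixel area ≥ 0.5% of the ROI,
- pixel area / fitted-ellipse area ∈ [0.7, 1.3],
- eccentricity ≤ 0.95,
- solidity ≥ 0.9 (a caldera is convex; ragged noise conglomerates are not),
- it does not touch the ROI border (a caldera lies wholly inside the
  vertebral window; this also stops a flooded background from
  masquerading as one giant ellipse).

The chosen threshold maximizes the summed retained component area, with
one guard: a threshold whose retained components explain less than
`min_mask_coverage = 0.5` of the mask's foreground is noise-dominated
and scores zero. Without this guard the max-area objective drifts to the
noisiest admissible threshold and inflates areas by the attached noise
halo (measured +7–16% on phantoms; ≤1.7% with the guard). Ties resolve
to the smallest swept value. The full sweep is recorded in the result so
the optimality of the choice is auditable. Areas are reported from
retained-component pixel counts (% of ROI); components at one threshold
are disjoint, so overlapping area is never double-counted. All filters
are config-exposed; threshold selection is per class, not joint.

ISO lesions are only detectable when the vertebral background differs
from the disc reference — an ISO lesion on a background equal to the
reference is by definition invisible. The phantom defaults encode this
(background 100, disc 160).

## Contrast accumulation

Pipeline: crop → bicubic upsample (default factor 2) → Gaussian blur
(default σ = 1.5 upsampled pixels; the historical system names only
"Blur") → threshold at `0.9 × mean` of the **blurred** window (the
pre/post-blur choice is unspecified upstream; post-blur is used and the
reported `mean_intensity` is the one the threshold derives from, so
`threshold_used / mean_intensity = 0.9` holds exactly) → 8-connected
components → closed contour polygons by marching squares on the padded
mask. The marker is the supra-threshold area as % of the ROI (the
extensive quantity suited to longitudinal plotting); the contour count
is diagnostic only. The comparison is ≥, so a constant nonzero window is
100% "accumulating"; an all-zero window short-circuits to 0%. On smooth
phantoms the marker moves < 2 points between upsample factors 2 and 3.

## Temporal sequences

`build_series` resamples every frame to the sequence's minimum pixel
spacing (frames without spacing metadata are treated as 1 mm isotropic,
with a warning), optionally normalizes intensities, scales the per-frame
ROIs to the resampled grid, runs the requested markers, and returns
date-sorted series. Same-day acquisitions are replicates and merge by
mean. ROIs are supplied per frame; there is no automatic vertebra
registration across studies. Marker/modality mismatches (Arcela is
usually computed on T1, caldera on T2, contrast on T1+contrast) warn but
do not fail.

## Separability audit

The fingerprint is the median-threshold hash: bilinear collapse to
32×32, threshold at the reduced image's median, ≥ resolving to 1 —
hence a constant image hashes to all ones. This is deliberately the
plain 32×32 reduction hash, not the DCT perceptual hash; fingerprints
are comparable only within this package. The hash is invariant to global
affine intensity changes that preserve ordering around the median.

The Kohonen map is trained online: per epoch the codes are visited in a
seeded random order; the best-matching unit (Euclidean) and its Gaussian
neighborhood move toward the sample; learning rate (initial 0.5) and
neighborhood radius (initial = half the grid, decaying to ~1 cell by the
final epoch) decay exponentially. Defaults: 10×10 grid, 500 epochs.
Training is bit-for-bit reproducible for fixed (data, grid, epochs,
seed). Internally the codebook is float32 with an incremental-sqnorm BMU
search; this is an implementation detail that does not change the
algorithm.

The audit maps each image to its BMU, takes the majority label per cell
(ties to the lexicographically smallest label), and counts 4-connected
same-label regions after unmapped cells inherit the label of the nearest
sample in codebook space — without that fill, a sparse mapping (90
images on 100 cells) fragments each class into several islands even at
purity 1.0. The audit passes (`separable = True`) when purity ≥ 0.75
and the region count equals the number of labels. This is a necessary
condition for training, not a sufficient one.

## MLP committee

Each member is a fully connected sigmoid network trained by per-sample
(online) backpropagation on a mean-squared-error objective against
one-hot targets. Outputs are independent per-class sigmoids and need not
sum to 1 — deliberately not softmax, since an ambiguous lesion scoring
high for two classes is diagnostically informative. Weights initialize
uniformly in [−0.5, 0.5] with per-network seed = base seed + index.
Defaults (config-exposed; the historical configuration is not
published): input = ROI resampled to 32×32, scaled to [0, 1] and
flattened (the 1024-bit hash is available as an alternative encoding);
one hidden layer of 32; committee of 5; 300 epochs; learning rate 0.2.
The committee is represented by the member with minimal final training
error; output averaging is available as an option. Selection by training
error risks overfitting, so the held-out error is logged with a warning
when a validation split is supplied. Models serialize to versioned JSON.

## Synthetic phantoms

A phantom frame is a uniform vertebral window (default 100) under a
disc band (top 16 rows, default 160, providing the caldera reference),
plus elliptical lesions and Gaussian noise (default sd 3), all rendered
deterministically per seed. Ground truth is exact and machine-readable:
rendered pixel area, analytic area πab, and % of the window per lesion.
Longitudinal sequences scale lesion semi-axes by the square root of a
per-timepoint area factor, at 3-month default intervals (a routine
follow-up cadence).

The classifier benchmark caricatures three tissue classes: `norm` —
regular horizontal trabecular banding (phase and period jittered only
slightly, because the audit requires a class's fingerprints to be
mutually similar, as trabecular structure is across vertebrae); `mst` —
dark nidus with a bright sclerotic rim, the typical appearance of a
healing osteolytic metastasis; `hema` — a bright coarse-textured round
blob. These are caricatures tuned for operator separability, not MR
physics: there is no k-space, coil, relaxation or partial-volume
modelling, no anatomy beyond one window and one disc band, and noise is
white Gaussian rather than Rician. Passing phantom tests therefore
demonstrates the operators' correctness and internal consistency — not
clinical accuracy on patient MRI, whose probabilities and marker values
this package makes no claim to reproduce.

## Problem sizes and numerical choices

Tests and acceptance checks run on 128×128 phantoms, 20 single-lesion
phantoms per caldera class, a 90-image audit set (30/class), a 10-seed
SOM stability check, and a 120-image classifier benchmark (90 train / 30
test) — sizes at which every ground truth is exact and the whole suite
completes in a few minutes on one CPU. Degenerate inputs are defined
rather than failed where a definition exists (empty admissible caldera
band → empty result; constant contrast window → 100%; all-zero window →
0%); genuinely undefined operations (zero-variance normalization,
single-label audits) raise errors. All randomness flows through
explicitly seeded numpy generators.

## Known limitations

- Marker absolute scales are implementation-defined (Arcela formula,
  hash variant, filter constants); only within-package comparisons are
  meaningful.
- No 3-D volumes, multi-frame DICOM, or PACS networking; one slice, one
  ROI at a time.
- No vertebra registration across a sequence; ROI drift correction is
  the operator's responsibility.
- The ISO class is undetectable against a background at the reference
  intensity (see above), and its biological interpretation is left open.
- Committee selection by training error is faithful to the historical
  design but statistically inferior to validation-based selection; the
  package logs, but does not enforce, the alternative.
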