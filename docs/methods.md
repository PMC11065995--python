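# Methods

## Scope and model

`wmhseg` segments white matter hyperintensities (WMHs) on thick-slice
(5–6 mm) axial FLAIR MRI, slice by slice, with an ensemble of two 2D
U-Nets, and reports voxel-overlap and surface-distance metrics plus lesion
volume in mL. The design assumptions are those of the screening setting it
targets: a single FLAIR sequence (no T1/T2), anisotropic voxels whose
thick axis is the slice axis, annotations at native resolution, and
heterogeneous scanners whose contrast differences are handled by intensity
augmentation rather than by harmonisation.

### Preprocessing

Each volume is min–max normalised to [0, 1] over the *whole* 3D volume —
not per slice, so the relative brightness of lesions across slices is
preserved — and no bias-field correction is applied. The degenerate
constant volume maps to all zeros rather than raising, so batch jobs never
crash on an empty acquisition. Bright artifacts do compress the intensity
scale under this rule; an optional percentile-clipping flag
(`clip_percentiles`) exists but is off by default, the default behaviour
being to leave artifacts in and rely on window-width (contrast)
augmentation during training. Slices are resized bilinearly to the square
model grid; predicted probability maps are restored to the native grid
bilinearly, clamped to [0, 1], and thresholded *after* restoration, so all
evaluation happens on the native annotation grid. Label resampling, where
needed, is nearest-neighbour so masks stay binary. Ties at the 0.5
threshold go to foreground; this is a documented convention affecting
measure-zero cases.

### Ensemble and loss

The ensemble fuses exactly two members by voxel-wise probability
averaging followed by a single 0.5 threshold on the fused map (one
threshold, one output — the fusion rule an averaged "main model output"
implies). The members differ by encoder family: a grouped-convolution
residual encoder (ResNeXt-style double 3×3 blocks, 4 groups) and an
inverted-residual depthwise-separable encoder (EfficientNet-style MBConv
without squeeze-excite). Both sit inside the same U-Net topology: an
encoder block per level with 2×2 max-pooling, a bottleneck, and a decoder
with nearest-neighbour upsampling and skip concatenation, ending in a 1×1
convolution with logistic activation. Normalisation inside blocks is
*instance* normalisation: statistics per sample and channel, so inference
is deterministic, identical to training behaviour, and per-scanner
contrast shifts are normalised away within each slice — the standard
choice in medical-image segmentation networks trained with small batches.

The loss is one minus a soft Matthews correlation coefficient. With
per-voxel probabilities p and binary targets y, soft counts are
TP = Σp·y, FP = Σp·(1−y), FN = Σ(1−p)·y, TN = Σ(1−p)·(1−y), computed
jointly over the whole batch (matching the global-count structure of the
MCC, rather than per-image averaging), and

    MCC = (TP·TN − FP·FN + ε) / (√((TP+FP)(TP+FN)(TN+FP)(TN+FN)) + ε),
    loss = 1 − MCC,  ε = 1e-7.

Placing ε in both numerator and denominator makes the degenerate cases
exact: perfect agreement — including an all-background prediction on an
all-background slice — costs exactly 0, a prediction independent of the
target costs 1, and perfect anti-agreement costs 2. The loss is
differentiable everywhere; its one hazard is a near-zero-gradient region
when predictions collapse to all-background early in training, addressed
by the warmup below.

### Training protocol

Adam with cosine-annealed learning rate (base → 0 over the run, no
restarts), batch size 15, and a short linear warmup over the first 10
steps. The warmup exists because aggressive early steps can push the
network into the all-background dead zone of the MCC loss, from which the
vanishing gradient cannot recover it; ten warmup steps removed every such
collapse we observed without affecting runs that never collapse. All
slices of all training cases enter every epoch, lesion-free slices
included, each augmented independently. There is no validation split and
no early stopping: training runs for the fixed epoch budget. Members are
trained independently with distinct derived seeds and (optionally)
distinct learning-rate multipliers (`MemberSpec.lr_scale`), since the two
encoder families converge at different speeds at small step counts. Every
batch's contributing case ids are logged, and the tests audit that no
test-role case ever contributes a training slice.

Two profiles package these choices. The **full** profile is the reference
protocol: 512×512 model grid, learning rate 0.001, 15 epochs, full-size
members, standard augmentation. The **desk** profile is the configuration
actually exercised by the test suite on one CPU core: 128×128 phantoms
and model grid, channel-reduced members (base width 8, depth 3), 5
epochs, base learning rate 0.02 (appropriate to the ≈70 optimisation
steps available at this scale, where 0.001 barely moves the loss), and
lighter augmentation magnitudes (shift ≤5%, rotation ≤10°, grid
distortion with probability 0.3). Problem sizes in the desk-scale tests —
30 cases at 128², and 37 cases at 64² for the pseudo-labeling
comparison — were chosen once as the smallest sizes at which training is
meaningfully non-trivial on a single core.

Model resolution matters more than capacity at phantom scale: restoring a
96×96 prediction to a 128×128 native grid caps the achievable Dice near
0.66 for small lesions purely through resampling, so the desk profile
keeps the model grid equal to the phantom grid.

### Pseudo-labeling

A trained ensemble predicts binary masks for every unlabeled case; *all*
predictions are kept (no confidence filtering), mirroring a pool of
machine annotations that inevitably mixes correct and incorrect labels.
Retraining then samples uniformly from the union of labeled and
pseudo-labeled cases with equal loss weight. A guard raises if any pseudo
case id intersects the test split (leakage) or the labeled training set.

### Augmentation

Horizontal/vertical flips, sub-pixel shift, rotation, window-width
contrast change about mid-gray (out = 0.5 + (in − 0.5)·gain, clamped),
and grid distortion (a smooth per-cell displacement field). Geometric
transforms apply identically to image and mask (bilinear vs
nearest-neighbour); the contrast transform touches only the image;
borders are zero-filled (background is dark on FLAIR). Magnitudes are
conventional medical-imaging defaults — probability 0.5 per transform,
shift ≤10% of the image, rotation ≤15°, gain in [0.7, 1.3], 5×5 grid
cells with ≤10% displacement — all exposed in `AugmentConfig`; no
magnitudes are inherited from prior work because none are specified
there. Augmentation is training-only.

## Evaluation

DSC = 2TP/(2TP+FP+FN), recall = TP/(TP+FN), precision = TP/(TP+FP),
computed per case on the native grid from exact voxel counts and
aggregated as unweighted means over cases. Specificity is deliberately
omitted: the background class is so large that specificity saturates
near 1 and discriminates nothing. Empty-mask conventions: both masks
empty → DSC 1.0; an empty denominator → recall/precision 1.0 (nothing
claimed, nothing missed). H95 is the maximum of the two directed 95th
percentiles of boundary-to-nearest-boundary distances, over boundary
voxel centres (6-connected erosion) in physical mm, with numpy's
linear-interpolation percentile; it is undefined when either mask is
empty and such cases are excluded from the H95 aggregate. Lesion volume
is voxel count × dz·dy·dx / 1000 (mL). The processing-time correction
maps a measured per-case runtime to a reference workload:
minutes × (reference slices / measured slices) × (measured GHz /
reference GHz), with reference defaults of 192 slices and 3.5 GHz;
measured timings are informational and never gate any test.

## The phantom generator

The generator exists so every pipeline stage is exercisable without
clinical data. It emulates, per case:

* **anatomy**: an elliptical brain per slice whose radii follow an
  ellipsoid cap along the slice axis; a bright cortical band; darker
  white matter; paired dark lateral ventricles on mid slices; a thin
  bright septum band between them (never annotated);
* **lesions**: a per-case target volume drawn from a lognormal in mL
  (default μ = 2.4407, σ = 0.9540 — moment-matched to a cohort mean of
  18.11 mL and SD 22.07 mL), split by `pvh_fraction` (default 0.6) into
  a periventricular component selected as the top-k voxels of a smoothed
  3D noise field biased toward the ventricle margin (confluent caps) and
  a deep component from an unbiased field (punctate, multi-slice blobs);
  top-k selection makes the generated volume match the drawn target
  voxel-exactly when the eligible region is large enough;
* **distractors excluded from ground truth**: lacunar infarcts (bright
  rim, dark centre, placed in deep white matter; default expectation 0.3
  per case — deliberately higher than the near-absence of lacunes in an
  annotated screening cohort, so the exclusion rule is actually
  exercised), enlarged perivascular spaces (small, below white-matter
  intensity; default 2 per case), and single-slice ambiguous bright
  specks (default 1 per case) emulating the rule that a lesion is only
  annotated when visible on neighbouring slices;
* **acquisition**: per-scanner contrast profiles (offset, gain) cycled
  across cases, additive Gaussian noise, slice thickness drawn uniformly
  from 5–6 mm, mild in-plane partial-volume blur, and an arbitrary
  scanner-unit scale so normalisation is non-trivial.

Each case derives its random stream from (seed, case index) through
`SeedSequence`, so cases are independent, order-insensitive, and
bit-reproducible.

What the phantom does **not** model: real tissue texture and physics,
skull/scalp, registration errors, multi-focal pathology beyond WMH-like
blobs, motion or flow artifacts, and true inter-rater annotation noise.
Passing phantom benchmarks therefore demonstrates that the pipeline's
machinery — normalisation, training, fusion, restoration, metrics,
pseudo-labeling plumbing — is correct and learnable end to end; it does
not certify clinical accuracy on real FLAIR data.

## Numerical choices

* Probabilities and weights in float32; gradient checks run in float64
  through the same code path.
* Convolutions are stride-1 "same"; downsampling is explicit 2×2
  max-pooling (ties to the first maximum), upsampling nearest-neighbour.
* Grouped convolutions are evaluated through a dense block-diagonal
  weight expansion (G-fold redundant arithmetic for one contiguous GEMM
  per kernel tap), which is substantially faster on CPU than sliced
  per-group products; depthwise convolutions use a broadcast-multiply
  path.
* H95 percentiles use linear interpolation between order statistics, so
  the oracle tests can assert exact equality.
* The MCC ε is 1e-7; the head convolution starts at zero bias (initial
  predictions near 0.5, where the MCC gradient is informative).
* `split_manifest` rounds fractions to nearest, so 207 labeled cases at
  fractions (138/207, 69/207) give exactly 138/69.

## Known limitations

* The desk profile's accuracy figures are phantom-scale properties, not
  clinical performance; the full profile's 512×512 configuration is
  provided but not exercised by the test suite.
* No pretrained encoder weights exist in this framework;
  `use_pretrained_init` is accepted for configuration parity and rejects
  `True` with a clear error. Training from seeded random initialisation
  at very small step counts is sensitive to the initialisation seed;
  warmup removes the catastrophic collapses but residual seed-to-seed
  variance remains.
* NIfTI orientation beyond voxel spacing is ignored; volumes are assumed
  axis-aligned with (slice, row, column) order, the thick axis first.
  Real-world data must be pre-oriented.
* Specificity, lesion-wise (connected-component) detection metrics, and
  significance tests between models are out of scope.
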