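# Methods

## Problem and scope

`petseg` implements fully automatic delineation of tumor functional uptake
in 3-D PET volumes, in the setting where the pathological uptake lies next
to — sometimes touching — an intense physiological uptake (the bladder in
cervical cancer) that must not be included, and where the cohort spans
several institutions with unharmonized scanners, voxel grids and
reconstruction settings. The pipeline covers synthetic cohort generation,
preprocessing, augmentation, the segmentation networks, patch-based
training, sliding-window inference, and leave-one-center-out evaluation.

No public multi-center cervical PET cohort with ground-truth masks exists,
so the package ships a phantom generator that reproduces the statistical
structure of the problem at sizes a desktop CPU can train against. All
quantitative results produced by the test suite and `scripts/acceptance.py`
are therefore statements about these phantoms, not about clinical data.

## Phantom generator

Each case is an ellipsoidal "body" of background uptake 1 (arbitrary
units) containing:

* a spherical **bladder** with uptake drawn as 1.5-5 x the tumor uptake.
  Urinary tracer pooling makes the bladder the hottest structure in most
  pelvic FDG scans; this is what defeats naive thresholding.
* a **tumor**: an ellipsoid with random anisotropy, optionally perturbed by
  a smooth random field (`tumor_lobulation`) so shapes are not round, with
  uptake 3-8 x background, multiplicative smooth heterogeneity field
  (amplitude `tumor_heterogeneity` in [0,1]), placed adjacent to the
  bladder at a surface gap drawn from 0 (touching) to 6 mm.

Anatomy is drawn in absolute millimetres (body semiaxes ~52-60 mm, bladder
radius 14-19 mm), independent of the scanner grid: patient size must not
correlate with the acquisition center, otherwise leave-one-center-out
validation tests an artificial shift rather than scanner heterogeneity.
Tumor volumes follow a clamped log-normal. At full scale the defaults
(median 22 cm^3, sigma(log) = 1.0, clamp 1-150 cm^3) put roughly 10% of
cases below the 6.4 cm^3 (200-voxel) small-tumor regime and give a mean
near 37 cm^3; the three-center desk profile uses median 7 cm^3, clamp
3-16 cm^3 so tumors fit the shrunken 128 mm field of view.

Scanner heterogeneity: each center profile fixes a native voxel spacing
(defaults follow the five-institution layout: 4.073 x 4.073 x 2.027 mm,
5.469 x 5.469 x 3.27 mm, 4 x 4 x 4 mm), an axial slice-count range
(77-192 at full scale), and a noise range. Partial volume is emulated by
Gaussian smoothing of the ideal activity map (FWHM 4.5 mm, configurable,
on by default — PET resolution is 4-5 mm); additive Gaussian noise
(SD = `noise_sd` x background) is applied inside the body only and the map
clipped at zero, so air stays exactly zero and per-scan "body statistics"
are well defined. Ground truth is the ideal pre-smoothing tumor support:
unambiguous and independent of the noise realization.

What the phantoms do **not** model: sinogram-level physics (no
reconstruction artifacts, no spatially correlated noise), attenuation,
motion, nodal/secondary uptakes, or anatomical texture. Passing the desk
study shows the pipeline mechanics work and that a CNN can learn
"segment the moderately hot blob, not the hottest one" across voxel grids;
it does not certify clinical performance.

## Preprocessing

All volumes and masks are linearly resampled to a common 4 x 4 x 2 mm grid
(output shape `round(native_shape x native_spacing / target)`, minimum 1 —
field of view preserved to half a voxel). Masks are linearly interpolated
and cut at 0.5; nearest-neighbour is available behind a flag. Whether a
clinical pipeline should threshold interpolated masks or use
nearest-neighbour is genuinely open; the 0.5 cut was chosen because it
keeps mask volume approximately unbiased under downsampling.

Intensities are Z-scored per scan using only non-zero (body) voxels; all
voxels, including zeros, pass through the same affine map. A scan that is
all zero, or whose body is constant, raises a degenerate-input error.

Training samples are fixed-size patches with corners uniform over valid
positions; volumes smaller than a patch are zero-padded (zero = background
before normalization, so padding never contaminates body statistics). An
optional foreground bias re-draws the corner so the patch contains tumor;
it is off by default and switched on in the desk profile (0.6) because at
batch size 2 and ~250 steps a sparse tumor class would otherwise be seen
too rarely to learn from.

## Augmentation

Six transforms, each applied independently with probability 0.2 per patch:
axial mirroring; rotation (each axis included with probability 1/2, at
least one forced, angle uniform in [5, 15] degrees with random sign) plus
isotropic scaling in [0.8, 1.2]; elastic deformation (4^3 control grid,
max displacement 5 mm — these two values are unstated upstream and are
package defaults); gamma correction with gamma in [0.8, 1.2] applied after
min-max mapping to [0,1] and back (the power law is undefined on negative
Z-scored values); contrast stretching of the range to 0.8-1.2 x anchored
at the sample minimum (the anchor convention is ambiguous; the
sample-minimum reading is implemented); additive Gaussian noise with SD
0.1-0.2 x the sample SD. Fixed order: spatial before intensity, so
intensity statistics are computed on the already-warped sample. Spatial
transforms move image and mask jointly and the mask is re-binarized at 0.5.

## Networks

The proposed model is a 3-D encoder-decoder on `(batch, channel, x, y, z)`
tensors:

* **Learnable downsampling**: strided 3^3 convolution + instance norm +
  ReLU + scSE; the stem uses a 7^3 kernel with stride 2 directly on the
  input (memory and receptive field).
* **Residual blocks** with full pre-activation ordering
  (norm -> ReLU -> conv, twice), scSE on the residual path, identity skip
  (1^3 projection when channels change).
* **scSE**: channel branch = global average pool -> bottleneck (reduction
  2) -> sigmoid per-channel gate; spatial branch = 1^3 conv -> sigmoid
  per-voxel gate; branches combined by addition (elementwise maximum
  behind a flag).
* **Decoder**: 3^3 transposed convolution (stride 2) blocks, encoder skip
  concatenated, channel-reducing residual block; a final upsampling block
  restores full resolution and a 1^3 convolution + sigmoid yields voxel
  probabilities.
* Instance normalization everywhere (batch size 2 makes batch statistics
  useless), epsilon 1e-5, affine parameters on. Kaiming fan-in
  initialization; zero biases.

The channel schedule (default [24, 48, 96, 192], desk profile [8, 16]) is
configurable and recorded in every checkpoint sidecar; the printed
schedule of the source architecture diagram is not legible, so the default
is declared, not inherited. The `StdUNet` baseline is built from the same
config: plain (conv -> instance norm -> ReLU) x2 blocks, max pooling,
fixed trilinear upsampling, same head.

Because no deep-learning framework is part of the runtime, the networks
run on an in-repo reverse-mode autodiff core (`petseg.nn.tensor`,
`petseg.nn.conv`): im2col-based 3-D convolution / transposed convolution
with hand-written adjoints, verified against central finite differences
and an adjoint identity in the test suite.

## Objective, metrics, baseline

Soft Dice loss with +1 Laplacian smoothing in numerator and denominator,
reduced over the whole patch, averaged over the batch. The smoothing keeps
the loss defined (and zero) when a patch contains no tumor at all — a
frequent event in whole-body patches.

Evaluation reports DSC, precision and recall per case. Edge conventions:
both masks empty -> all three are 1; exactly one empty -> all 0. The T40
baseline thresholds at 40% of the maximum uptake inside a search region;
run fully automatically the region is the truth bounding box dilated by 2
voxels (a deliberately permissive region: when the hot bladder intrudes,
the threshold latches onto the bladder maximum and the tumor is lost,
which is the baseline's documented failure mode). The region rule is a
config knob reported with results. The per-case contrast statistic is
operational: max uptake inside the truth mask over the mean uptake in a
2-voxel peritumoral shell excluding the bladder.

## Training and inference

Adam (beta1 0.9, beta2 0.99) with cosine annealing per epoch from lr_max
1e-4 to lr_min 1e-6, warm restarts every 25 epochs (a single-decay mode
exists behind `warm_restarts=False`; the restart reading of "every 25
epochs" is the default). Moment estimates are kept across restarts. One
random patch per training case per epoch, batch 2, 400 epochs at full
scale. A 20% validation split, stratified by center, is scored each epoch
(Soft Dice loss and hard DSC at 0.5 on a foreground-centred patch per
case) and the best-validation-DSC parameters are kept.

Whole-volume prediction tiles the volume with training-size windows at 50%
overlap and averages overlapping probabilities (uniform weights; Gaussian
blending behind a flag); masks are cut at 0.5 with no post-processing by
default, and can be resampled back to the native grid (linear + 0.5).

## Desk-scale study

The study behind `scripts/acceptance.py` and the pipeline tests: 20 cases
over three centers (7/7/6) with mixed spacings (4x4x2, 4x4x4,
5.469x5.469x3.27 mm), 32^2 in-plane matrices, 16-40 slices. Model
channels [8, 16]; training patch 32 x 32 x 16 (the whole in-plane extent),
40 epochs x ~6 steps (~240 Adam updates) with a single cosine decay from
5e-3 to 1e-4 and foreground bias 0.6; augmentation as above. The
single-phantom memorization check uses 300 steps at the same patch size.
Leave-one-center-out cross-validation trains the proposed network and
StdU-Net from scratch per fold with identical seeds and evaluates both
plus T40 on the held-out center; the cross-fold average is the unweighted
mean of fold means. Everything is seeded; two runs with the same seed are
bitwise identical (pure NumPy arithmetic, stable RNG streams).

Problem sizes were chosen so the whole study runs in minutes on one CPU
core; the narrow network and short schedule are sufficient on phantoms
because the phantom foreground/background statistics are far simpler than
clinical PET.

## Numerical choices and degenerate inputs

* Resampling uses voxel-centre alignment (`index x spacing` world
  convention, diagonal affines); identity resampling is exact.
* Mask re-binarization threshold after any linear interpolation: 0.5.
* Wilcoxon signed-rank on identical paired samples is degenerate; it is
  reported as "no difference" with p = 1 rather than an error.
* Outlier rule: per fold, DSC < Q1 - 1.5 IQR (boxplot rule), recorded in
  the report, needs >= 5 cases.
* Stratification uses rank-based deciles with ties broken by case id, so
  group boundaries are deterministic.
* maxpool gradient at ties is split equally; scSE sigmoid gates saturate
  exactly to 1.0 in float32 at |logit| >= ~17, which the gate-algebra
  tests exploit.

## Known limitations

* The phantom's simplicity means absolute metric levels are optimistic;
  only qualitative orderings (CNNs above T40, failures concentrated in
  small/low-contrast tumors) transfer as claims.
* At desk scale the StdU-Net baseline is competitive with — in the
  acceptance run, slightly ahead of — the proposed network: the scSE
  architecture's advantages are claimed for full-scale clinical training,
  and a 20-case phantom study with [8, 16] channels cannot resolve them.
  The desk study demonstrates that both CNNs, unlike thresholding, solve
  the bladder-adjacency problem; it does not rank the two architectures.
* The NumPy backend is single-threaded per op and holds im2col buffers, so
  full-scale (128 x 128 x 64, channels [24,48,96,192], 400 epochs)
  training is out of reach on CPU; the code paths are identical at desk
  scale, which is what the tests exercise.
* One tumor per case; no multifocal disease, no nodal uptake.
* SUV calibration is out of scope: intensities are arbitrary uptake units,
  which is sufficient because Z-scoring removes the scale.
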