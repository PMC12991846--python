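# Methods

This note records the models, conventions, and numerical choices behind
`paiq`, and what the synthetic benchmark does and does not establish.

## Preprocessing and data model

All metric computation operates on reconstructed 2D images after per-image
min–max normalization to [0, 1] (`data_range` R = 1), the standard
preprocessing for photoacoustic reconstructions; raw channel-data filtering
and beamforming are out of scope. A constant image normalizes to all-zeros
rather than erroring so fully degraded background-only frames survive batch
runs. Geometry is 0-based, row-major, half-open, origin top-left. Metrics
whose published constants assume 8-bit data (GMSD c = 170/255², FSIM
T2 = 160/255², HaarPSI C = 30/255², BRISQUE C = 1/255, VIF σ_n² = 2·(R/255)²)
are rescaled by (R/255)² (or R/255 for additive constants) so normalized
inputs reproduce 8-bit behavior.

## Full-reference metrics

* **SSIM family.** 11×11 Gaussian window, σ = 1.5, K1 = 0.01, K2 = 0.03,
  valid-region convolution (no padding); agreement with scikit-image's
  implementation is exact. MS-SSIM uses the canonical five-scale exponents
  (0.0448, 0.2856, 0.3001, 0.2363, 0.1333), 2×2 mean-pool downsampling, the
  luminance term at the coarsest scale only, and auto-reduces the scale
  count with a warning when the image is too small (128 px supports four
  scales with an 11-px window).
* **IW-SSIM** shares that mean-pool multiscale backbone (so that uniform
  weights reduce it exactly to MS-SSIM, a tested degeneracy) and weights the
  local SSIM terms by information content computed from bandpass residuals
  (level minus upsampled next level). The weight is the mutual information
  between a Gaussian source and its two noisy percepts: with local signal
  power s², distortion gain g and distortion noise σ_v² estimated from 3×3
  sliding windows, and sensory noise σ_n = 0.03·R,
  w = ½·log₂[((s²+σ_n²)(g²s²+σ_v²+σ_n²) − g²s⁴)/(σ_n²(σ_v²+σ_n²))].
* **S3IM.** Neighborhood size floor(H/16)·2+1; the Gaussian local mean uses
  σ = neighborhood/6 truncated at the neighborhood radius. With the offset
  fixed at 0.5 and the neighborhood rule as the only prescribed parameters,
  this implementation masks a pixel when it exceeds its Gaussian local mean by
  offset·k·R with k = 0.1 (config-exposed). The margin sits *above* the
  local mean: structure must stand out from its surroundings, a constant
  image yields an empty mask, and a bright line is masked without a halo.
  The alternative sign would mask every pixel of a constant image, which
  contradicts the metric's purpose of suppressing uninformative background.
  An empty combined mask returns 1.0 with a warning (two structureless
  images are trivially similar) so blank frames don't break ladder runs.
* **GMSD / MS-GMSD.** Prewitt 3×3 (÷3) gradients after a 2×2 mean prefilter
  with 2× downsampling; the score is the population standard deviation of
  the similarity map (the variance reading is an option, off by default).
  MS-GMSD is the equal-weight root-mean-square of per-scale GMSD over a
  four-level dyadic pyramid.
* **VIF** is implemented in the spatial domain exactly as its per-window
  formula is written — Σ g·log₂(1+s²/σ_n²) / Σ log₂(1+s²/σ_n²) with gain
  g = σ_xy/σ_x² and s² = σ_x² from 9×9 uniform windows — not as the original
  wavelet-domain VIF. A reference that is locally constant everywhere
  (numerically: max local variance ≤ 1e−10·R²) is rejected.
* **UQI.** 8×8 uniform sliding window with ε = 1e−12 added to both
  denominator factors. Consequence: windows that are identically zero in
  both images contribute 0, not 1, so a mostly-black image scores below 1
  even against itself; identity checks therefore use images with signal in
  every window. This keeps the behavior total and deterministic without a
  special-case ladder.
* **HaarPSI.** 2× mean-pool subsampling, three one-scale 2^j×2^j Haar
  high-pass filters per orientation; local similarity from the two finest
  levels, weights from the coarsest; logistic pooling with α = 4.2 and the
  squared inverse logistic as final score.
* **FSIM.** Phase congruency from an FFT log-Gabor bank (4 scales × 4
  orientations, min wavelength 6, multiplier 2, σ_onf 0.55, angular spread
  σ_θ = π/4/1.2) with median-based noise-energy compensation (k = 2);
  gradients from the Scharr operator; α = β = 1, T1 = 0.85,
  T2 = 160/255²·R².

PSNR reports +∞ for identical images (MSE = 0); these infinities are
excluded from statistical samples with a logged count.

## BRISQUE features

MSCN uses the canonical 7×7 Gaussian window (σ = 7/6). GGD and AGGD
parameters are estimated by moment matching (ratio-of-moments inversion on
a 0.001-step shape grid clamped to [0.2, 10]) rather than maximum
likelihood, for determinism and speed. The chain stops at the
36-dimensional feature vector: the final 0–100 score requires a
support-vector regressor trained on human-labeled natural images, and no
such weights are shipped; any externally trained scorer can consume the
features.

## Detectability metrics

Standard deviations are population standard deviations — with ROIs of ≥ 100
pixels the distinction from sample deviations is negligible, and it keeps
the gCNR identities exact: disjoint-support distributions score exactly 1,
identical pixel multisets exactly 0. gCNR uses 100 equal-width bins
(config-exposed) spanning the joint min–max of the paired ROIs. The
histogram-overlap integral is invariant under monotone remapping in the
continuum; with fixed-width bins a nonlinear remap perturbs the estimate by
binning noise (±0.03 at 100 samples/100 bins), so only affine invariance is
exact. ROIs are supplied explicitly (CSV or API); there is no automatic
target detection.

## Separability ranking

Welch's unequal-variance two-sided t-test is used for subset pairs —
subset variances differ systematically across degradation levels, so the
equal-variance form would be mis-specified. All C(k,2) pairs of a ladder are
tested at α = 0.05 with no multiple-testing correction (a Bonferroni option
exists, off by default). NMD averages |mean difference|/value-range over
significant pairs only; value ranges are 1 for the similarity metrics
(SSIM family, UQI, VIF, HaarPSI, FSIM — their practical range on
nonnegative images), a nominal 80 dB dynamic range for PSNR, and the
observed pooled range for the GMSD family (all config-overridable).
Normalizing PSNR by its within-suite spread instead would inflate its
effect sizes purely because its scale is open-ended. CS = SC × NMD; ranking sorts by CS descending with ties broken by
SC then name. Negating a metric's values leaves SC, NMD and CS unchanged
(tested), so lower-is-better metrics need no special handling.

Spearman-vs-quality correlates per-image values with subset quality rank;
when a subset holds more than one image the rank variable is tied, so even
a perfectly monotone metric tops out slightly below 1.

## Synthetic phantoms and ladders

The generator emulates the image-domain signature of the two dominant
photoacoustic degradations:

* **Sparse view:** Radon transform over n equispaced angles in [0, 180°),
  ramp-filtered backprojection, clip to ≥ 0, re-normalize. The ladder
  8/16/32/64/128 angles produces the characteristic streaks; dense nested
  subsets reuse one 128-angle sinogram per phantom.
* **Frame averaging:** additive Gaussian noise with σ = σ₀/√n_frames,
  clipped to [0, 1]. σ₀ = 2.0 per frame, so the ladder
  128/256/384/640/1280/2560 frames spans σ ≈ 0.18 → 0.04 — a realistic
  span for normalized reconstructions.
* **SNR ladders:** noise scaled to a target RMS-signal-to-noise in dB
  (10–50 dB).
* **Domain shift:** 2-px Gaussian blur plus multiplicative speckle of
  strength 0.8/level on Derenzo phantoms — a different artefact family used
  only for out-of-distribution evaluation.

Vessel phantoms are smooth random-walk branching strokes (width 1–4 px,
foreground fraction kept within 2–25%); Derenzo phantoms are sector
triplets of discs with per-sector decreasing radius, placed with an
explicit minimum-separation rule so the connected-component count always
equals the disc count. A single global seed fans out to per-image and
per-level `SeedSequence` spawn keys; the same seed reproduces every ladder
bit-for-bit.

What the synthetic benchmark shows — and does not. Passing ordinal-fidelity
and ranking checks on these ladders demonstrates that the metrics resolve
angular-undersampling and noise degradations in the right order and that
the statistical framework reproduces the structural-metrics-beat-PSNR
pattern at desk scale. The phantoms lack real acoustic physics
(transducer bandwidth, heterogeneous sound speed, depth-dependent fluence),
real anatomical texture, and experimental-system variability, so absolute
metric values and model errors do not transfer to experimental archives.

## Quality-regression models

PAQNet assigns the 5×5 kernel to the first convolution and 3×3 to the rest,
giving 2,502,273 (≈ 2.5 M) parameters at 128×128 input; alternative kernel
assignments are config-selectable. IQDCNN uses 2×2 max-pooling after each of its four
32-filter 5×5 convolutions (pooling placement is unstated in its
description; without pooling the first dense layer alone would exceed 500 M
weights), giving 4.28 M parameters. EfficientNetIQA follows the B0 stage
plan (MBConv with squeeze-excitation, stem adapted to one channel) with a
128-unit regression head, 4.17 M parameters, randomly initialized — no
pretrained weights are downloaded or shipped.

The engine is NHWC numpy/float32 with hand-derived backpropagation
(verified against float64 central differences to ~1e−7 relative); stride-1
dense convolutions run as k² shifted-slice BLAS matmuls, small-channel and
strided convolutions via im2col, depthwise via einsum. Training uses MAE loss,
Adam with learning rate 1e−4, batches of 16, and early stopping on
validation loss with best-checkpoint restore. Multi-output training
min–max-normalizes each target over the train split after negating
lower-is-better metrics (GMSD family) so every head is oriented
higher-is-better; evaluation de-normalizes before computing MAE, Spearman ρ
and Pearson r per dataset. Constant predictions report correlations of 0
with a warning. Grad-CAM weights the final convolutional activations by the
spatially averaged gradient of the chosen output, rectifies, bilinearly
upsamples and min–max-normalizes.

**Problem sizes.** The packaged parameter-recovery experiment trains PAQNet
on 5,120 labelled images (vessel phantoms under frame-averaging noise at
log-uniform random levels, 32 images per phantom), validates on 384, and
evaluates on a held-out six-level frame ladder (72 images) plus the
domain-shifted Derenzo ladder (48 images), for one epoch — the noise-to-SSIM
mapping is simple enough that a single pass reaches ≈ 0.04 MAE and
ρ ≈ 0.92 in distribution, while the domain-shifted error stays several
times higher. The benchmark-suite checks use four ladders of 8 phantoms per
level at 128×128.

## Known limitations

* IW-SSIM, HaarPSI and FSIM follow their published formulations but are not
  numerically cross-checked against third-party implementations; their
  tests verify identities, bounds, degeneracies and literal recomputations
  instead.
* The BRISQUE scorer (SVR) and CLIP-IQA are intentionally absent.
* 2D single-channel images only; no DICOM, volumes, or multi-wavelength
  stacks.
* The Radon-based sparse-view emulation approximates circular-array
  tomography geometry; it is not a wave-equation simulation.
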