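# Methods

## Problem and model

`fdosr` implements arbitrary-scale super-resolution (SR) for real-valued 3D
intensity volumes, aimed at the whole-heart MRI setting where isotropic 3D
acquisitions are slow and a low-resolution (LR) scan plus an SR model can
stand in for a long high-resolution (HR) acquisition. The model is an
encoder/decoder pair:

* **Encoder f_θ** — a residual dense network operating on the LR grid:
  two shallow 3×3×3 convolutions, 8 residual dense blocks (RDBs; 3
  conv+ReLU layers with dense concatenation, then a 1×1×1 local-fusion
  convolution and a local residual addition), global feature fusion
  (1×1×1 then 3×3×3 convolution over the concatenated RDB outputs), a
  global residual addition of the first shallow-convolution output, and a
  head convolution to a 128-channel feature volume. There is no pooling,
  no normalization layer, and no encoder→decoder skip connection.
* **Upscale** — parameter-free trilinear resampling of the feature volume
  from the LR grid to the target grid. Because resampling works for any
  output size, the same trained network serves any real scale factor
  (non-integers included); this is what makes the SR factor arbitrary.
* **Decoder g_φ** — an 8-layer per-voxel MLP (7 × linear+ReLU at width
  128, then one linear layer without activation) with shared weights,
  mapping each voxel's feature vector to one intensity.

Training minimizes, over LR/HR pairs (x, y),

    L = ||y − g_φ(f_θ(x))||₁ / N  +  λ · || mask ⊙ (FFT3D[y] − FFT3D[g_φ(f_θ(x))]) ||₁

i.e. a mean-absolute data-consistency term plus an L1 penalty on the masked
difference of the orthonormal 3D spectra ("synthetic frequency domain" —
the FFT of the reconstructed magnitude image, not raw k-space). The mask
keeps high spatial frequencies, steering training toward preserving fine
detail (thin vessels, tissue borders) that plain L1 training tends to blur.
Default λ = 1e-3.

## The spectral mask

`build_mask(dims, outer_zero_fraction=0.3)` zeroes 30% of the spectral
extent per axis and keeps the rest. In the unshifted (DC-at-corner) array
layout of `numpy.fft.fftn`, high frequencies sit at the array center, so
the kept region is a central box of `round((1−f)·N)` indices per axis
(343 of 1000 coefficients for a 10³ grid at f = 0.3); under the
DC-centered layout the same physical coefficients sit at the corners. Both
conventions are supported and are exactly equivalent under the half-grid
shift (tested). For even kept lengths the band is biased one index toward
the low side. The DC coefficient (image contrast/mean) is never inside the
kept region at the default fraction, so the penalty never constrains
global contrast. A radial (ellipsoidal) mask geometry is provided as an
alternative; the box geometry is the default because it is separable and
is the standard k-space truncation idiom.

Two reductions of the spectral L1 are available: `sum` (the plain L1 norm)
and `mean` (per-kept-coefficient). Training uses `sum` by default: on the
desk-scale phantoms this keeps the λ = 1e-3 penalty comparable in
magnitude to the data term (a per-coefficient mean makes the penalty
numerically inert at that λ). The evaluation-side residual reports use
`mean` so values are comparable across grid sizes.

## Shape rules

All grid arithmetic lives in `fdosr.shapes` and is shared by every module:
degrading an N-voxel axis by factor s yields `floor(N/s)` voxels
(never extrapolates); super-resolving an M-voxel axis yields
`round(M·s)`. For non-integer s the composition `round(floor(N/s)·s)` can
undershoot N by up to `ceil(s)−1`, so during training and evaluation the
target grid is always taken from the stored HR volume; free inference uses
the rounding rule. One geometric mapping (cell-centered,
`src = (i+0.5)·N/M − 0.5`) is used by the trilinear degradation, the
feature upscale, and the nearest-neighbor baseline, so methods are
compared under identical geometry.

## Synthetic phantoms

The generator emulates the statistical structure of the study data rather
than anatomy: on a 32³–64³ grid it renders (i) full-span axis-aligned
tubes of radius 0.5–3 voxels (vessel analogs) with a one-voxel linear edge
ramp and a rejection-sampled separation constraint (center distance
> r_i + r_j + 2) so connected-component labeling can recover the tube
count; (ii) ellipsoidal shells with distinct shell/interior intensities
(chamber analogs); (iii) a smooth background gradient; (iv) additive
Gaussian noise (σ = 0.01 by default, on the normalized intensity scale).
Four contrast profiles (`react`, `ncssfp`, `ssfp`, `irssfp`) stand in for
the four clinical sequences and differ in background level, vessel
contrast, and shell polarity. Volumes are min–max normalized to [0, 1];
PSNR is therefore reported with data range 1.

What the phantoms do **not** model: MR physics (coil sensitivity, partial
volume, triggering), compressed-sensing reconstruction artifacts, curved
vessels, or anatomical shape priors. Passing the phantom studies shows the
training machinery and the regularization behave as designed; it does not
certify clinical image quality.

Degradation is trilinear resampling by default (common scanner-side
resampling practice); an ideal low-pass `kspace_truncation` variant is
provided because the method reasons in the frequency domain. Whether the
original study degraded in image space or k-space is not stated anywhere;
tests pin the trilinear path. The same factor is applied on all three axes
(isotropic volumes).

## Training procedure

Per optimization step a fresh scale factor s ~ U[2, 4] is drawn, one HR
phantom is degraded to its LR counterpart at that factor, and Adam updates
the parameters on the composite loss (masks are rebuilt per target grid
size and cached). Runs are exactly reproducible from the config seed
(phantom content, scale draws, initialization, and data order all derive
from it). Optional coherent patch training (crop the HR patch, then
degrade it) is available for larger volumes; desk runs train on whole 32³
phantoms.

The reference full-scale schedule (initial learning rate 1e-4, stepped
every 200 epochs over 2400 epochs) needs far more steps than a desk CPU
run affords. `desk_training_config()` therefore fixes the package's
desk-scale optimization: 200 steps, learning rate 1e-3, global-norm
gradient clipping at 1.0, Adam β₂ = 0.99, and validation-based
best-checkpoint selection (validation PSNR at factor 2 every 3 epochs on a
small separate phantom split). These values were calibrated once on pilot
phantom runs for stable descent within 200 steps; the stepped decay
schedule (`lr_at_epoch`) and the 1e-4 full-scale default remain available
through `TrainingConfig`.

Divergence handling: the loop raises a named `TrainingDivergedError` when
the loss or any gradient becomes non-finite, or when the epoch-mean loss
exceeds 1000× the first epoch's mean for 10 consecutive epochs. An
overweighted penalty (λ ≈ 1e-2 at full scale) is the known failure mode;
at desk scale Adam's per-parameter normalization absorbs a large λ at the
default step size, so the divergence test drives the instability with
λ = 10 together with an aggressive unclipped step size (0.2) — the point
under test is that divergence surfaces as the named error rather than a
hang or a silent bad fit.

## Evaluation

Metrics: MSE/RMSE (voxelwise), PSNR = 10·log10(range²/MSE) dB with a +inf
sentinel for identical volumes (excluded from aggregated means), and 3D
SSIM with the standard Gaussian window (σ = 1.5, 11³ support, truncation
3.5, C₁ = (0.01L)², C₂ = (0.03L)², Wang-style population weighting)
computed from separable weighted local sums over windows fully inside the
volume. The implementation is written directly from the definition and is
cross-checked in the tests against an independent reference implementation
(agreement ~1e-7; the window is 11³ rather than 7³ because that is the
standard SSIM configuration and the one the reference implements exactly).

`evaluate_corpus` emits one row per (volume, factor, method) over the
factor grid {2, 2.5, 3, 3.5, 4}; aggregation reports mean ± SD per method
and factor. `ablation_lambda` sweeps λ over {1e-2, 1e-3, 1e-5, 1e-10,
1e-15} by default, recording a diverged run as row status rather than
aborting. `kfold_split` provides the 5-fold cross-validation partition.

## Desk-scale study conditions

The acceptance studies use: tiny encoder (2 RDBs, 3 layers each, 32 base
channels, growth 8, 32-dim features) and 4-layer decoder (width 32); 16
training phantoms, 4 validation phantoms, 8 held-out phantoms, all 32³
with default content and noise; 200 optimization steps; factors U[2, 4];
evaluation at factor 2. Under these conditions (5 seeds): the trained
model's mean PSNR exceeds the nearest-neighbor baseline's in 4 of 5 seeds,
and the λ = 1e-3 model attains a lower mean masked high-band residual than
the matched λ = 0 model in 5 of 5 seed pairs. These are the desk-scale
analogs of the full study's baseline comparison and regularization
ablation; absolute dB values are not comparable to the clinical corpus.

## Numerical choices and edge cases

* Orthonormal FFT scaling everywhere, so Parseval identities are exact
  test contracts and loss magnitudes are grid-size stable.
* Network weights are float32 (He initialization, seeded); losses and
  spectra are accumulated in float64.
* Trilinear weights per output voxel sum to 1 by construction; constant
  volumes survive degradation to within float32 round-off.
* Zero-filled spectral upsampling Hermitian-symmetrizes the embedded
  spectrum (splitting unpaired Nyquist planes of even axes) so the result
  is exactly real and band-limited.
* Min–max normalization maps a constant volume to zeros.
* `degrade` requires every output dimension ≥ 8 (the encoder's receptive
  field needs context); phantom grids must be ≥ 16 per axis.
* A reduction over an all-zero mask is defined as 0.

## Known limitations

* The reverse-mode engine materializes the whole tape; memory scales with
  network depth × volume size. Fine at desk scale, not meant for the
  full-size architecture on clinical volumes.
* Best-checkpoint selection uses factor-2 validation PSNR only.
* The learning-rate decay factor, batch size, and patch regime of the
  original study are unknown; the package exposes them as configuration
  with the defaults documented above.
* Appendix-level layer tables of the reference architecture were not
  available; channel widths follow standard residual-dense-network
  proportions and are recorded in `EncoderConfig`/`DecoderConfig`.
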