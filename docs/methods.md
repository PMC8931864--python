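# Methods

This note records the models implemented in `cimphase`, their assumptions,
the parameters that matter, and the design choices made where the physics or
the published recipe left the design open.

## Phase scenes

A scene is a 2-D phase map (radians) at a stated wavelength and pixel size;
samples are treated as pure phase objects (unit amplitude), which is the
standard thin-transparent-specimen assumption of QPI.

* **Bead scenes.** A projected sphere: thickness `2*sqrt((d/2)^2 - r^2)`,
  phase `(2*pi/lambda)*(n - n0)*thickness`, peak `2*pi*d*(n - n0)/lambda`.
  The default constants (1 um polystyrene bead, n = 1.588, in oil,
  n0 = 1.518, 623 nm) give 0.71 rad and anchor both reconstruction pipelines
  to an analytic value. Bead validation uses 25 nm object-space sampling so
  the bead spans 40 pixels: the sideband filter of the DPM reconstruction
  must pass essentially all of the bead's spectral energy for the peak to
  be meaningful, which sets the sampling, not the camera geometry.
* **Cell fields.** Sums of elliptical super-Gaussian blobs with randomized
  centre, radius, eccentricity, orientation and peak amplitude; a fraction
  receives a difference-of-Gaussians central dimple as a purely visual
  stand-in for the erythrocyte torus (no biophysical claim). The sum is
  clipped at the upper bound of `phase_range` so overlaps cannot exceed the
  stated dynamic range. All generators are pure functions of
  (parameters, seed), with a single `numpy` Generator per call.
* **Dynamic sequences.** Independent smooth Gaussian random fields confined
  to the object support, rescaled to a prescribed RMS (default 0.05 rad,
  the scale of nanometre membrane fluctuations), 100 ms frame interval
  stored as metadata.

## DPM forward model and reconstruction

Forward: `I = |s * exp(i*(phi + bg)) + r * exp(2*pi*i*(fx*x + fy*y))|^2` with

* carrier `(fx, fy) = (0.25, 0.25)` cycles/pixel by default — the grating
  period and camera pitch are instrument constants not fixed here, and the
  diagonal carrier maximizes DC/sideband separation;
* speckle `s = (1 - c) + c*h`, `h` a correlated circular Gaussian field
  (Gaussian-smoothed to the stated grain size, unit mean power), `c` the
  speckle contrast — a partially developed speckle model chosen because the
  artifact is named but not modelled in the source instrument description;
* a random order-2 background polynomial of stated amplitude (radians), and
  additive Gaussian shot noise scaled to the mean intensity;
* illumination 532 nm, exposure metadata 2 ms.

Inverse (Hilbert / sideband method): demodulate against the carrier,
low-pass with a hard circular mask of radius `0.5 * |carrier|` (the standard
off-axis condition; configurable), inverse FFT, take `-angle` (sign pinned
by the round-trip test), unwrap with reliability-sorted 2-D unwrapping
(scikit-image), then remove the background: preferably by subtracting the
reconstruction of a no-sample calibration interferogram, otherwise by a
fitted order-2 polynomial. The polynomial fit is iteratively sigma-clipped
(4 iterations, 2 sigma) so that sample pixels do not contaminate the
background model; this requires genuinely empty background in the field of
view, which the default study conditions provide. The median of the result
is pinned to zero (empty-background level). Cross-wavelength comparison
multiplies by the wavelength ratio (e.g. 532/623), since phase is inversely
proportional to wavelength at fixed optical path difference.

Hard-mask filtering of a non-periodic frame rings at the borders; the
round-trip tests therefore use scenes that are band-limited on the FFT torus
(periodic smoothing), isolating the property actually claimed — exact
inversion when the scene bandwidth fits inside the sideband filter.

## SLIM forward model and reconstruction

The ring-aperture/SLM geometry is reduced to its essential effect: the
unscattered component `U0` is the spatial mean of the complex field
`U = exp(i*phi)` and is the component whose phase is stepped. Frames are
`I_delta = |U0*exp(i*delta) + (U - U0)|^2`, `delta in {0, pi/2, pi, 3pi/2}`,
623 nm; the 20 nm LED bandwidth is not spectrally modelled — SLIM's low
noise is emulated by low/zero shot noise relative to DPM. Halo and
partial-coherence artifacts are out of scope.

Reconstruction uses the exact pointwise identities
`I_0 - I_pi = 4|U0||U1|cos(dphi)`, `I_{pi/2} - I_{3pi/2} = 4|U0||U1|sin(dphi)`,
`sum I_delta = 4(|U0|^2 + |U1|^2)`, solves the quadratic for
`beta = |U1|/|U0|` taking the weak-scattering root `|U1| <= |U0|`, and
assembles `phi = atan2(beta*sin(dphi), 1 + beta*cos(dphi))`, i.e.
`arg(U/U0)`. This inverts the forward model to numerical precision wherever
the weak-scattering root is the true one; the dataset's study conditions
(sparse cells, sub-radian peaks) are chosen to stay in that regime, which is
also the regime of the bead validation. Negative discriminants under noise
are clamped with a warning. The global phase of `U0` is unobservable; the
background is pinned to the image median.

## Registration

The DPM arm carries an extra 2.5x 4-f relay, so a DPM frame is a magnified
central crop of the SLIM field. With a fixed bench the mapping is scale +
translation (rotation fixed at zero). The scale is found by a deterministic
search (40-point geometric grid over the stated bounds, then golden-section
refinement) maximizing the normalized cross-correlation of the rescaled
moving view's central window inside the fixed image; translation is the NCC
peak with parabolic subpixel refinement. Windowed NCC was chosen over
Fourier–Mellin log-polar correlation because at 2.5x the shared content is
only 16% of the fixed frame, which defeats global spectral-magnitude
matching, and over phase correlation because spectral whitening is
noise-dominated on smooth phase images. Accuracy on clean synthetic pairs:
better than 1% in scale and 0.5 px in translation.

Dataset assembly registers once per acquisition run using a dense sub-micron
bead field (a calibration target, imaged through both simulated arms with
the configured noise), mirroring bench practice; the transform is then
applied to every pair. Pairs live on the DPM (magnified) grid — the grid
the network sees — with the SLIM truth resampled onto it (bicubic, on phase
values, never on raw intensities).

## The translator network

Architecture (compact U-Net variant): four encoder stages of
16/32/64/128 channels, 256-channel bottleneck, mirrored decoder with skip
concatenations. Each stage is two (3x3 conv, batch norm, ReLU) operations
with a 1x1-convolution residual shortcut summed after the pair (the shortcut
is 1x1 even when channel counts match); 2x2 max-pool downsampling; 2x2
transposed-convolution upsampling; dropout 0.25 after encoder stages 3 and 4
and the bottleneck (three sites — the published description fixes the count
and region but not the rate or exact stages); final 1x1 convolution, linear
output. All convolutions are same-padded, so output shape equals input
shape; sides not divisible by 16 are reflect-padded and cropped back.
Total: 2,031,553 trainable parameters, within the 3.3e6 budget; the bound is
checkable against any `NetConfig` variant via `count_parameters`.

The layers are implemented directly on numpy arrays with explicit
forward/backward passes (im2col + GEMM convolutions) and an Adam optimizer;
every layer gradient is verified against central differences in the test
suite. The final 1x1 convolution is initialized to zero kernel and 0.5 bias
so optimization starts from the mid-range constant prediction instead of the
(large-variance) random feature stack. Training is deterministic given the
seed: one generator drives the split, crop sampling, dropout masks and
initialization.

Training recipe: inputs and targets affinely scaled from [-pi, pi] to
[0, 1] (out-of-range pixels clipped and counted); per epoch one random
square crop per training image (uniform over valid offsets); MSE loss; Adam
with decay rates (0.9, 0.999). Defaults follow the published full-scale
recipe (learning rate 6e-5, batch 4, crop 400, 1000 epochs); desk-scale runs
use smaller crops/epochs and a larger learning rate, which changes the
optimization schedule, not the model. The checkpoint with minimum validation
loss is selected; the per-epoch train/validation loss history is kept on the
results object (`plot_history`). The 80/10/10 train/validation/test split is
by field of view (no published ratio; a standard choice). Validation loss
may be computed on centre crops (`val_crop`) to keep per-epoch model
selection cheap on CPU.

Weights are exchanged through a single HDF5 file,
`/layers/<name>/{kernel,bias,bn_gamma,bn_beta,bn_mean,bn_var}` plus the
configuration as a YAML string and the loss history; round trips are
bit-exact and shape-tampering is reported with the offending layer named.

## Metrics

PSNR `10*log10(peak^2/MSE)` with peak 1 on [0, 1]-scaled images (the peak
convention is recorded in the report); identical images report an infinity
sentinel. Pearson correlation over flattened pixels (undefined on constant
images, by error). SSIM with `C1 = (0.01 L)^2`, `C2 = (0.03 L)^2`, `L = 1`
(standard stability constants), evaluated per 11x11 Gaussian window
(sigma 1.5) and averaged with the edge-contaminated border discarded; a
global single-window mode evaluates the printed formula once on whole-image
statistics. The local implementation is cross-checked against scikit-image
in the tests.

## Synthetic study conditions, and what passing does not show

The paired dataset emulates the published acquisition geometry: one scene
per field of view; clean SLIM ground truth (four noiseless frames); a
speckled, background-contaminated single-shot DPM view through the 2.5x
relay at 532 nm, wavelength-normalized to 623 nm; registration by bead
target. Default conditions: 256-pixel fields at 0.1 um/pixel, 12 cells of
1.0–2.5 um radius per field, peaks 0.3–0.9 rad (a thin smear; also the
weak-scattering validity regime of the SLIM model), speckle contrast 0.25
with 6 px grains, 0.6 rad background polynomial, 1% shot noise. On 50 such
pairs, a 40-epoch desk-scale training improves held-out PSNR, Pearson and
SSIM over the raw DPM input.

What this shows: the full pipeline — simulation, reconstruction,
registration, training with validation-argmin checkpointing — is correctly
wired, and the network learns to remove exactly the degradations the DPM
model injects. What it does not show: performance on real blood smears.
Real data have halo artifacts, focus drift, camera nonlinearity, sample
dynamics between the four SLIM frames, and cell morphology far richer than
super-Gaussian blobs; published test-set figures on real data are therefore
not comparable to, and not reproduced by, these synthetic runs.

## Numerical choices and degenerate inputs

* Carrier validation: magnitude strictly inside (0, 0.5) cycles/pixel;
  carrier estimation searches one spectral half-plane, excludes a 3-bin DC
  guard, and raises a no-carrier error when the best peak is under 5x the
  median spectral magnitude (e.g. constant images).
* Sideband/DC proximity warns rather than fails (best-effort result).
* SLIM discriminant clamping tolerance: 1e-6 of the total frame energy.
* Unwrapping inputs are reduced to (-pi, pi] before reliability-sorted
  unwrapping; outputs are congruent to the input modulo 2*pi.
* Registration raises when the best NCC stays below 0.2 (uncorrelated
  content); template insets and a 20 px search margin bound the detectable
  translation.
* Max-pool gradient ties are broken toward the first maximum (measure-zero
  for continuous data).
* Batch-norm eval mode uses running statistics (momentum 0.1, eps 1e-5);
  dropout is inactive at inference, so repeated inference is bit-identical.

## Known limitations

* The SLIM model's ideal-DC decomposition makes reconstruction exact only in
  the weak-scattering regime (`|U1| <= |U0|` pointwise); dense or
  high-phase scenes pick the wrong quadratic root locally. The generators'
  defaults stay inside the regime, and the limitation is inherent to the
  four-frame model reduction, not to the inversion code.
* The hand-written CNN trains on CPU at desk scale (seconds per epoch at
  64-pixel crops); the published 1536-pixel, 1000-epoch regime is
  configurable but not a practical CPU target.
* Rotation between the arms is assumed zero and not estimated.
* No pupil/NA resolution model: both arms share the scene's pixel grid, so
  resolution differences between the modalities are not emulated.
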