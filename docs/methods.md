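# Methods

This note documents the models, numerical choices and study conditions
behind `bpfscope`, in the package's own words. Nothing here reports a
number that the test-suite or `scripts/acceptance.py` does not itself
compute.

## Imaging model and assumptions

The forward model is scalar Fourier optics for an incoherent, aberration-free
wide-field microscope at a single wavelength. The pupil is sampled on an
N×N grid with a circular aperture of diameter D pixels; the normalized
radius ρ reaches 1 at the cutoff NA/λ. Defocus enters as the quadratic
pupil phase exp(−i2πψρ²) with ψ = z·NA²/(2λn), which is the standard
paraxial defocus parameter — accurate for NA ≲ 0.8 and not intended for
immersion objectives (NA > 1) or depth-dependent index mismatch. PSFs are
computed with orthonormal FFTs so a phase-only pupil conserves energy
exactly (the raw PSF sums to the pupil pixel count for any phase map and
any ψ); every PSF is then normalized to unit total energy so image
intensity does not depend on defocus.

Image formation convolves the scene with the PSF using reflective padding
(avoiding wrap-around on textured scenes), min–max normalizes the result to
[0, 1], and adds Gaussian noise of σ = 0.05 on that scale. The noisy image
is not clipped internally; clipping happens only on image export.

**Sampling.** The image-plane pitch is δx = λD/(2·NA·N). The default
D = N/2 gives δx = λ/(4NA) — twice the Nyquist rate of the incoherent
cutoff — so PSFs are alias-free, and δx (0.175 µm at the reference optics)
slightly oversamples the camera pitch e/M ≈ 0.195 µm. Two modes are
offered: "PSF accuracy" for profile work (use a larger N/D ratio, e.g.
δx = 0.0875 µm, for FWHM fitting), and a "camera" mode that rebins PSFs to
e/M by area-weighted (energy-conserving) binning before convolution.

## Filter parameterization and binarization

The design is a vector of K ring phases on concentric annuli of equal
radial width (ρ_k = k/K; edges are a parameter, so equal-area layouts can
be configured). Phases live in [−π, π] and are re-wrapped after every
update; values already in range pass through bit-exactly. The penalization
polynomial P(φ) = φ⁷/7 − 2π²φ⁵/5 + π⁴φ³/3 has derivative
P′(φ) = φ²(φ−π)²(φ+π)² ≥ 0 with zeros exactly at {−π, 0, π}; the feature
loss ‖P′(φ̄)‖₂ is therefore zero precisely when the design is binary.
Binarization maps |φ| ≥ π/2 to π (midpoint between the wells) and is
idempotent. For fabrication, a π step at design wavelength λ₀ requires an
etch depth d = λ₀/(2(n_substrate − n_air)); the phase the etched rings
impart at another wavelength is φ(λ) = 2πd(n(λ) − n_air)/λ, ignoring
substrate dispersion unless an index at λ is supplied.

## Joint training

The end-to-end loss is the batch-mean per-image RMSE between the network
output and the ground truth, plus α·L_BPF. The penalty weight is annealed
geometrically, α(epoch) = α₀·g^epoch with α₀ = 10⁻⁶ and g = 10 over 10
epochs — the standard penalty-method schedule; by the final epochs the
penalty dominates and every ring settles into a well. Defocus is drawn per
sample, uniform on ±ψ_max with ψ_max = ψ(target·DoF_clear/2). After the
joint phase the design is binarized and the network alone is fine-tuned on
the binary filter (the deployed condition) for a configurable number of
steps.

Gradients through the network come from a small reverse-mode autodiff
engine written on numpy (im2col convolutions backed by BLAS); gradients
through the optical stage — ring phases → pupil → |FFT|² → unit-energy
normalization → reflective-padded convolution → min–max normalization —
are applied analytically as vector–Jacobian products. The min/max in the
normalization uses the subgradient at the first arg-extremum; the energy
normalization uses the quotient rule over the (odd-cropped) PSF support.
The complete chain is verified against central finite differences to
~10⁻⁸ relative accuracy in the test-suite.

Optimization uses Adam for both parameter groups (network 2·10⁻³ with
cosine decay to a 10 % floor; phases 2·10⁻²). Adam for the phases is
deliberate: its normalized steps let the annealed penalty carry every ring
to a well within a 200-step budget, which plain gradient descent cannot do
(an option `phase_optimizer="gd"` exists for experimentation). Polyak
averaging of the network weights is available (`ema_decay`) but off by
default — at 300-step budgets it blurs rather than helps. Non-finite
losses abort with the offending step's state. A single seed drives scene
selection, augmentation (random 90° rotations/flips, training split only),
defocus draws, noise and weight initialization; identical seeds reproduce
the full training history bit-for-bit.

**Network.** An encoder–decoder with skip connections: two 3×3 conv+ReLU
layers per level, 2× average-pool downsampling, nearest-neighbour
upsampling with skip concatenation, and a 1×1 residual head added to the
input. The head is zero-initialized, so a fresh network is exactly the
identity — a natural starting point for restoration and the reason an
untrained checkpoint passes inputs through unchanged. Full-scale default:
depth 4, base 32 channels; desk scale: depth 3, base 16.

## Depth-of-field protocol

SSIM is computed from global image statistics — means, variances and the
covariance of the two whole images — with C₁ = 10⁻⁴ and C₂ = 9·10⁻⁴,
exactly as the defining formula states (no sliding window; a windowed
variant is available behind a flag). For each z on a symmetric grid the
scenes are imaged with noise, reconstructed, and scored; curves report the
mean and standard error over scenes. The DoF estimate is the length of the
maximal contiguous interval containing z = 0 on which mean SSIM ≥ 0.900,
with the crossings located by linear interpolation between grid samples;
if even the in-focus SSIM falls below threshold the DoF is 0 by
definition. The extension ratio divides by the clear-aperture DoF measured
under the identical protocol with no reconstruction network — restoration
networks are trained for every pupil except the clear aperture, whose
unprocessed image is the baseline.

FWHM analysis fits amplitude·exp(−(x−x₀)²/2σ²)+offset to profiles through
the PSF peak along both axes (averaged), FWHM = 2√(2 ln 2)·σ; fit failures
raise rather than default. Contrast uses the Michelson convention
(max−min)/(max+min).

## Synthetic scenes and phantoms

The scene generator stands in for a large histopathology training corpus:
a random-phase texture with power-law radial power spectrum (default
exponent −1.5) composited with elliptical Gaussian blobs and smoothed
random-walk filaments, min–max normalized to [0, 1]. Because real ground
truths are themselves micrographs from a finite-NA (0.9) objective, scenes
carry an acquisition band limit, modelled as a Gaussian blur of σ = 0.6 px.
That width was calibrated once against the anchor the DoF protocol itself
prescribes: the clear-aperture SSIM should pass ≈ 0.90 at the analytic DoF
edge (±DoF_clear/2) with in-focus SSIM ≈ 0.92. Under this calibration the
measured clear-aperture DoF (≈ 1.5 µm) sits close to the analytic 1.19 µm,
making threshold, scene statistics and protocol mutually consistent.

What the generator does **not** emulate: diagnostic semantic content,
stain-specific chromatic structure, spatially varying illumination, and
shot-noise statistics (noise is additive Gaussian). Passing desk-scale
tests therefore demonstrates the mechanics and the optics of the method,
not clinical image quality.

Bead phantoms render sub-resolution fluorescent microspheres (0.175 µm,
well below λ/2NA) as Gaussian spots of that FWHM at sub-pixel positions,
with a rejection rule enforcing ≥ 3 PSF-FWHM separation. Because the bead
diameter is half the diffraction FWHM, its size is *not* negligible in a
width measurement: the expected bead-image FWHM is the PSF width broadened
in quadrature, √(FWHM_PSF² + d_bead²) (≈ +11 %). The bead cross-check
compares the fitted bead-image width against that prediction.

## Desk-scale study conditions

The full-scale design (64 rings, 16× DoF target, ~25 000 training images,
GPU-hours of U-Net training) is not reproducible on one CPU in minutes, so
the end-to-end property tests run a scaled-down protocol whose problem
sizes were fixed as the package's own choice: 64×64 scenes (64 training, 8
held-out for evaluation), K = 16 rings, depth-3/base-16 network, 10
epochs × 20 joint steps + 100 binary-filter fine-tune steps (300 optimizer
steps in total), batch 8, σ = 0.05, evaluation on z ∈ [−8, 8] µm in 0.5 µm
steps, fixed seed. The DoF *target* scales with the ring count: the design
family budgets roughly 4 rings per unit of DoF extension (64 rings for a
16× design, 128 for 24×), so the 16-ring desk design targets 4×
(ψ_max ≈ 1.28). The initializer is a phase axicon of slope π, selected by
a network-free screen of axicon/spherical initializations for a centered,
single-lobe extended focus — the initial condition matters substantially
for where this non-convex optimization lands.

**Known limitation.** At this scale the RMSE objective over uniformly
sampled defocus consistently converges to an outer π-annulus design whose
inner-disc and ring areas nearly cancel on the optical axis, i.e. an
extended focal *shell* with a weak exact-focus plane. The trained system
then holds SSIM ≥ 0.9 over a total axial extent of roughly three clear
apertures, but with a shallow dip right at z = 0 that sits a few hundredths
below threshold — and the DoF definition (contiguous interval containing
z = 0) scores that as zero. Specialist retraining at the focal plane and
linear (Wiener) baselines show the focal plane of this mask family is
genuinely information-poor, so this is a property of the desk-scale
optimization landscape (16 rings, 300 CPU steps, small network), not a
defect of the gradient machinery — which is verified against finite
differences. The corresponding acceptance test is left failing rather than
weakened; at full scale the restoration network's far higher capacity is
what lifts the focal plane well above threshold.

## Numerical choices and degenerate inputs

- Orthonormal, center-shifted FFTs everywhere; the pupil grid center is at
  pixel (N//2, N//2), matching `fftshift` conventions.
- Even-sized PSFs are cropped to odd support (dropping the first row and
  column, then renormalizing) so that "same-size" convolution alignment is
  unambiguous; the training gradients account for the renormalization.
- Ring lookup uses the half-open convention [ρ_{k−1}, ρ_k); a pixel exactly
  on an interior edge belongs to the outer ring; ρ = 1 exactly is inside
  the aperture and assigned to the outermost ring.
- Min–max normalization of a constant image returns zeros; training
  gradients vanish there.
- Tiled reconstruction blends overlapping patches with separable linear
  feather windows and divides by the accumulated weights, making the blend
  an exact partition of unity (an identity network reproduces the frame to
  machine precision, seams included). Default: 576 px tiles, 10 % overlap;
  multichannel frames are processed channel-by-channel with the same
  single-wavelength network.
- Wiener deconvolution embeds the centered PSF at the image size and rolls
  its peak to the origin; `nsr = 0` is the exact inverse filter and is only
  meaningful for non-vanishing OTFs.
- Gaussian FWHM fits start from moment-based estimates; non-convergence
  raises `FitError`.

## Limitations

Scalar, paraxial, aberration-free, single-wavelength optics; no
Gibson–Lanni or vectorial model; no spatially varying aberration; no
photolithography mask layout (the export is a ring table + etch depth); no
registration-based whole-slide stitching (grid mosaic with feathering
only); synthetic scenes as described above.
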