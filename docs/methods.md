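# Methods

## The thermometric model

A single quantum dot's emission spectrum is modeled as a Gaussian in
wavelength, amplitude·exp(−(λ−μ)²/2σ²), with μ ≈ 651 nm and
σ ≈ 11.1 nm for the emulated 655 nm emitter. The thermometric
parameter is the band-intensity ratio

    R = I_high / I_low,
    I_low  = ∫ spectrum over [λm − w, λm),
    I_high = ∫ spectrum over [λm, λm + w),

with λm = 650 nm and w = 20 nm by default. The bands are half-open so
the shared boundary at λm counts exactly once; the customary way of
quoting them ("630–650 and 650–670 nm") makes the boundary look
double-counted, but it is a measure-zero point for the integrals. On a
sampled spectrum the integrals are trapezoidal on the supplied grid
with interpolated band edges; the closed form for a Gaussian spectrum,

    R(μ, σ) = [Φ((λm+w−μ)/σ) − Φ((λm−μ)/σ)] / [Φ((λm−μ)/σ) − Φ((λm−w−μ)/σ)],

(Φ the standard normal CDF) serves as the reference oracle and is
exactly 1 when μ = λm. R is invariant to any global gain on the
spectrum — the reason a ratio survives photobleaching and focus drift.

Two temperature-response parameterizations coexist:

- **shift**: μ(T) = μ_ref + 0.105 nm/°C · (T − T_ref), with R following
  from the closed form. This is the physical picture of the band-edge
  red shift.
- **empirical-linear**: R(T) = R_ref + 0.062/°C · (T − T_ref), the
  measured single-particle response.

They disagree: the shift-only model with σ = 11.1 nm predicts
dR/dT ≈ 0.015/°C, a quarter of the measured 0.062/°C. Intensity
quenching or spectral-width changes presumably contribute, but the
mechanism is not settled, so the package keeps both models and uses the
empirical one for all temperature conversion; nothing in the code
guesses at the mechanism. The synthetic spectrum generator accepts
either kind — for the empirical-linear kind it inverts the closed form
(Brent root-finding on μ) so the spectral and ratio layers agree by
construction.

Relative sensitivity S = |dQ/dT|/Q compares thermometers with
different parameters Q; with Q = R ≈ 1 and dR/dT = 0.062/°C, S is
≈ 6%/K. `sensitivity_scan` reports S over a temperature range and its
maximum S_m.

## Photobleaching and calibration

Repeated acquisition bleaches the ratio itself toward an equilibrium:

    R(t) = (R0 − Req)·e^(−λt) + Req,

fitted by bounded nonlinear least squares (λ ≥ 0; initial values
R0 = first sample, Req = last sample, λ = 2/span). The default
emulated protocol is one frame per second, 500 frames, λ =
0.00635 s⁻¹. Correction is **multiplicative** detrending to the t = 0
level, R_cal = R_raw · R_model(0)/R_model(t), because the ratio is
scale-like; a pure model trace corrects to a constant exactly, and a
λ = 0 model is the identity. (Additive detrending would instead
subtract R_model(t) − R_model(0); the multiplicative form was chosen
once and is the only one wired in.)

Calibration fits ordinary least squares of R on stage temperature per
particle (temperature is the controlled variable), requiring ≥ 3
points spanning ≥ 2 °C; the default design is 30–42 °C in 1 °C steps.
The ensemble sensitivity is the arithmetic mean of per-particle slopes.
Pooling points across particles before regressing is deliberately not
done: intercept heterogeneity between particles (their individual
baseline ratios differ more than their slopes) dilutes the pooled
correlation well below the per-particle ones, which the
`aggregate_slopes` report surfaces as `pooled_r`.

Measurement resolution is the normal-quantile half-width z·s of
repeated calibrated measurements at constant temperature, with s the
sample standard deviation of *individual* measurements — a population
interval, not a standard error of the mean. The rationale: the
resolution answers "how large must a single measured ratio change be
before it exceeds measurement scatter", and an SEM at n = 500 would
absurdly claim a resolution forty times finer than any single
measurement supports. At 95% confidence and s = 0.05 this gives 0.098
in ratio units (≈ 1.6 °C at the mean slope); whether a published
resolution of this kind is an interval on single measurements or on a
mean is often ambiguous — this package's choice is the former,
documented here, not asserted as anyone else's intent.

Reversibility is a pass/fail check on two-temperature cycling: for
each set point the per-cycle values are compared with their mean, and
the check passes when the largest deviation stays within the
resolution half-width.

## Photometry and quality control

Candidate spots are local maxima of the channel-summed image above
median + 8·(1.4826·MAD); adjacent tied maxima (sampling plateaus of a
symmetric spot) merge silently, and distinct candidates closer than
the minimum separation are non-maximum suppressed with the survivor
flagged `overlapping`. Each candidate is fitted with an isotropic 2D
Gaussian plus constant background; fit failure, zero amplitude, or
amplitude below 3× the residual rms raises the `non_gaussian` flag
(aggregates do not fit a single Gaussian). Diameter is the fitted
FWHM, 2√(2 ln 2)·σ_xy ≈ 2.3548 σ_xy — the standard single-particle
convention; the alternative (thresholded-area equivalent diameter) was
not used. Note the image-domain FWHM convolves emitter size with the
PSF, so rendered and re-measured diameters include the PSF
contribution in quadrature.

Channel intensities are background-subtracted aperture sums (circular
aperture, pixel-center inclusion; background = median of a 2×–3×
radius annulus, per channel). Because the annulus bias is proportional
per channel and the flat background is common, the extracted ratio is
exact on noise-free renders and invariant to a global gain.

The diameter gate retains spots strictly between cohort mean ± sample
standard deviation (ddof = 1); ties on a threshold are excluded, and a
zero-variance cohort degenerates to "retain all" with a flag in the
report. The axial gate accepts focal planes within ±0.25 µm of the
smoothed intensity peak (11 planes at the 0.05 µm stepping), where the
ratio is empirically flat; a profile with no interior peak is an
error, not a gate.

## Thermometry

Per-particle intercepts are unknowable in advance, so only ratio
*differences* convert to temperature: ΔT = ΔR / slope. A response is
classified against the resolution half-width (increase / within
resolution / decrease on the sign and magnitude of ΔR). Compartment
comparisons use a two-sided Welch t-test (unequal variances) on the
ratio samples, with a permutation test (difference of means, label
reshuffling) available as a distribution-free cross-check; zero-variance
degenerate groups short-circuit to p = 1 (equal means) or 0. The
default conversion slope is the ensemble mean calibration slope
(0.062/°C); an intracellular calibration can be substituted where
available.

## 3D morphometry

Volume is the foreground voxel count times the voxel volume. Surface
area comes from a level-0.5 marching-cubes mesh of the binary mask,
Gaussian-smoothed with σ = 1 voxel beforehand: raw binary marching
cubes overestimates a sphere's area by ~9% (and voxel-face counting by
~50%), while the smoothed estimator recovers a sphere of 50 voxels
radius to ~0.3% and converges monotonically as voxels shrink.
Anisotropic voxels enter through the mesh spacing; the smoothing is
isotropic in voxel units, so strongly anisotropic stacks trade a little
physical isotropy of the smoothing for simplicity. Two caveats are
measured and accepted: (i) smoothing rounds sharp edges, so a cube's
area is underestimated by ~1% at 150 voxels per side (worse for small
cubes); (ii) the estimator can push a coarse sphere's *measured*
sphericity slightly above 1 (e.g. 1.06 at 6 voxels per radius) even
though exact sphericity obeys Ψ ≤ 1 — sphericities within a couple of
percent of 1 should be read as "sphere-like", not ranked. Objects
thinner than ~4 voxels across (relevant for neurite-like cylinders)
need finer voxels for trustworthy areas. Segmentation is Otsu or fixed
threshold, small-object removal, then the largest 26-connected
component.

Sphericity Ψ = π^⅓(6V)^⅔/A and specific surface area A/V are computed
from these estimates; compartment comparisons report the ratios of
sphericity, specific surface area, raw surface area and volume — both
raw and specific area ratios are given because "a neurite's surface
area is larger than the cell body's" is only meaningful per volume,
and the package does not decide which reading a user wants.

## Synthetic data: what it emulates and what it does not

Defaults encode the study conditions: 600–700 nm spectra sampled every
2 nm; bleach traces at 1 s × 500 frames with λ = 0.00635 s⁻¹;
calibration at 30–42 °C in 1 °C steps with per-particle slopes
(0.074, 0.053, 0.060)/°C; z-profiles stepped at 0.05 µm with a
±0.25 µm ratio plateau; stimulus time courses sampled every 30 s with
a +0.058 ratio step. No detector model was reported for the emulated
instrument, so the image generator uses a generic one chosen once:
Poisson shot noise on counts, Gaussian read noise of sd 2 counts, flat
background of 5 counts/pixel. Calibration intercepts are likewise
unreported; the generator draws them around −1.0 (giving ratios of
0.9–1.6 over the design range at the default slopes, the right order
of magnitude) with a configurable spread for heterogeneity.

Spots render as 2D Gaussians with σ² = σ_PSF² + (d/2.3548)², counts
split 1 : R between channels, conserving total counts exactly before
noise. Blinking is off by default; a two-state telegraph process is
available for robustness tests. The phantoms (sphere, cube,
soma sphere + neurite cylinder) carry closed-form area and volume.

Passing round-trip tests on these data shows the estimators are
correct *for the generating models*: a real instrument adds optical
aberrations, non-Gaussian spectra and PSFs, stage drift, blinking,
autofluorescence and segmentation ambiguity that the generator does
not emulate. In-cell quantities that depend on real biology (the CCCP
response magnitude, response-class counts, measured compartment
sphericities, the pooled in-cell correlation) are therefore covered by
qualitative property tests, not numeric reproduction.

## Problem sizes and numerics

Monte-Carlo checks use 200 replicates (bleach-constant recovery at
noise sd 0.02; spectrum-fit recovery at 2% noise). Voxel phantoms for
the closed-form checks use a 10 µm-radius sphere and a 30 µm cube at
0.2 µm voxels (≈ 1–4 M voxels), small enough to run comfortably in a
test suite while keeping voxelization error inside the stated 2%
bands. Curve fits everywhere are Levenberg–Marquardt (or bounded
trust-region) via `scipy.optimize.curve_fit` with analytic-free
initialization chosen for unimodal data: weighted moments for spectra,
endpoint values for bleach traces, window extrema for spots.
Degenerate inputs (constant spectra or traces, flat fit windows,
all-equal diameters, monotone z-profiles, empty segmentations) raise
typed errors rather than returning silently wrong numbers.
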