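# Methods

## Rotation descriptions and conventions

The knee is the rotation of the shank relative to the thigh.  All
quantities are expressed in the thigh coordinate system; the relative
rotation matrix `R` holds the shank X, Y, Z axes in its columns
(equivalently, the table of dot products between shank and thigh axes,
formed from world orientations as `R = T^T S`).  Three descriptions are
interconverted:

* **Cardan ZXY**: `R = Rz(θ1) Rx(θ2) Ry(θ3)` with θ1 flexion–extension
  about the thigh Z axis, θ2 adduction–abduction, θ3 internal–external
  rotation.  Extraction uses θ2 = asin(R₃₂), θ1 = atan2(−R₁₂, R₂₂),
  θ3 = atan2(−R₃₁, R₃₃) and raises a gimbal-lock error for
  |R₃₂| ≥ 1 − 1e−9.
* **Attitude (helical)**: angle θ = acos((tr R − 1)/2) ∈ [0°, 180°] and
  unit axis **k** from the skew part (R − Rᵀ)/(2 sin θ).  Near θ = 180°
  the skew part vanishes and the axis is recovered as the invariant
  direction of `R` (null vector of R − I), with the sign taken from the
  residual skew part.  Below θ ≈ 6e−5° the axis is unidentifiable; the
  documented fallback is the nominal flexion axis [0, 0, 1] plus a
  degeneracy flag.  The Rodrigues reconstruction is
  `cos θ I + sin θ [k]ₓ + (1 − cos θ) k kᵀ`.
* **JCS projection**: joint axes **e**₁ = [0, 0, 1] (thigh Z),
  **e**₃ = second column of `R` (shank Y),
  **e**₂ = (**e**₃×**e**₁)/‖**e**₃×**e**₁‖, and the non-orthogonal
  projection of the attitude vector θ**k** given in the README.  The
  construction degenerates when ‖**e**₃×**e**₁‖ ≤ 1e−6 (shank long axis
  aligned with the flexion axis) and the projection when the mixed
  product |e₁×e₂·e₃| < 1e−9.

Degrees are used at every public interface and file format; radians
internally.  Gait cycles are 101 frames at 0–100% of the cycle.  Along a
cycle the (θ, **k**) vs (−θ, −**k**) ambiguity is resolved by requiring
consecutive axes to have positive dot products, interpolating axes of
degenerate frames from their neighbours, and finally orienting the whole
cycle so the axis points along +Z of the thigh on average.  The signed
rotation angle that results is comparable across trials even when the
motion crosses zero, which matters for variability statistics.

The projected components and the Cardan angles agree to first order
(they are identical on a pure hinge), but they are *not* numerically
close at large flexion with non-zero offsets: the difference behaves
like flexion × offset (about 2.4° at 60° flexion with a 5° rotation
offset).  The test suite asserts the first-order property — exact hinge
agreement and linear shrinkage of the difference with the offsets — not
a fixed small bound.

## Uncertainty model

The seven independent parameters are x = (θ, kₓ, k_y, e₁ₓ, e₁_y, e₃ₓ,
e₃_z); the main-direction components kz, e₁z, e₃y are recovered from the
unit norms and required positive (knee convention: rotation and flexion
axes along +Z of the thigh, shank long axis along +Y).  Each output
y = f/g (common denominator g = e₁×e₂·e₃, with e₂ substituted by its
construction so f and g depend only on the seven parameters) carries the
first-order variance

u²(y) = 1/g⁴ Σᵢ (g ∂f/∂xᵢ − f ∂g/∂xᵢ)² u²(xᵢ)

with all inputs uncorrelated.  Input uncertainties: u(θ) directly (in
radians internally), and per axis a cone of half-angle α about the main
direction, mapped to a standard uncertainty tan(α) on each of the two
free components, independently and identically.  α is a half-angle: the
tan(α) displacement of the axis tip only makes sense for the half-angle
deviation.  The four sources {θ, k, e₁, e₃} contribute squared terms
that sum exactly to the combined variance (the implementation computes
the combined value as the root of that sum, so additivity is exact by
construction); outputs are not additive in standard-deviation units.

Partial derivatives are generated symbolically with sympy on first use
and cached for the process lifetime; the test suite validates all 28
partials (7 parameters × (3 numerators + shared denominator)) against
central finite differences of an independent plain-numpy forward model
at 200 random poses to 1e−6 relative error.

The linearization point along a gait cycle is the across-trial mean
pose per frame: arithmetic mean of the signed rotation angle and
normalized arithmetic mean directions of **k**, **e**₁, **e**₃
(degenerate frames excluded from axis averaging).

### Degeneracy and domain limits

* Frames with |θ| < 1° carry an unidentifiable rotation axis; all three
  axis-cone contributions are reported as zero there with a degeneracy
  flag (the θ contribution survives).
* The parameterization breaks down when a main-direction component
  approaches zero.  On a knee template with constant varus/rotation
  offsets this happens at near-zero flexion, where the residual rotation
  axis lies almost in the thigh's transverse plane (kz ≈ 0): the
  sensitivities contain 1/kz factors and the analytic outputs spike, and
  Gaussian sampling of (kₓ, k_y) crosses the unit disk.  Such poses are
  detected (`near_domain_boundary`, main component within 4 input SDs of
  zero) and skipped by the Monte-Carlo check; first-order results at
  those frames should not be trusted.

## Monte-Carlo oracle

Verification draws Gaussian perturbations of the seven parameters
(matching the analytic input model exactly), reconstructs the axes
through the unit-norm reductions and evaluates the exact projection
equations, reporting sample SDs next to the analytic values.  Gaussian
rather than uniform-on-cone sampling is used because the variance rule
is distribution-agnostic and Gaussians make SD semantics exact.
Out-of-domain draws are rejected and resampled, with a hard error above
50% rejection to surface misuse at large cone angles.  All randomness is
seed-parameterized with no global state.  At 2° inputs the analytic and
empirical values agree within ~1.5% relative wherever the output exceeds
0.5°; the mismatch grows with input size, as expected of a first-order
model.

## Synthetic gait generator

The generator emulates a single-subject reproducibility design (default
5 sessions × 8 trials, the stance phase ending at 61.6% of the cycle).
The template flexion profile is the sum of two raised cosines — a stance
bump (default 18° peaking at a quarter of stance) and a swing bump
(default 60° at 72% of the cycle, returning to 0 at 100% so the cycle is
periodic) — with constant adduction (2°) and internal-rotation (5°)
offsets composed through the ZXY sequence.  These are conventional
normal-gait magnitudes, not a fit to any particular subject.

Noise model:

* **Intrinsic, per trial**: a smooth low-frequency offset on θ formed
  from a constant plus a first harmonic with random Gaussian
  coefficients, scaled so the framewise SD equals `sd_theta` exactly at
  every frame (white per-frame noise would be unrealistically killed by
  time-normalized averaging); plus one random tilt of the rotation axis
  per trial drawn from the `cone_k` cone.
* **Extrinsic, per session**: one fixed misorientation of the thigh
  frame (tilting **e**₁) and of the shank frame (tilting **e**₃), drawn
  once per session from the respective cones and applied to all its
  trials as `R' = Q₁ᵀ R Q₃` — marker-placement error constant within a
  session.

Default dispersions (sd_theta 2°, cone_k 3°, session cones 3°)
approximate reported single-subject knee reproducibility magnitudes.
With all dispersions zero the generator returns the template bit for
bit, and every downstream statistic is exactly zero.  Session-level
perturbations contribute to inter-session but not intra-session
variability; trial-level perturbations contribute to both.

What the generator does not emulate: soft-tissue artifact waveforms,
within-trial transients, event-detection errors, or any real subject's
flexion curve.  Passing tests therefore demonstrate the correctness and
calibration of the propagation machinery on motion with gait-like
structure, not agreement with any specific experimental dataset.

## Variability analysis

For each trial the rotation angle, axis orientation, Cardan angles and
projected components are extracted framewise.  Scalar RMSDs (the
reported equations vary across the literature; the definitions here are
this package's):

* intra-session: deviations from the per-session frame mean, pooled over
  sessions, trials and frames;
* inter-session: deviations from the grand frame mean over all trials,
  pooled over trials and frames.

Axis orientation uses the RMS angular deviation (acos of the dot
product) from the respective mean direction, with degenerate frames
excluded.  Table summaries use the arithmetic mean and the *population*
standard deviation (divisor n), which reproduces the printed summary
statistics of the published reference table used in the tests.
A single 5×8 dataset yields a θ-row RMSD estimate with roughly 9%
relative sampling SD (40 trials of 3-coefficient smooth noise), so the
calibration checks average three replicate datasets.

Qualitative agreement between an analytic uncertainty curve and an
experimental SD curve is classified per gait phase (stance up to 61.6%,
early/mid swing to 85%, terminal swing to 100%) by the ratio r of the
phase means: '−−' r < 0.5, '−' r < 0.8, '0' r ≤ 1.25, '+' r ≤ 2,
'++' above — symmetric factor bands around parity; a near-zero
experimental mean is flagged indeterminate rather than labelled.

## File formats and reproducibility

Pose CSVs come in a `relative` dialect (row-major relative rotation per
frame) and a `segments` dialect (thigh and shank world orientations),
auto-detected from the header.  Rotations are validated to 1e−6
orthonormality with row-level error reporting, then projected to the
nearest proper rotation (SVD) because the fixed 9-significant-digit
output formatting leaves round-off beyond the strict 1e−9 internal
tolerance; trials off the integer 0–100% grid are resampled by linear
interpolation of the continuity-fixed rotation vector.  All CLI outputs
embed provenance (config hash, seed, tool version) and are bit-identical
for fixed config and seed.  Configuration JSON is validated with unknown
keys rejected.

## Problem sizes

The test suite and the acceptance script use: 101-frame cycles; 5×8-trial
datasets (three replicates for the calibration average); Monte-Carlo
n = 10⁵ per checked frame at 11 frames; 200 random poses for the
finite-difference validation.  These sizes give sampling errors well
inside the asserted tolerances (MC sampling error ~0.2% relative at
n = 10⁵).
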