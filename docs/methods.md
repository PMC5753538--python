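# Methods

This note documents the models, parameter choices and numerical decisions
behind the `dtcmr` package, and what the synthetic phantom does and does not
emulate.

## The phantom

The left ventricle is modelled as a single 2D short-axis slice: an annulus
between an endocardial and an epicardial radius on a square pixel grid, with
the slice normal serving as the longitudinal direction. Within the wall:

* **Helix angle (HA)** varies linearly with transmural depth from
  `ha_endo_deg` (default +60°) at the endocardium to `ha_epi_deg` (default
  −60°) at the epicardium. Healthy human transmural ranges of roughly ±60°
  are literature-typical; the range is a parameter, not a constant. The
  convention is right-handed (endocardial HA positive, decreasing toward the
  epicardium), which makes the depth-normalised helix-angle gradient (HAG)
  positive, +1.2 °/% for the default ramp; both sign conventions are
  documented here and configurable through `LVPhantomSpec`.
* **E2A** (sheetlet elevation) is uniform over the wall per cardiac phase.
  The study driver defaults to ~60° at systole and ~20° at diastole,
  consistent with a sheetlet mobility of ~40° between the contracted and
  relaxed states; the sweet-spot phase sits midway.
* **Eigenvalues** default to (1.6, 0.8, 0.5)·10⁻³ mm²/s — literature-typical
  in-vivo myocardial values (MD ≈ 0.97·10⁻³ mm²/s, FA ≈ 0.53). The tensor at
  each pixel is assembled as Σ λᵢ eᵢeᵢᵀ with e₁ at the local helix angle in
  the wall-tangent plane, e₂ elevated out of that plane by |E2A| in the
  cross-myocyte plane, e₃ completing the triad.
* **Blood pool** pixels are rendered at 3× the myocardial S0, constant
  across frames, emulating incomplete blood-signal nulling; the background
  is empty.
* **Noise** is Rician: the magnitude of the clean signal plus independent
  complex Gaussian channels of standard deviation σ (in image units;
  σ = 0.05 with S0 = 1 corresponds to SNR ≈ 20).
* **RR jitter**: each frame's encoding-beat RR is drawn from a truncated
  Gaussian with default σ = 5 ms around the nominal RR, matching typical
  intra-subject RR variability. For STEAM frames the *true* diffusion
  weighting follows `b(RR)/b(RR_nom) = (RR − δ/3)/(RR_nom − δ/3)` from the
  Stejskal–Tanner expression with diffusion time Δ = RR and gradient
  duration δ (default 2.4 ms); the recorded metadata keeps the nominal b, so
  the beat-to-beat correction stage must recover the truth from the recorded
  RR — a closed verification loop.

What the phantom does **not** emulate: EPI/parallel-imaging reconstruction,
coil profiles, eddy currents, slice-profile effects, 3D ventricular
geometry, through-plane fibre components beyond the prescribed helix ramp,
restricted diffusion and diffusion-time dependence, and partial-volume
effects at tissue boundaries. Passing tests therefore demonstrate the
correctness of the *processing chain* under a known forward model, not the
accuracy of any sequence on real myocardium; in particular, diffusion-time
differences between STEAM and spin-echo encoding — a dominant in-vivo
effect — are absent by construction (both sequences see the same tensors).

## Acquisition protocols

Matched two-shell protocols: b_ref = 150 s/mm² and b_main = 450 s/mm² in
the same 6 non-coplanar directions. STEAM: TR = 2 RR, 8 b_main and 1 b_ref
averages, TE = 25 ms. M2-SE: TR = 1 RR, 16 b_main and 2 b_ref averages,
TE = 76 ms. The reference shell replaces "b0" images in the tensor
calculation; the small spoiler b-values of the b0 images (34/30 s/mm²)
appear only in the SNR theory, not the fit.

## Preprocessing and tensor fit

Order of operations: blood nulling → registration → restoration of the
nulled intensities → frame rejection → beat-to-beat b correction → fit.

* **Blood nulling** zeroes pixels above `threshold_factor` (default 2.0) ×
  the per-frame median myocardial intensity, keeping an exact restore
  ledger. The factor is a package default; only "very high signal
  intensity" is prescribed by the use case.
* **Registration** is rigid translation only: normalized cross-correlation
  against the series median image, integer search within ±10 px, parabolic
  subpixel refinement of the correlation peak. Sub-pixel estimates below
  0.1 px per component are treated as refinement noise and snapped to zero,
  so aligned frames are never resampled (this keeps noiseless round trips
  exact). Shifts wrap at the image edge, making integer round trips exactly
  invertible.
* **Frame rejection** is an automated surrogate for visual motion
  assessment: a frame is dropped when its correlation with the per-(b,
  direction) median image falls below 0.80. Singleton conditions cannot be
  assessed and are kept. Rejection that leaves fewer than 7 frames is an
  error (rank-deficient fit).
* **b correction** rescales each STEAM frame's b by
  `(RR − δ/3)/(RR_nom − δ/3)`; spin-echo frames pass through.
* **Tensor fit**: ordinary least squares of ln(signal) on `[1, −b·row]`
  with the 6-element b-matrix row; every frame is a separate row (no
  averaging), so duplicating a frame is exactly equivalent to doubling its
  weight. No Rician-bias correction and no iterative/robust reweighting —
  the estimator is deliberately the plain log-linear inversion. Pixels with
  any non-positive signal are flagged invalid rather than log-clipped.
  Imaging/crusher cross-terms in the b-matrix are ignored.

## Maps and conventions

Eigenvalues are sorted descending; negative eigenvalues are retained (the
pixel is flagged) because clamping before MD would bias it downward; flagged
pixels are excluded from FA/mode/angle summaries. FA ∈ [0,1],
mode = 3√6·det(Ã/‖Ã‖) ∈ [−1 oblate, +1 prolate]. All angles treat
eigenvectors as axial (sign-invariant) quantities folded to (−90°, 90°]
(HA, TA) or [0°, 90°] (E2A).

The cardiac triad comes from signed distances to the two contours: depth =
s_epi/(s_epi − s_endo) is 0 on the epicardial and 1 on the endocardial
contour and smooth across both, so its gradient gives the local wall normal
even for non-circular walls (centroid rays are the fallback at degenerate
pixels). Circumferential = longitudinal × radial (counter-clockwise in
image axes).

Two published constructions of the E2A measurement plane exist; the default
here measures e₂'s elevation in the **cross-myocyte plane** (spanned by the
radial direction and the in-wall axis perpendicular to the *projected*
primary eigenvector). The alternative (axis perpendicular to the full e₁,
`plane="e1-orthogonal"`) is available behind a flag; the two coincide on the
phantom.

## Quality statistics

Transmural HA profiles are sampled along 72 equally spaced spokes (5°
steps; the spoke count is a package default) by bilinear interpolation,
parameterized epi (0%) → endo (100%). HAG is the mean of per-spoke OLS
slopes (the pooled-fit variant is available behind a flag); HA R² and RMSE
are per-spoke means, with R² of a zero-variance regression defined as 0.
The HA-map score replaces visual scoring: a spoke is "normal" when its fit
has R² ≥ 0.3 and the expected slope sign (both configurable surrogates for
a visual judgement); the normal fraction f maps to 3 (f > 0.95), 2
(f > 0.75), 1 (f ≥ 0.5), 0 otherwise — 0 marks the acquisition as failed
and excludes it from group statistics. TA std is the ddof=1 standard
deviation of TA over the wall. SNR per image is the repeated-measurement
estimator (per-pixel temporal mean/SD, ROI mean), with zero-SD pixels
excluded with a warning rather than returned as infinite.

## Sequence theory

The SNR ratio model assumes ideal 90°/180° flip angles, longitudinal
recovery over one RR for both sequences, the ½ stimulated-echo factor and
T1 decay over the mixing time TM ≈ 1 RR for STEAM. The diffusion distance
uses the 1D convention √(2DΔ) by default — the convention that produces the
familiar ~75 µm (STEAM, Δ ≈ 1 s) and ~10 µm (spin echo, Δ ≈ 20 ms)
free-water figures; √(6DΔ) is available. Breath-hold arithmetic counts the
preparation shots (EPI phase correction + parallel-imaging reference) once
per breath-hold: `TR_RR × (prep + averages × (b0 + directions))`, giving
16 RR (M2-SE, 2 averages) and 18 RR (STEAM, 1 average).

The in-vivo theoretical ratio is *not* asserted anywhere: evaluating the
formula with in-vivo relaxation times requires a myocardial diffusivity
value for the e^(−bD) terms that is not uniquely determined, so only the
agar-phantom configuration (all parameters measured) is treated as a
reference value.

## Gradient design

Moments are evaluated in closed form per linear segment, accumulated in
segment-local coordinates to avoid catastrophic cancellation at late times;
refocusing markers flip the effective polarity of subsequent lobes. b-values
integrate q(t)² exactly (q is piecewise quadratic). The motion-compensated
design places a short (d1) + long (d2) trapezoid pair before the refocusing
gap and the time-mirrored pair after it, physical polarities (+ − | − +).
The effective waveform is then antisymmetric about the gap centre, which
nulls M0 and M2 *identically* for any lobe durations; the single remaining
condition M1 = 0 is solved for d2 by bracketed root finding, and the target
b is hit by root finding on d1 (or by quadratic amplitude scaling when the
minimum-duration waveform already exceeds the target). Moments are reported
about the waveform start; with M0 = 0 the first moment is
reference-independent, and with M0 = M1 = 0 so is M2, hence nulling at the
gap centre implies nulling at the echo. Nulling tolerance: |M1|, |M2| ≤
10⁻⁶ × the corresponding single-lobe magnitude. γ defaults to the proton
value 2.675·10⁸ rad s⁻¹ T⁻¹. The printed lobe durations of any specific
scanner implementation are not reconstruction targets — the design is
constrained by b, Gmax and slew, not by duration.

## Strain

The displacement generator is an analytic ring deformation
`r(R)² = a + (R² − R_endo²)/λ` with two degrees of freedom per timeframe:
`a` (squared deformed endocardial radius) and `λ` (a through-plane stretch
factor). A pure-2D incompressible ring links radial and circumferential
strain and cannot reach arbitrary peak pairs — real myocardium thickens
more than 2D area conservation allows — hence the second degree of freedom.
The two parameters are solved (fsolve) so that the *myocardial-mean*
Green–Lagrange radial and circumferential strains hit the prescribed peaks
(defaults 0.50 and −0.177) at mid-series, with a sin² activation returning
to zero at the ends. Inside the cavity the map is extended with matched
value and slope at the endocardium so finite differences across the wall
boundary stay second-order accurate.

Strain measurement: displacement gradient by central differences, F = I +
∇u, E = (FᵀF − I)/2 projected on the *reference* (end-diastolic) radial and
circumferential directions, averaged over the wall; engineering strain is
available behind a flag. Peak radial strain is the curve maximum, peak
circumferential the signed minimum. Recovery error at the default 1.5 mm
grid is below 1% and shrinks with resolution.

## Statistics

Between-sequence comparisons use the paired Wilcoxon signed-rank test
(exact distribution for n ≤ 25, normal approximation above; zero
differences dropped — the classic Wilcoxon convention; an all-zero
difference vector is reported as statistic 0, p = 1). Across cardiac phases:
Friedman test, followed (only when significant at α = 0.05) by three
pairwise Wilcoxon tests at the Bonferroni level α/3 ≈ 0.0167. Correlations
of per-subject metric differences (systole − diastole, or between
sequences at a phase) with peak strain use the Pearson coefficient on
*signed* differences, with non-simultaneous 95% regression confidence-band
parameters returned for reporting; score-vs-RR uses Spearman with midranks.
All statistics are invariant to the row order of the summary table.

## Study driver and problem sizes

The default study is 15 synthetic subjects × 2 sequences × 3 cardiac
phases on a 64×64 grid at 1.5 mm pixels, with per-subject nominal RR drawn
from N(970, 140²) ms, peak radial strain from N(0.50, 0.05²) and E2A
mobility generated as 80°·(peak radial strain) + noise, so the strain
correlation has built-in signal (sheetlet reorientation as the mechanism of
wall thickening). Two frames per cell are shifted by (3, −2) px to exercise
registration. These sizes keep a full cohort under a minute on one CPU
while leaving every stage non-trivial; the generator parameters are fixed
study conditions, not tuning knobs. Per-cell failures (including HA-map
score 0) are recorded and excluded from group statistics without aborting
the cohort; outputs carry the seed and a configuration hash, and reruns
with the same seed are identical at the summary level.

## Configuration

Specs, protocols and the experiment configuration are plain dataclasses
with explicit validation in `__post_init__`; JSON (de)serialization lives in
`dtcmr.io`. This keeps the configuration contract in one place without an
extra dependency.

## Known limitations

* Single-slice 2D geometry; no 3D sheetlet-normal analysis, tractography or
  glyph rendering.
* The Rician noise floor is simulated but not corrected for — matching the
  plain log-linear estimator, which is biased at low SNR (the test suite
  demonstrates the positive FA bias at SNR ≈ 20).
* The frame-rejection and HA-map-score thresholds are automated surrogates
  for human visual assessment; their defaults are package choices.
* No strain correction of measured diffusion is applied, and the phantom
  tensors do not depend on diffusion time, so sequence differences driven
  by those mechanisms cannot be reproduced synthetically.
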