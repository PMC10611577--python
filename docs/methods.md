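# Methods

This note documents the models, conventions, and design choices behind the
package, in the spirit of a methods appendix. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The closed-loop model

### Incremental GLM

Every network voxel's signal is modeled as intercept plus linear scanner
drift. The engine keeps the five running sums needed to solve this
two-parameter OLS per voxel (`n, Σt, Σt², Σy, Σty`), folds each arriving
volume in first, and solves; by construction the coefficients at TR *t*
equal a batch OLS over volumes 0..t, and the test suite enforces agreement
with a from-scratch refit to < 1e−8 at every TR. The activation estimate is
the newest volume's residual under the current fit, divided by the
**baseline residual SD** — the per-voxel SD of the residuals of the
baseline block (default ⌈30 s / TR⌉ = 25 volumes at TR 1.2 s) under the fit
available when the baseline ends, frozen thereafter (ddof = 2 for the two
fitted parameters). Voxels whose baseline residual SD falls below a floor
(1e−8; e.g. noise-free synthetic data) report 0 rather than an amplified
rounding error. During the baseline block a provisional running SD is used
and estimates are flagged as baseline.

NOI summaries are unweighted means of the per-voxel z values over each
binary mask (a binary mask makes the "weighted average" uniform). Voxels in
both masks are logged and assigned to neither. PDA is the CEN summary minus
the DMN summary: positive PDA = target state = dot moves up.

A consequence worth stating: because the nuisance fit keeps updating with
all acquired data, any *sustained* activation shift is progressively
absorbed into the intercept/drift estimates — the estimator registers
transients, not plateaus. The synthetic "successful modulation" condition
is therefore built from sparse DMN reactivation bursts (mind-wandering
events, default ~0.12/TR hazard, 2 TRs long, 2 baseline-SD amplitude)
against a quiescent CEN: between bursts the DMN sits below its own fitted
trend, so PDA is positive on most feedback TRs. A sustained step, by
contrast, drifts back toward zero and eventually overshoots negative; both
behaviors are consequences of trend-discounting, not bugs.

### Display staircase

The dot ordinate lives in circle-center units: ±1 are the circle centers,
one unit = half the 472-px center distance = 236 px. Each TR the dot moves
by `gain · PDA` (default gain 0.1 per baseline-SD; the paradigm's
pixel-per-PDA scaling is a free display choice, and time-in-target is
provably independent of it since it depends only on the PDA sign). The dot
qualifies for a circle when its center reaches the circle's near edge
(|y| ≥ 1 − radius/236); the dot's own 12-px radius is ignored — the
simplest geometric reading. Qualifying TRs accumulate per circle
(cumulatively, not necessarily consecutively) and at 5 the circle's radius
is multiplied by 0.9, the dot recenters, and the counter clears; radii are
computed as `56 · 0.9^k` from the shrink count so the law holds exactly in
floating point. Each circle has an independent cap of 5 shrinks per run;
at the cap a full counter clears with no other change. An integer
volume-to-display lag is configurable (default 0); the paradigm's reported
feedback delay is not modeled literally because a 30.5-s delay is
inconsistent with per-TR updates at TR 1.2 s.

Time-in-target uses only post-baseline (feedback) TRs; the baseline block
contributes to the nuisance fit and the SD scale but not the performance
metric.

## Localizer

Spatial ICA (FastICA on the in-brain voxel × time matrix) stands in for the
decomposition; only the selection and thresholding logic is owned here.
Component maps are z-scored over in-brain voxels. Template matching
maximizes |r| and sign-flips the winning map when r < 0 (source separation
is sign-ambiguous). If one component wins two templates it goes to the
larger |r| and the runner-up serves the other, so the two feedback targets
are always distinct components. Binarization keeps exactly
⌈0.10 · n_inbrain⌉ voxels ("upper 10%" read relative to in-brain voxels,
which matches the reported mask sizes' order of magnitude); ties break by
flat voxel index for determinism. Automatic dimensionality estimation is
not implemented — the component count is a config parameter (default 30;
toy-grid tests use 5).

## Denoising and connectivity

* **FD**: Power convention — sum of absolute frame-to-frame translation
  changes plus 50 mm × sum of absolute rotation changes (radians → arc
  length); FD[0] = 0. Rotations are stored in radians everywhere;
  conversion to mm happens only inside the FD formula.
* **Outliers**: |global-signal z| > 5 or FD > 0.9 mm (lenient preset);
  3 / 0.5 mm stringent preset. Flagged frames become one spike regressor
  each (scrubbing by regression, not deletion).
* **CompCor**: in-mask voxel series are linearly detrended and the top
  5 left singular vectors per tissue are the noise regressors (orthonormal
  by construction).
* **Denoise ordering**: the confound design (intercept, drift, 6 motion
  parameters + first differences, CompCor, spikes) is band-pass projected,
  voxel series are residualized against it, and residuals are band-pass
  projected. The filter is a hard spectral mask on the real FFT
  (0.008–0.09 Hz, DC excluded), i.e. a true projection; filtering the
  regressors first makes the whole step *exactly* idempotent, which the
  tests check at 1e−6 relative norm. Collinear or zeroed design columns are
  pruned (rank-revealing QR); the intercept always zeroes under the filter,
  by design.
* **Seeds**: a sphere seed contains every voxel whose world-space center
  lies within the radius of the seed's world coordinate under the volume's
  affine (8-mm sphere on a 2-mm grid centered on a voxel → 257 voxels, the
  lattice count). No template registration is performed; synthetic affines
  stand in for MNI space.
* **Connectivity**: Fisher z = atanh(r) of each voxel against the mean seed
  timecourse; |r| is capped at 1 − 1e−7 (flagged) so maps stay finite, and
  zero-variance voxels report 0 with a flag. Seed voxels keep their own
  values. Pre/post change fits `Δz ~ intercept + centered covariate` per
  voxel, tests the intercept, applies Benjamini–Hochberg within the search
  mask, and reports 26-connected clusters (the common SPM-style choice).
  Brain–behavior maps use partial correlation (df = n − 3 with a
  covariate) thresholded at p < 0.001 uncorrected. Gaussian smoothing
  (default 6 mm FWHM) is available but off for toy grids.
* **ICC**: two-way, single-rater, absolute agreement — ICC(A,1), whose
  value is identical under random- and mixed-effects assumptions — via
  pingouin, with the F-test p-value.

## Mediation

Three OLS regressions (Y~X; M~X; Y~X+M) give paths c, a, and (b, c′) with
unstandardized b, standardized β (from z-scored refits), SE, t, and
two-tailed p. The Sobel statistic is the classical delta-method form on
unstandardized coefficients, z = ab/√(b²SE_a² + a²SE_b²), with a two-tailed
normal p — this variant reproduces published tables from their printed
coefficients within last-digit rounding, as the acceptance script
demonstrates. β_c = β_a·β_b + β_c′ holds exactly for the fitted values and
is asserted to 1e−10. All tails are explicit arguments; nothing infers a
tail from an effect sign. A percentile bootstrap CI for ab exists but is
off by default. `standardized_betas_from_corr` solves the two-predictor
standardized system directly from a correlation matrix, enabling desk-scale
cross-checks when only printed correlations are available.

## Synthetic data: what it emulates, and what it does not

Networks are sums of Gaussian blobs confined to disjoint slabs of the grid
(default 20×20×10 voxels, 2-mm synthetic affine), so supports can never
overlap. Voxel signal is loading-weighted network timecourse + linear drift
+ Gaussian noise (optional AR(1), coefficient 0.3 by default where enabled,
mimicking BOLD autocorrelation). When a within-network correlation is
requested, the network amplitude is calibrated by bisection on the
closed-form pairwise correlation so the mean pairwise r over the map's
top-50% core matches the request despite loading spread; between-network
correlation is induced at the latent level (ρ = r_between / r_within).
Motion is a bounded uniform random walk (±0.02 mm, ±2e−4 rad per frame)
plus sparse single-frame spikes at least 2 frames apart (adjacent spikes
would cancel in the frame difference). The behavioral cohort follows
X → M → Y with configurable standardized paths (defaults a = −0.67,
b = −0.76, c′ = 0.18 — strong performance→connectivity and
connectivity→mindfulness paths with a small direct remainder) and noise
scales chosen so Var(M) = Var(Y) = 1.

Not modeled: hemodynamic convolution, physiological noise, k-space/EPI
artifacts, registration/segmentation, scanner streaming, and rendering.
Passing tests therefore demonstrate the correctness of the estimators and
decision rules under idealized BOLD-like inputs, not robustness to real
acquisition physics.

## Problem sizes and numerical choices

Tests and the acceptance script use the 20×20×10 grid with 125-volume
feedback runs and 250-volume rest runs; chance-level calibration of
time-in-target uses 1000 seeded runs, planted-effect detection 100, FDR
power 100 replicates and the FDR null 1000 replicates (judged against a
one-sided 99% binomial band around the nominal 0.05, since the
any-discovery rate of BH under the global null sits *at* the nominal level
rather than below it), and mediation recovery a 5000-subject cohort. These
sizes keep every check reproducible in minutes on one CPU while leaving
Monte-Carlo error well inside the asserted tolerances. Degenerate inputs
(constant series, zero-variance voxels, |r| = 1, empty masks, collinear
designs) are either flagged results or typed errors, never silent NaNs.
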