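# Methods

## The tilt model

A circumpapillary circle scan samples a 3.4 mm circle around the optic
disc (1024 A-scans per circle in the reference protocol) and is displayed
unrolled: both image ends are the nasal side of the disc, the middle
temporal. If the disc plane is tilted by an angle relative to the optical
axis, the RPE band crosses the scan cylinder along (approximately) an
ellipse; unrolled, that intersection is one sine period per circumference.
The trace of RPE positions `(x, y)` (x = scan column, y = image row,
y increasing downward) is therefore modeled, after centering, as

    v = a · sin(b·u − c)

with amplitude `a` (pixels) the tilt metric, angular frequency `b`
(rad/px) expected at `b0 = 2π/scan_width`, and phase `c` locating the tilt
direction. Torsion of the eye only shifts `c`, which is why the amplitude
is direction-independent.

**Centering.** `u = x − (min(x)+max(x))/2`, `v = y − mean(y)`. The
y-mean-centering replaces the intercept the three-parameter model lacks;
the x-midpoint makes `u` symmetric on a full-width grid. Centering is
idempotent and removes any global vertical offset; the operation is
enforced by type (`fit_sine` accepts only `CenteredTrace`).

**Fitting.** For fixed `b` the model is linear:
`v = A·sin(bu) + B·cos(bu)` with `a = √(A²+B²)`, `c = atan2(−B, A)`. The
fit solves this exactly at `b0` (deterministic — no random starts), then by
default refines `(a, b, c)` jointly by damped least squares
(`scipy.optimize.least_squares`, trust-region reflective) with `b` bounded
to `[0.5, 2]·b0`; the bounds encode the single-period anatomy and keep
sparse noisy traces from locking onto harmonics. After refinement `(a, c)`
are re-polished by the exact linear solve at the refined `b`. Fitted
parameters are normalized to `a ≥ 0`, `c ∈ [0, 2π)` (negative amplitude is
absorbed as a π phase shift), making the metric invariant to a global
y-flip of the image. Convergence: relative parameter/residual change
below 1e−10, capped at 200 iterations; on non-convergence the best
parameters so far are returned flagged `converged=False`.

**Degenerate traces.** A perfectly flat trace has zero total sum of
squares; the fit short-circuits to `a = 0` with `R²` defined as 1 (a flat
RPE means a small tilt, which the metric should report as such, not as a
failure). Near-flat traces simply yield small amplitudes and often fail
the quality gate. The gate is strict: `quality_pass ⇔ R² > 0.90`, so
`R² = 0.90` exactly fails. Traces need ≥ 8 points to constrain 3
parameters; fewer is an error at fit time (2-point traces remain loadable
for I/O round trips).

**Tilt direction.** The scan angle of the wave minimum,
`θ = ((c + 3π/2)/b) · (2π/scan_width) mod 2π`, with θ = 0 at the (nasal)
scan start. Undefined at `a = 0`. The fit result carries `scan_width` so
this mapping needs no extra state.

## Modified ovality ratio

From ordered disc-margin points (fundus-photo pixels, y down, right eye):
`d_max` is the longest point-pair chord of the convex hull; the long-axis
angle is measured clockwise from the vertical (up) direction and folded
into [0°, 90°]. A disc is *vertical* when that angle is < 45° and
*horizontal* when > 45°; exactly 45° classifies as vertical, keeping the
classical min/max formula for the boundary. Vertical discs score
`d_min/d_max ≤ 1`, horizontal discs `d_max/d_min ≥ 1`, so horizontal
elongation (the axial-growth signature) is separated from vertical tilt
instead of being conflated with it.

`d_min` defaults to the minimum caliper width (smallest distance between
parallel supporting lines), the standard well-posed definition for
irregular outlines; the chord through the centroid perpendicular to
`d_max` is available as `min_mode="perpendicular"` since the original
measurement procedure (manual calipers) does not disambiguate the two.
For ellipse polygons with ≥ 180 vertices both agree with the analytic
axis ratio to < 0.01.

## Reliability and association statistics

- **ICC**: two-way absolute agreement, single measures (McGraw–Wong
  ICC(A,1)) as the headline, computed from the ANOVA mean squares
  `(MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE))`, with the F-based
  95% CI (Satterthwaite denominator df) and the p-value of the
  subject-variance F test. The average-measures ICC(A,k) is available via
  `measures="average"`. Absolute agreement penalizes systematic rater
  offsets; the consistency ICC would not. The point estimate and interval
  agree with `pingouin.intraclass_corr` (cross-checked in the tests;
  implemented in-module because pingouin rounds its interval to two
  decimals, too coarse for reliabilities near 1). Exact agreement
  (MSE = MSC = 0) returns ICC 1 with a degenerate [1, 1] interval.
- **Spearman**: Pearson correlation of mid-ranks; two-sided p from
  `t = ρ√((n−2)/(1−ρ²))` on n−2 df (the common software default for
  n > 10). An exact-permutation p (`method="exact"`) enumerates all
  pairings for n ≤ 10.
- **Summaries**: mean, sample SD (n−1), min, max.

## Synthetic data

The generators emulate the three kinds of study data and are pure
functions of their spec (explicit seeds, no global state):

- **Traces**: `y = baseline + a·sin(b·x − c) + drift + N(0, σ²)` on a
  uniform grid. Defaults are the study conditions: 64 manually plotted
  points per 1024-column scan, amplitude 37 px, one period per
  circumference, phase π/2 (RPE high at the nasal ends, low temporally),
  plotting noise σ = 2 px — a plausible jitter for manual marking at
  screen resolution. The optional centered quadratic drift models
  non-sinusoidal courses; default 0.
- **Images**: a Gaussian-profile bright band (σ = 3 px, peak 200) painted
  along the interpolated trace plus optional background noise. Extraction
  finds, per column, the intensity-weighted centroid in a ±8-row window
  around the brightest pixel and median-smooths the profile (halfwidth 3);
  noiseless round trips recover the curve to ≤ 0.5 px RMS for amplitudes
  0–80 px.
- **Cohorts**: a 5-variate Gaussian copula over (amplitude, ovality,
  spherical equivalent, axial length, height) with latent linear
  correlation `2·sin(π·ρ_s/6)` so realized Spearman correlations hit their
  targets. Marginal means/SDs and the amplitude correlation row
  (−0.59, −0.29, 0.11, −0.39) are the reference cohort conditions
  (126 young-adult, predominantly myopic right eyes: amplitude
  37.0 ± 17.5 px, ovality 0.89 ± 0.11, SE −4.71 ± 3.41 D, AL 25.4 ± 1.5 mm,
  height 167.6 ± 8.4 cm); the refraction/axial-length correlation is −0.82.
  Covariate pairs with no stated correlation follow a single-factor
  structure (products of the amplitude correlations), which keeps the
  matrix positive definite. Ovality is truncated to be positive; the
  amplitude marginal is left Gaussian, so a few draws per cohort can be
  slightly negative (see limitations). Duplicate ratings are
  `amplitude + noise`, with within-rater SD 1.1 px and second-rater SD
  5.0 px derived from `σ_e = σ_s·√((1−ICC)/ICC)` at the reference
  reliabilities 0.996 (intra) and 0.959 (inter). `axis_class` follows the
  modified-ratio construction (ratio > 1 ⇔ horizontal).

## Cohort analysis

Per-statistic listwise deletion (dropped counts logged); at least 3
usable rows required. `amplitude_mean` is the mean of the two raters when
both are present, matching the convention of using rater means once
reliability is established. Subgroups split on `axis_class` (derived from
the ratio when absent). The fit-quality fraction is reported when a
per-eye `R²` column exists (e.g. merged from `run_trace_batch` output).

## Problem sizes

The test suite and acceptance script use: exactness checks at n = 1024
points; noise Monte-Carlo with 100–200 replicate seeds; copula
calibration with 500 replicate cohorts of n = 126; replicate-averaged
cohort statistics over 200 cohorts; fit-quality measured over 10 × 126
simulated eyes. These sizes give Monte-Carlo standard errors an order of
magnitude below the quantities' natural variability while keeping the
whole suite in the tens of seconds.

## Known limitations

- The Gaussian copula reproduces pairwise rank correlations, not the full
  joint law of real cohorts. In particular, truncating to the vertical-axis
  subgroup (ovality ≤ 1) attenuates the amplitude–ovality correlation
  (to ≈ −0.49 from −0.59), whereas the reference cohort's subgroup
  correlation was essentially unattenuated — real disc shape is not
  bivariate-Gaussian in this respect. Passing calibration tests therefore
  demonstrates the pipeline's statistics, not distributional realism.
- The Gaussian amplitude marginal admits rare negative draws
  (≈ 1.7% per cohort at mean 37, SD 17.5); only ovality is truncated.
- Band extraction assumes a single dominant bright band per column; it is
  a stand-in for manual plotting on synthetic renders, not a retinal layer
  segmentation for clinical scans.
- No magnification correction for axial length is applied; amplitudes are
  reported in pixels of the native scan geometry (a µm conversion is
  deliberately not part of the pipeline).
- Fit-quality percentages depend on the assumed plotting-noise level and
  amplitude distribution; with the defaults, ≈ 95% of simulated eyes pass
  the R² > 0.90 gate.
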