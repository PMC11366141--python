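# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `actimyo`.

## Movement-biomarker extraction

A leg's recording is a tri-axial acceleration series in units of g on a
uniform grid (nominally 12.5 Hz, ±16 g dynamic range).  Processing:

1. **Downsampling to 10 Hz** by linear interpolation onto a 10 Hz grid
   spanning the input.  Linear interpolation is dialect-free and adequate
   for the sub-5 Hz content that drives the features; its worst-case error
   for a sinusoid of frequency f is (2πf)²h²/8 with h the input spacing
   (≈ 3% of amplitude at 1 Hz from a 12.5 Hz grid).  Whether decimation
   with anti-aliasing would better match a given device toolchain is
   unknowable from the feature definitions; the choice is configurable only
   by reimplementing `resample_to_10hz`.
2. **High-pass filtering**: 4th-order Butterworth, 0.2 Hz cutoff, applied
   forward-backward (`sosfiltfilt`).  Zero-phase filtering avoids
   displacing bout boundaries; the price is that stopband attenuation acts
   twice (a 0.02 Hz component is suppressed below 1e-8).  Recordings
   shorter than 3× the filter settling length (15 s at 0.2 Hz) are
   rejected.
3. **Exclusion masking**: documented passive-movement episodes
   (physiotherapy, transports, repositioning) are intervals [start, end);
   overlapping episodes are merged; samples inside them are flagged.  A 5-s
   window containing *any* excluded sample is wholly excluded —
   conservative and reproducible.  A trailing partial window is dropped.
4. **SMA**: per window, the mean of |a_x|+|a_y|+|a_z| over the window's
   samples, in g.  Defining SMA as a mean rather than an integral makes the
   0.135 g activity threshold independent of the window length (the
   integral definition divided by the window length is identical).
5. **Bouts**: a bout is a maximal run of consecutive non-excluded windows
   with SMA ≥ 0.135 g (the threshold is inclusive).  There is no gap
   tolerance: a single sub-threshold window ends a bout, and an excluded
   window breaks a run.  Consequently an exclusion episode dropped into the
   middle of a bout *splits* it; total active time is monotone under added
   exclusions but the bout count is not.
6. **Features**: %active = 100 × active windows / non-excluded windows;
   overall intensity = mean SMA over non-excluded windows (active *and*
   inactive windows — whether "overall" should average only active windows
   is ambiguous; we chose all analyzed windows); AB/hour = bouts per
   non-excluded hour; and the log-normal maximum-likelihood fits of bout
   intensities and durations.  The closed-form MLE is the mean and the
   population (divide-by-n) standard deviation of the natural logs.  With
   zero bouts the four log features are missing (NaN) and the row is later
   dropped from the model table.

Left and right legs are processed and modelled as separate observations;
nothing is averaged across legs.

## Outcome and analysis table

The outcome is the relative change of rectus femoris thickness versus
day 0, in percent (atrophy negative), computed from the mean of three
repeated ultrasound measurements per site and day; missing repeats are
errors, never imputed.  By default days 3, 7 and 10 enter as repeated
observations per leg; a switch restricts the table to day 10 (the scale on
which the standardized effects are interpreted — see "Day scaling" below).
Movement features are computed once per leg over the full monitored span
and attached to every day's row.  Rows missing the outcome or any of the 12
predictors are dropped with full accounting (candidate rows = kept +
dropped).  Sex is encoded 0/1 and passes through z-scoring like every other
listed predictor.

## Penalized mixed model

With patient random intercepts b_i ~ N(0, σ_b²) and residuals
ε ~ N(0, σ_e²), the estimator minimises

    ½ log|V| + ½ (y − β₀1 − Xβ)' V⁻¹ (y − β₀1 − Xβ) + λ Σ_j |β_j|,
    V = σ_e² I + σ_b² Z Z',

with the intercept and the variance components unpenalized.  The algorithm
alternates two exact blocks until the penalized objective changes by less
than 1e-8 (flagged, not raised, on non-convergence):

* **β-step**: with (σ_b², σ_e²) fixed, V^{-1/2} is applied per cluster
  (v → v − (1 − (1+mρ)^{-1/2}) v̄ for a cluster of size m, ρ = σ_b²/σ_e²)
  and the whitened LASSO is solved by cyclic coordinate descent with
  soft-thresholding in the Gram ("covariance updating") form, with an
  active-set strategy; coordinate updates cost O(p).  Zeros are exact.
* **variance step**: with β fixed, the profiled negative log-likelihood
  over ρ is minimised by bracketed root-finding on its derivative
  (the ρ = 0 boundary is checked explicitly), and σ_e² follows in closed
  form.  `fix_rho` pins ρ instead, which at ρ = 0 reduces the estimator to
  an ordinary LASSO — the basis of one of the two solver oracles.

Both steps decrease the objective, so the alternation is monotone.  The two
oracle checks in the test suite: at λ = 0 the fit agrees with direct ML
optimization of the unpenalized mixed model (statsmodels `MixedLM`,
reml=False) to 1e-4 on all coefficients; at ρ = 0 it agrees with
scikit-learn's `Lasso` (α = λσ_e²/n) to 1e-3.

**λ grid**: 50 log-spaced values from λ_max (the smallest λ that zeroes
every penalized coefficient, computed from the whitened score at the
null model) down to λ_max/1000.

**Nested cross-validation**: outer 4-fold / inner 2-fold partitions of
*patients* (never rows), seeded and keyed on sorted patient identifiers so
the result is invariant to row order.  Per λ the inner validation MSE uses
predictions with the random effect set to 0 (the population mean — our
convention for unseen patients throughout).  The per-outer-fold optimum is
the argmin, ties broken toward the larger (more parsimonious) λ; the final
λ is the arithmetic mean of the four outer optima and the final model is
refit on the full training set.  Path fits for the MSE curves run at
prediction-grade tolerance (1e-6, 40 alternations) with warm starts; final
fits at full precision.

**Split**: patients are stratified by rank of their mean outcome into
quartiles; test patients are drawn per stratum by largest-remainder
allocation (remainder ties assigned symmetrically from the extremes of the
outcome ordering, so neither tail is favoured), giving a test fraction
within ±1 patient of the 20% target and no patient straddling the split.
With fewer than 8 patients the split falls back to an unstratified grouped
split with a warning.

**Metrics**: MSE, RMSE, MAE, and R² as the squared Pearson correlation of
predicted and actual values (undefined and flagged for constant
predictions).  R² on this definition is shift-invariant, so a constant
prediction offset does not reduce it.

**BCa cluster bootstrap**: patients are resampled with replacement (a
patient drawn twice enters as two distinct clusters) and the model is refit
at the fixed final λ from a warm start; 10,000 resamples by default,
scaled down in tests.  z₀ comes from the fraction of bootstrap coefficients
strictly below the point estimate (clipped to (1/(B+1), B/(B+1))), the
acceleration from the jackknife-over-patients skewness formula, and the
interval endpoints are the BCa-adjusted quantiles.  A coefficient constant
across all resamples (e.g. always shrunk to zero) yields a flagged
degenerate interval.  Known limitation: the bootstrap resamples the
*penalized* estimator, so intervals centre on the shrunken estimate; z₀
corrects median bias of the bootstrap distribution about the point
estimate, not shrinkage bias about the truth.  In the package's own
coverage study (200 simulated cohorts of 100 patients, day-10 rows, 500
resamples, per-cohort λ from a coarse nested CV) the 95% intervals covered
the planted effects in ~83% of cohorts — undercoverage that is
characteristic of naive bootstrap inference for LASSO-type estimators;
debiased approaches are out of scope.

Similarly, the penalty that minimises cross-validated prediction error is
known to *over-select*: small null coefficients survive at the CV-optimal
λ.  In the package's selection study (200 patients, two true predictors at
(−5.1, +1.6) and eight nulls) the nested-CV model virtually always retains
both true predictors and estimates their mean effects within ±20% of
truth, but typically zeroes only 1–4 of the 8 nulls; support recovery
would require stronger penalisation (a one-standard-error rule or
BIC-type criterion) than the argmin contract used here.

**Secondary analyses**: the limb-group comparison is a Gaussian GEE with
identity link, exchangeable working correlation within patient and robust
sandwich variances, cell-means coding, all three pairwise contrasts
Wald-tested with p-values multiplied by 3 (capped at 1); with the working
correlation forced to independence the estimates coincide with pooled OLS.
The temporalis model is OLS with 95% CIs on complete rows, raising on rank
deficiency with the aliased columns named.  The activity contrast uses the
Welch unequal-variance t-test (the group sizes are 3 vs 53); note that with
n = 3 the Welch–Satterthwaite degrees of freedom are ≈ 2, so even a
t-statistic of 26 yields p ≈ 3e-3, not < 1e-3.

## Synthetic-data generator

The generator is first-class, tested code; it defines the study conditions
for every Monte-Carlo check.

**Recordings.** Static gravity (1 g along a configurable unit vector) +
zero-mean Gaussian sensor noise (default SD 0.01 g per axis) + planted
bouts, clipped to ±16 g.  A bout is a fixed-frequency 2 Hz sinusoid per
axis with independent random phases and per-axis amplitude
(π/6) × intensity, so the rectified three-axis mean equals the planted
intensity analytically (after filtering, which passes 2 Hz essentially
unchanged; the 12.5→10 Hz interpolation and the 5-sample-per-cycle
discretization attenuate the realized SMA by ~7%).  Bout log-durations and
log-intensities follow configurable log-normal laws (defaults: duration
log-mean ln 18 s, log-SD 0.6; intensity log-mean ln 0.3 g, log-SD 0.4).
Bout counts are Poisson in *non-excluded* hours — %active and AB/hour are
defined on analyzed time — and bouts are placed uniformly, non-overlapping,
≥ 10 s apart and outside exclusion episodes, so adjacent bouts can never
merge into one detected run.  Exclusion episodes are Poisson per day
(default 6/day, log-normal durations around 15 min) drawn from a dedicated
substream so `generate_exclusion_log` reproduces exactly the episodes the
recording generator reserved.  Each leg's three substreams (exclusions,
bouts, noise) are keyed on (seed, crc32(leg id), stream), so any recording
regenerates independently of call order.

**Cohort.**  Per patient: age ~ N(59.2, 15.9²) clipped to [18, 95], sex
Bernoulli(0.585), mSOFA ~ N(4.5, 2.1²) clipped ≥ 0, weight ~ N(75, 12²) kg,
calorie and protein adequacy ~ N(62.6, 18.4²) and N(57.9, 21.6²) percent
(deficits derived from 25 kcal/kg/day and 1.3 g/kg/day prescriptions over
10 days), baseline RFM thickness ~ N(10.3, 2.6²) mm truncated positive, and
a random intercept ~ N(0, 7²) percentage points.  Per leg: the second leg
is missing with probability 15/53 (expected 91 legs for 53 patients), and
%active follows a log-normal law matched to mean 0.84 / SD 1.08 percent
(healthy preset: 13.3 / 0.8, with 24 h of wear so the Poisson noise floor
of the realized fraction sits below the between-subject SD).  The other
movement features follow plausible independent laws; by default the null
predictors are generated independent of the outcome, and a `confound_nulls`
switch couples overall intensity to %active for robustness experiments.

**Outcomes.**  Day-10 change (%) = −19.5 + (−5.1)·z(baseline RFM) +
(+1.6)·z(%active) + b_i + ε, ε ~ N(0, 8.2²); z-scores use the generated
sample's mean/SD, so the planted coefficients live on the same scale the
modelling z-scores produce.  σ_b = 7 and σ_e = 8.2 make the marginal
day-10 SD ≈ 12.  Temporalis day-10 atrophy is drawn at N(−15.3, 11.1²),
independent of leg movement.  Ultrasound tables carry three repeats per
site/day with 0.1 mm measurement noise; thickness values invert the
relative-change definition exactly.

**Day scaling.**  Day-3 and day-7 changes are fixed fractions (0.4, 0.8)
of the day-10 change plus N(0, 2.5²) noise — the longitudinal trajectory is
otherwise unspecified.  A consequence worth knowing: a model fit on the
*pooled* day-3/7/10 table estimates ≈ 0.73 × the day-10 standardized
effects (the mean of the day fractions), so effect-recovery studies and
reported coefficients use the day-10-restricted table, while pooled fits
are used where stability at small n matters.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: physiological gait waveforms (bouts are pure
2 Hz tones), device binary formats, postural drift and sensor re-taping
artifacts, informative missingness (leg datasets drop out at random),
correlation between clinical covariates, and any real association between
the movement features beyond the planted %active effect.  The headline
explained-variance figures of a real cohort are likewise out of reach by
construction: with fixed effects (−5.1, 1.6) against a marginal SD of 12,
the population-level test R² is capped near 20% on day-10 data, so the
package's reported R² values are small and serve only to compare models
with and without movement features under identical conditions.  For that
directional comparison the movement contribution is planted at the
magnitude of the reported real-data gap (≈ 24% of outcome variance) so the
direction is statistically identifiable in 20 seeds.

## Problem sizes used in the shipped studies

Unit tests run on miniature data (tens of windows, ≤ 40 clusters).  The
Monte-Carlo studies use: 100 recordings of 0.5 h for planted-bout
recovery; 20 cohorts of 200 patients (day-10 rows) for effect recovery,
selection and the model comparison; 200 cohorts of 100 patients with 500
bootstrap resamples (scaled down from the 10,000 used for a real analysis)
for BCa coverage; and the acceptance script simulates 53 patients with 6 h
recordings per leg end to end plus a 200-patient recovery cohort.  These
sizes keep each study's sampling error well below the margins being
asserted while remaining desk-scale.
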