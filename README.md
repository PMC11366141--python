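# actimyo

Accelerometer-derived movement biomarkers and penalized mixed-model
prediction of muscle atrophy in neurocritical care cohorts.

Physical inactivity drives muscle atrophy in critically ill patients, a key
mechanism behind ICU-acquired weakness (ICUAW). `actimyo` implements, as a
tested and reusable pipeline, a study design in which thigh-fixed tri-axial
accelerometers (±16 g, 12.5 Hz) quantify *active* movement — passive
episodes such as physiotherapy, transports and repositioning are
prospectively excluded — and the resulting movement biomarkers predict
rectus femoris muscle (RFM) atrophy measured by serial ultrasound.

It is written for biostatisticians and clinical researchers who want to
reuse the biomarker definitions or the penalized mixed-model machinery, and
ships a synthetic-data generator that emulates such a cohort with known
ground truth, so every stage is testable end to end.

## What it computes

**Movement biomarkers** (per leg): the raw series is downsampled to 10 Hz,
high-pass filtered (4th-order Butterworth, 0.2 Hz, zero phase), masked for
exclusion episodes and cut into non-overlapping 5-s windows.  Per window the
signal magnitude area is

    SMA = mean(|a_x| + |a_y| + |a_z|)   [g]

and an *activity bout* (AB) is a maximal run of windows with SMA ≥ 0.135 g.
Seven features summarise a recording: %active (percent of analyzed time in
bouts), overall intensity (mean SMA), AB/hour, and the log-normal
maximum-likelihood location/scale of bout intensity and duration
(AB-intensity log-mean/log-SD, AB-duration log-mean/log-SD).

**Outcome model**: relative RFM thickness change versus day 0 (%) on days
3/7/10, two legs per patient, is modelled as a Gaussian linear mixed model
with patient random intercepts and L1-penalized fixed effects,

    y_ij = beta0 + x_ij' beta + b_i + eps_ij,   b_i ~ N(0, sigma_b^2),
    minimize  -loglik + lambda * sum_j |beta_j|,

over 12 z-scored predictors (age, sex, baseline RFM, mSOFA, calorie and
protein deficit, and the six movement features).  The solver alternates
GLS-whitened coordinate descent with soft-thresholding (exact zeros) and
profiled maximum-likelihood variance updates.  Around it: VIF > 5 pruning,
a patient-grouped stratified 80/20 split, 4-outer/2-inner nested
cross-validation of λ (final λ = mean of the outer optima), test-set
MSE/RMSE/MAE/R² (squared Pearson correlation), and BCa confidence intervals
from a cluster bootstrap that resamples patients.  Secondary analyses: a
Gaussian GEE (exchangeable working correlation, Bonferroni-adjusted
pairwise contrasts) comparing limb groups, an OLS model for temporalis
atrophy, and a Welch t-test contrasting %active in healthy controls versus
patients.

## Worked example

```python
import numpy as np
from actimyo import cohort, features, modeling, simulate

# one synthetic leg: ~12 bouts/h of 0.5 g, ~20 s each, no exclusions
cfg = simulate.SimConfig(seed=4, recording_hours=1.0, bout_rate_per_hour=12.0,
                         bout_duration_logmean=np.log(20.0), bout_duration_logsd=1e-6,
                         bout_intensity_logmean=np.log(0.5), bout_intensity_logsd=1e-6,
                         exclusion_episodes_per_day=0.0, noise_sd_g=0.005)
rec, truth = simulate.generate_accel_recording(cfg, "P7_L")
fs = features.extract_movement_features(rec, truth.episodes)
print(len(truth.bouts), fs.n_bouts, round(fs.pct_active, 2))
#> 14 14 8.47        (14 planted bouts, all recovered; ~8.5% active time)

# a full cohort at study scale, day-10 outcomes
sc = simulate.generate_cohort(simulate.SimConfig(seed=3, n_patients=200,
                                                 leg_missing_rate=0.0))
table, _ = cohort.build_analysis_table(sc.ultrasound, sc.clinical,
                                       sc.features, day10_only=True)
cols = ["baseline_rfm_mm", "pct_active", "age", "sex", "msofa",
        "calorie_deficit", "protein_deficit", "overall_intensity_g",
        "ab_intensity_logmean", "ab_duration_logmean"]
mm, _ = modeling.build_model_matrices(table, None, cols)
grid = modeling.lambda_grid(mm.X, mm.y, mm.groups, 50)
cv = modeling.nested_cv(mm, grid, seed=1)
print({c: round(b, 2) for c, b in zip(cv.final_fit.columns,
                                      cv.final_fit.beta) if c in cols[:2]})
#> {'baseline_rfm_mm': -5.07, 'pct_active': 1.57}
```

The planted standardized effects were −5.1 percentage points of atrophy per
SD of baseline RFM thickness and +1.6 per SD of %active; the nested-CV
penalized mixed model recovers them from the generated data.

The same pipeline is scriptable from the shell:

```bash
actimyo run-all --out runs/demo --seed 1
actimyo extract-features --recording leg.csv --exclusions excl.csv --out feats.csv
```

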