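# slrwalk

Predicting **walking independence** after incomplete cervical cord injury
(ICCI) from trunk and lower-limb surface EMG and inertial signals recorded
during **straight-leg raising (SLR)**.

In the acute phase of ICCI the key clinical question is whether a patient
will walk independently at discharge. Peripheral muscle strength alone
(the lower-extremity motor score, LEMS) predicts much of this, but trunk
function matters too: patients who compensate for leg weakness show
abnormal trunk-muscle activation during SLR, most visibly in the
**contralateral external oblique (EO)**. `slrwalk` implements, as a tested
reusable library, the full analysis chain from raw multichannel recordings
to a two-predictor logistic prediction model — plus a synthetic-cohort
generator with known ground truth, because no public recordings of this
protocol exist.

## The analysis chain

A recording session per patient: 3 SLR trials (raise the nondominant leg
to 30°, hold 10 s) and 3 bilateral-SLR normalization trials (5 s), each
with 8 EMG channels and 3 IMU sites (triaxial accelerometer + gyroscope)
sampled synchronously at 1000 Hz.

1. **Kinematics** — SLR start point from the lower-leg pitch angle
   (complementary-filter fusion of accelerometer inclination and
   gyroscope); the analysis window runs from the start point to 10 s
   after it. Gravity is removed with a zero-lag 4th-order Butterworth
   1-Hz high-pass, and the *combined acceleration* per site is the
   per-sample Euclidean magnitude, averaged over the window and the
   3 trials.
2. **EMG features** — band-pass 5–450 Hz (zero-lag 4th-order
   Butterworth); RMS every 50 ms; activation normalized to the
   submaximal reference (windowed RMS over the central 3 s of the
   bilateral-SLR trials) and expressed as **RMS%**; spectral **median
   frequency (MDF)** from a 20-scale complex-Morlet continuous wavelet
   transform (bandwidth and center-frequency parameters 1), summing
   squared coefficient magnitudes over the window per scale.
3. **Cohort statistics** — Fisher exact tests (exact Freeman–Halton
   enumeration for r×c tables) for categorical group ratios;
   normality/homogeneity-gated unpaired *t* vs Mann–Whitney *U* for
   continuous variables; pairwise Pearson correlation screen.
4. **Prediction** — 26 candidate predictors (sex, age, BMI, length of
   stay, days injury→measurement, UEMS, LEMS, 3 combined accelerations,
   8 RMS%, 8 MDF). Four steps: overall-median imputation → lasso
   logistic screen with 10-fold cross-validated λ → enumeration of all
   two-predictor models whose pair is *not* significantly correlated
   (α = .05) → maximum-likelihood fits compared by
   AIC = −2 log L + 2k. The winner is evaluated by confusion matrix
   (walking-dependent positive, threshold 0.5), accuracy / sensitivity /
   specificity, and ROC AUC with a stratified-bootstrap 95% CI.

## Worked example

`examples/04_model_selection.py` builds a 40-patient synthetic cohort
(20 walking-dependent, 20 walking-independent, with the published
covariate structure and sporadic missing values) and runs the 4-step
procedure:

```
imputed cells: 27
lasso optimal lambda: 0.0286
nonzero predictors: ['sex', 'total_length_of_stay', 'uems', 'lems', 'rms_ra_ips',
 'rms_ra_con', 'rms_io_con', 'rms_eo_con', 'mdf_rf_ips', 'mdf_io_con', 'mdf_eo_con']
intercept-only baseline AIC: 57.45

candidate two-predictor models (AIC ascending):
                      lems + rms_eo_con               AIC   22.20
                      lems + rms_ra_con               AIC   27.94
                      lems + rms_io_con               AIC   33.96
                      ...

selected: ('lems', 'rms_eo_con'), AIC 22.20
  intercept    beta    0.696   OR    2.005   p 0.371
  lems         beta   -4.582   OR    0.010   p 0.009
  rms_eo_con   beta    2.405   OR   11.081   p 0.008

confusion matrix (positive = WD): TP 18  FN 2  FP 3  TN 17
accuracy 0.875  sensitivity 0.900  specificity 0.850
AUC 0.983 (95% CI 0.943-1.000)
```

Read: the minimum-AIC model pairs the LEMS with the contralateral-EO
RMS%. The negative standardized LEMS coefficient means stronger legs
predict independence; the positive EO coefficient means elevated
contralateral trunk activation — compensation — predicts dependence.
Coefficients and odds ratios are on the standardized-predictor scale.

The other examples cover cohort synthesis (`01`), signal-level feature
extraction against ground truth (`02`), group statistics (`03`) and the
one-command pipeline (`05`). A thin CLI mirrors the stages:

```sh
slrwalk run --synthesize --n-per-group 20 --seed 1 --out run/
slrwalk synth --n-per-group 4 --seed 2 --out cohort/   # trial CSVs + covariates.csv
slrwalk features --cohort cohort/ --out features.csv
slrwalk stats --features features.csv --out stats.csv
slrwalk predict --features features.csv --out report/ --seed 1
```

## Trial file dialect

One CSV per trial: `#`-header lines (`role`, `fs_hz`), then a `time`
column (s) followed by the 8 EMG channels — `rf_ips, bf_con, ra_ips,
ra_con, io_ips, io_con, eo_ips, eo_con` (sides relative to the raised
leg; volts) — and 18 IMU columns `{asis,thigh,lower_leg}_{acc,gyr}_{x,y,z}`
(g and deg/s). `covariates.csv` holds one row per patient; missing values
are empty cells. UTF-8, `.` decimal separator.

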