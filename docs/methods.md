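# Methods

This note documents the models, parameters and numerical choices behind
`slrwalk`, and what the synthetic cohort does and does not establish.

## Signal model of the synthetic cohort

**EMG.** Each channel is amplitude-scaled, spectrally shaped Gaussian
noise: white noise is multiplied in the frequency domain by a Gaussian
bump centred on the muscle's spectral centroid (SD = min(0.25·f_c,
distance to the 5/450 Hz band edges ÷ 3), so the bump stays inside the
analysis band and its spectral median equals the centroid), then rescaled
to a target RMS. This makes both downstream features controllable ground
truth: windowed RMS is proportional to the amplitude parameter (exactly
linear at fixed seed) and the median frequency equals the centroid to
within a few percent. It deliberately omits motor-unit structure,
nonstationarity within the hold, movement artefact and electrode noise.

**IMU.** The pitch trajectory is 0° at rest, a C¹ half-cosine ramp to the
raise angle (default 30° in 1 s), then constant through the 10-s hold.
The accelerometer reads gravity projected through the pitch (so the rest
posture is exactly (0, 0, 1) g and inclination inverts to the true pitch)
plus rigid-body tangential/centripetal terms at a site-specific lever arm
(0 m pelvis, 0.25 m thigh, 0.50 m lower leg; the pelvis sensor does not
rotate), plus white noise (default SD 0.02 g per axis). The gyroscope is
the analytic pitch rate plus noise (default SD 0.5 deg/s). Units: g,
degrees, arbitrary volts — chosen so the gravity invariants are exact.

**Covariates.** Per-group means/SDs follow the published cohort
description (e.g. LEMS 38.2 ± 6.4 walking-dependent vs 48.4 ± 3.1
walking-independent; sex 18:2 vs 16:4 male:female). Motor scores are
drawn bivariate-normal and truncated to [0, 50]; the within-group
UEMS–LEMS correlation is solved from the pooled target (0.54) by a
moment decomposition of pooled covariance into between- and within-group
parts. Truncation at the 50-point ceiling compresses the
walking-independent LEMS distribution (its post-truncation mean sits
~1.4 points below the configured 48.4); marginal-mean recovery is
therefore only asserted for covariates away from their bounds.

**Group effect and the compensation coupling.** The generating effect is
the published LEMS deficit plus elevated contralateral external-oblique
(and mildly internal-oblique) activation in the walking-dependent group
(default gains 0.85 vs 0.60 of the normalization-trial amplitude; no
published group activation summaries exist, so these are free parameters
of the generator). Because both effects separate the groups, their
pooled correlation would otherwise be strongly negative — which would
make the model-selection step *exclude* the generating pair. The
published correlation screen found no significant LEMS–activation
correlation, which implies a positive within-group coupling (stronger
patients activate more) offsetting the between-group component. The
generator encodes exactly that: the per-patient log-gain of the
compensation muscles is correlated with the patient's within-group LEMS
z-score, with the coupling solved from the configured means/SDs so the
pooled covariance is approximately zero. Per-patient gains and centroids
are lognormal (σ = 0.30 and 0.05); trials add within-patient activation
variability (σ = 0.15).

**Two generator paths.** `generate_cohort` emits full 1000-Hz signals;
`generate_feature_table` emits the same per-patient parameter draws
directly as the 26-predictor table (RMS% = 100 × gain with the 3-trial
measurement spread, MDF = centroid, combined acceleration as a lognormal
spread around each site's motion/noise floor). Model-selection
simulations (50 cohorts of 200 patients) use the feature path; the
signal path is exercised end-to-end on smaller cohorts. Problem sizes
throughout (40-patient pipeline runs, 200-patient recovery cohorts,
100-trial onset studies) were chosen as the smallest at which the
studied properties are stable.

**What passing tests show.** Recovery of RMS%, MDF, onsets and the
generating predictor pair demonstrates internal consistency of the
analysis chain under the generator's assumptions — stationary
narrow-band EMG, a clean pitch trajectory, lognormal activation
structure. It does not validate the clinical claim on real recordings,
which carry artefacts, nonstationarity and inter-session variability the
generator does not emulate.

## Analysis-stage choices

**Pitch estimation.** First-order complementary filter at 0.5 Hz
crossover: low-passed accelerometer inclination (atan2 of the along-limb
over perpendicular axis) plus high-passed integrated gyroscope. The
recursion is seeded with the mean inclination of the first 0.25 s rather
than a single sample, so the settling transient does not pollute the
short pre-movement baseline. Full 3-D orientation tracking is out of
scope.

**Onset rule.** First sample where pitch exceeds the baseline median
(first 0.5 s) + 2° sustained for ≥ 0.2 s, then backtracked to the last
sample within 0.25° of baseline. The threshold makes the crossing
unambiguous at the configured sensor noise; the backtrack removes the
rate-dependent lag between movement start and threshold crossing (a pure
crossing rule is late by ~0.17 s on a 1-s half-cosine raise). All three
values are configurable.

**Window summary.** The combined acceleration is summarized by its
time-mean over the 10-s window before trial averaging (peak available by
option); the source description fixes only "mean of the 3 trials", not
the within-window statistic.

**Filtering.** All filters are zero-lag (forward–backward) 4th-order
Butterworth, implemented as second-order sections: at 1 Hz (and 5 Hz) on
a 1000-Hz record the cutoff sits near 0.1% of Nyquist, where the
polynomial transfer-function form is numerically unstable (≈5% passband
amplitude error observed). Edge handling is the default odd-reflection
padding; assertions about DC rejection exclude a 0.5-s settling region
per edge.

**Windowed RMS.** Non-overlapping 50-ms windows; a trailing partial
window is discarded so every value summarizes a full window. Note the
windows-then-trials averaging order for the normalization reference
(windows averaged within the central 3 s, then across the 3 trials).
Window-RMS of narrow-band noise carries a small (~5%) downward bias from
the few degrees of freedom per window; it cancels in the normalized
percentage because reference and task trials share it.

**Wavelet MDF.** 20 scale pseudo-frequencies log-spaced over 10–450 Hz
(the count and wavelet — complex Morlet, bandwidth and center frequency
1 — are fixed; the scale values are a package choice), mapped to scales
via the wavelet's center frequency. Squared coefficient magnitudes are
summed over the analysis window per scale; the MDF is where the
cumulative frequency-ordered power reaches half the total, linearly
interpolated with each scale's mass centred at its pseudo-frequency
(midpoint convention) — so one active scale returns exactly its
frequency and two equal scales return their midpoint. The per-time
alternative (MDF per sample, then averaged) is a defensible second
reading of the procedure; the time-summed variant is implemented. The
constant-Q scale spacing biases the MDF a few percent low relative to a
Fourier periodogram median; the cross-oracle tolerance (15%) covers
this.

**Test dispatch.** Normality via Shapiro–Wilk per group and homogeneity
via median-centered Levene, both at α = .05 (the gate tests are named
nowhere in the source description; these are the common choices). When
either fails the comparison falls back to Mann–Whitney (not Welch),
mirroring the either/or phrasing of the procedure; the U p-value is
exact for ≤ 12 untied observations per group, tie-corrected normal
otherwise.

**Exact contingency tests.** The r×c Freeman–Halton test enumerates all
margin-constrained tables with exact rational arithmetic (`fractions`),
summing the probabilities of tables no more probable than the observed
one. Feasible because cohort tables here are small (2×2, 2×3 at n = 40);
scipy's 2×2 implementation serves as an independent cross-check in the
tests.

**Lasso screen.** Predictors standardized to zero mean/unit SD;
λ grid of 100 log-spaced values from the smallest all-zero λ
(max|Xᵀ(y − ȳ)|/n) down 4 decades; 10-fold outcome-stratified seeded CV
minimizing mean held-out binomial deviance ("smallest error" is
otherwise undefined), ties toward the larger λ; refit on all data at the
optimum. The L1 solver is liblinear with C = 1/(nλ) and a large
intercept scaling so the intercept is effectively unpenalized.

**Candidate fits and AIC.** Maximum-likelihood logistic fits
(statsmodels) on the standardized pair; Wald SEs/p-values; odds ratios
exp(β) with 95% Wald CIs, all on the standardized scale (the published
coefficient/OR columns are not mutually consistent — exp(estimate) ≠
printed OR — so no attempt is made to match that scale). Fits with
|β| > 15 or non-convergence are flagged (quasi-)separated: the AIC is
computed from the likelihood actually achieved at the returned
coefficients, so a genuinely separated fit approaches the 2k path limit
while a merely failed fit keeps its poor likelihood and cannot win
selection. Ties in AIC break to the earlier pair in the deterministic
sorted-pair order.

**Evaluation.** Walking-dependent is the positive class; default
in-sample predictions of the final fit at threshold 0.5 (a 40-patient
confusion matrix over the whole cohort), with stratified 10-fold
cross-validated prediction as an option since the source is ambiguous
about which its matrix reports. AUC CI: stratified bootstrap percentile,
2000 resamples, seeded. AUC equals the Mann–Whitney U formulation on the
same scores (tested exactly).

**Imputation.** Missing values take the overall (both groups pooled)
median of their variable; a patient without normalization trials loses
all eight RMS% features (mirroring the absent bilateral-SLR EMG case),
surfaced as NaN and imputed the same way.

## Known limitations

- The generator's group effect sizes for activation features are free
  parameters; no published values anchor them.
- Dominant-leg logic is not simulated; all SLR trials are
  nondominant-side by construction, and channel names are
  ipsilateral/contralateral rather than left/right.
- At the configured (strong) effects, ~half of 40-patient cohorts are
  in-sample separable, giving degenerate-AIC winning models; this is a
  property of the study conditions, not a defect of the selection rule.
- The exact Freeman–Halton enumeration is exponential in table size; it
  is intended for small clinical tables only.
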