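# Methods

This note documents the models and numerical choices behind `wristpaee`:
what the synthetic cohort emulates, how the signal metrics and non-wear
rules are defined, how the calibration models are estimated, and what
the package's passing tests do and do not demonstrate about real data.

## The estimation problem

A wrist accelerometer records triaxial acceleration (here 60 Hz, units
of g) that mixes gravity, human movement and sensor noise. The quantity
of epidemiological interest is PAEE, an intensity time series in
J·min⁻¹·kg⁻¹. The package derives movement metrics from the raw signal,
calibrates them against a criterion PAEE signal (in the emulated study,
individually calibrated combined heart-rate + trunk-acceleration
sensing) on a training subsample, and evaluates the resulting prediction
equations in held-out participants, including whether they reproduce the
PAEE–BMI association obtained with the criterion.

## Signal processing

* **Calibration.** Offsets and gains drift per axis; during stationary
  periods the vector magnitude should be exactly 1 g. Stationary windows
  (10 s, per-axis SD < 13 mg) are collected; if they span ≥ 6 distinct
  orientations (pairwise > 15°), per-axis offset and gain are fitted by
  least squares so that `(raw − offset)/gain` has unit stationary VM.
  Fewer orientations leave the problem underdetermined: the caller gets
  a `CalibrationInfeasibleError` and falls back to identity with a
  warning. This is a deliberately simplified stationary-period
  calibration, not a full production auto-calibration (no temperature
  correction, no sphere-fit weighting).
* **Filtering.** Both filters are 4th-order Butterworth applied
  forward–backward (zero phase): 20 Hz low-pass for sensor noise, 0.2 Hz
  high-pass on the VM series for HPFVM. The filter family and order are
  a design choice (the standard accelerometry default); zero-phase
  filtering avoids shifting energy across epoch boundaries. Tests check
  the implementation against the closed-form magnitude response — the
  analog prototype in the passband, and the bilinear-warped digital
  response near Nyquist, where the two legitimately differ.
* **Metrics.** ENMO subtracts 1 g from VM and truncates negative values
  to zero per sample. HPFVM high-passes VM and takes the absolute value
  per sample before averaging; a high-passed signal is signed and the
  rectified mean is what makes it a non-negative intensity comparable to
  ENMO (for a sinusoid of amplitude *a*, epoch-mean HPFVM → 2a/π, ENMO
  → a/π, which is why HPFVM ≈ 1.5× ENMO at equal movement).
* **Epochs.** Grids are anchored at each participant's first sample,
  half-open intervals [t, t+300 s), arithmetic means, outputs in mg. An
  epoch is valid only if fully covered by wear-time samples; model
  fitting additionally requires both sensors valid. 300 s divides the
  day exactly (288 epochs/day).

## Non-wear rules

Wrist: per-axis SD computed in consecutive non-overlapping 60 s blocks;
a run of blocks with all three axes below 13 mg lasting ≥ 1 h is
non-wear. Block windows make the rule deterministic with boundary error
bounded by one block. Combined sensor: a contiguous run of exactly zero
epoch trunk movement lasting strictly > 90 min with the heart-rate
validity flag false throughout (zero movement with valid heart rate is
sleep). "Non-physiological heart rate" is represented as an upstream
boolean per epoch; no heart-rate waveform cleaning is implemented. At
cohort scale only epoch summaries exist, so the pipeline uses an
epoch-level wrist proxy (runs of exactly zero wrist movement ≥ 1 h); the
raw-signal rule is exercised on generated 60 Hz bouts.

## Synthetic cohort generator

The generator is the package's stand-in for a free-living validation
study; its defaults are the study conditions (n = 1695, six days,
5-minute epochs) and are not tuned per experiment.

* **Cohort.** Sex 48/52 male/female; age, height and sex-specific BMI
  means/SDs match the emulated population (men ≈ 49.7 y, 1.78 m,
  27.0 kg·m⁻²; women ≈ 50.1 y, 1.63 m, 26.1 kg·m⁻²). BMI includes an
  inverse dependence on habitual PAEE (−0.08 kg·m⁻² per J·min⁻¹·kg⁻¹)
  plus residual noise, so the association analysis has a known target.
* **Latent intensity.** Each participant has a habitual intensity level
  μ_p (lognormal between-person σ = 0.27 around 36.7 J·min⁻¹·kg⁻¹,
  identical by sex — observed wrist acceleration differs little between
  men and women). Epoch intensity is μ_p × a diurnal profile (sleep
  block 23:00–07:00 at 4% of waking level, sinusoidal midday bump,
  mean one) × mean-one lognormal within-person variation (σ = 0.8),
  giving the right-skewed intensity distribution characteristic of
  free-living data. An AR(1) parameter on the within-person innovations
  is exposed but defaults to 0: no published value constrains it, and
  serial correlation does not enter any epoch-level estimand used here.
* **Wrist truth.** The generator *inverts* known concave quadratic
  metric→PAEE curves, so the curvilinear relationship the models
  estimate exists by construction: PAEE = β₁m + β₂m² with vertices at
  1369 mg (HPFVM) and 983 mg (ENMO) — the global maxima the derived
  equations should reproduce — anchored so 46 mg HPFVM / 31 mg ENMO map
  to 36.4 J·min⁻¹·kg⁻¹. Wrist metrics are observed exactly by default
  (the predictor in the calibration models *is* the observed wrist
  signal; optional measurement-error parameters exist for attenuation
  experiments).
* **Criterion error.** Criterion PAEE = intensity × u_p × v_e with
  mean-one lognormal person factors u_p (σ = 0.287; sex-specific means
  1.05 for men, 0.954 for women, population mean 1) and epoch factors
  v_e (σ = 0.42). Multiplicative error keeps the criterion non-negative,
  reproduces the skewed error structure of heart-rate-based PAEE, and —
  crucially — preserves E[criterion | wrist metric] exactly on the truth
  curve, so the fitted fixed effects have an unambiguous target. The
  sex-specific calibration factors create both the male/female PAEE gap
  (≈ 38 vs 34.5 J·min⁻¹·kg⁻¹) and the opposite-signed sex biases that
  the stratified evaluation should detect; σ values were chosen so the
  held-out between-individual explained variance sits near 45–50% and
  the epoch RMSE near 35 J·min⁻¹·kg⁻¹, the ranges such combined-sensing
  criteria achieve. Trunk acceleration is linear in HPFVM
  (0.026 + 0.002·HPFVM m·s⁻²) with its own multiplicative factors.
* **Non-wear injection.** Poisson episodes (0.15/day/sensor, 1.5–4 h):
  wrist episodes zero the wrist metrics; combined episodes zero trunk
  movement, invalidate heart rate and remove the criterion. Ground
  truth wear flags are kept, giving the detectors an exact target.
* **What the generator does not emulate.** ENMO and HPFVM are both
  deterministic transforms of the same latent intensity, so the
  simulator cannot discriminate the two metric families the way real
  data can (their relative performance differences here come from
  functional form only, and ENMO/HPFVM quadratic models are effective
  ties). There is no activity-type structure, no day-to-day behavioural
  autocorrelation by default, no device timing drift, and criterion
  error is independent of activity type. Passing tests therefore
  demonstrate correctness of the estimation machinery under a
  controlled, realistic-marginal generative model — not that wrist
  acceleration achieves any particular accuracy in a real population.

## Model estimation

The four models are random-intercept (participant-level) linear models
estimated by REML via `statsmodels.MixedLM`. The wrist metric is
mean-centred before squaring for conditioning; coefficients are
back-transformed to the raw-mg scale for reporting. Fixed-effect
standard errors are **cluster-robust** (CR1 sandwich over participants,
built on the fitted GLS weights): with criterion error that scales with
intensity, model-based REML standard errors understate the sampling
variance of the fixed effects several-fold, while the sandwich is valid
under arbitrary within-person covariance and heteroscedasticity.
Variance components (random-intercept SD, residual SD) are reported from
REML. Degenerate designs (zero wrist variance, singular fits) fall back
to pooled OLS with cluster-robust errors, logged; noise-free data short-
circuits to the exact least-squares solution. Predictions use fixed
effects only — held-out participants have no estimated intercept — with
flat truncation at the quadratic vertex and a floor at zero, making the
prediction function monotone non-decreasing.

The linear models (1 and 3) are intentionally misspecified against the
quadratic truth; their recovery target is defined as the population
least-squares projection of the truth curve onto {1, m}, computed by an
independent large-sample Monte Carlo over the latent epoch distribution.

The 60/40 split is at the person level (train size = round(0.6·n) on a
seeded shuffle); all of a person's epochs share the assignment. Model
selection minimises held-out RMSE on both outcomes, resolving
disagreement by PAEE RMSE and exact PAEE ties by trunk RMSE.

## Evaluation statistics

Explained variance is partitioned as in repeated-measures practice:
between = squared Pearson correlation of participant means, within =
squared correlation of pooled within-participant deviations; the
underlying sum-of-squares partition (total = between + within) is an
exact identity and is tested to 1e-9 relative. Errors are
predicted − criterion, so positive bias is overestimation. Limits of
agreement are mean ± 1.96 SD of epoch-level errors (a per-participant
option exists; the aggregation level is a reporting choice). BMI
categories are <25, [25, 30), ≥30 kg·m⁻²; age tertiles come from the
test-set empirical distribution with boundary values assigned to the
lower tertile; bias trends regress participant-mean error on sex and
mean-centred age and BMI. RMSE is epoch-level. MET conversion divides by
71 J·min⁻¹·kg⁻¹.

## Association analysis

Participant-level OLS of BMI on wear-time mean PAEE (per source),
adjusted for age and sex (female = 1), with normal-theory 95% CIs.
Wear-time means use only epochs where the source is valid; for model
predictions, epochs lacking a criterion value are excluded too, keeping
all sources on identical epochs. Source comparison flags whether each
model's point estimate falls inside the criterion CI and whether its CI
covers the criterion point estimate.

## Problem sizes and determinism

The default replica is the full emulated study (1695 participants ×
1728 epochs, ≈ 2.9 M rows; a complete run takes a few minutes on one
core). The truth-recovery experiment uses 20 replicates of 300
participants — large enough that the robust CIs are narrow relative to
the coefficients, small enough to rerun routinely. All randomness flows
from integer seeds through `numpy.random.Generator` streams keyed by
(seed, stage, participant); identical configurations produce
byte-identical CSV output, and pipeline stage seeds are derived from the
master seed by hashing the stage name.

## Known limitations

* The wrist non-wear rule needs raw signal; at epoch scale the pipeline
  substitutes the zero-movement proxy described above.
* The auto-calibration is a desk-scale simplification (see above).
* Robust-CI coverage of the mixed models is asymptotic in the number of
  participants; with very few clusters (tens) the CIs can undercover.
* The generator's equal-by-sex movement distribution and purely
  multiplicative criterion error are stylised; real sex differences in
  wrist placement, activity type and heart-rate calibration are richer.
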