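# Methods

## Scope and model

`parkscreen` implements a fixed-coefficient linear prediction of the
UPDRS3 motor score from objective motor tests, plus the pipeline that
develops and validates such a model.  The prediction equation is

    UPDRS3^ = b0 + b1·HRmv + b2·HRmv² + b3·FTmv + b4·T_peg (+ b5·age)

with HRmv and FTmv the hand-rotation and finger-tapping mean absolute
angular velocities (deg/s, non-dominant hand, first 12-s trial) and
T_peg the grooved-pegboard time (s, capped at 300).  The quadratic
hand-rotation term uses the raw, uncentered velocity; with the shipped
coefficients the equation is non-increasing in HRmv across the whole
plausible range (vertex at −b1/(2·b2) = 1255 deg/s).  Predictions are
returned raw — they can be negative for extremely fast performers — with
clipping at zero offered only as presentation; rank-based validation must
see raw values.  Screening positivity uses the ≥-cut-point convention at
every threshold, matching the dichotomized gold standards (clinician
score ≥ 10 and ≥ 15).

## Kinematic summary measures

The bradykinesia tasks oscillate around zero angular velocity on one
task-specific gyroscope axis (tapping: x; rotation: y); tremor tasks use
the root-sum-square of the three gyro axes and feed only the screening
stage.  Per trial, on the isolated axis:

- **mean velocity** — mean |v| over *all* sampled time points (not only
  within-cycle samples);
- **cycles** — spans between consecutive upward zero crossings of the
  low-pass-filtered (4th-order Butterworth, default cutoff 12 Hz,
  zero-phase), mean-centered series; candidate cycles with peak |v|
  below a floor (default 10 deg/s) are discarded as non-movement.
  Crossing detection uses a small relative tolerance (10⁻³ of the peak)
  so filter edge transients do not drop a boundary crossing;
- **mean peak velocity** — mean of per-cycle max |v|;
- **coefficient of variation** — SD/mean of per-cycle peaks (needs ≥ 2
  cycles, else missing);
- **decrement in peak velocity** — OLS slope of per-cycle peaks against
  cycle index divided by the mean peak: a relative, amplitude-scale-free
  change per cycle.  The first-vs-last-cycle ratio was considered and
  rejected as noisier;
- **cycles/second** — cycle count over trial duration;
- **decrement in cycles/second** — relative OLS slope of the per-cycle
  instantaneous rate (reciprocal cycle duration).

With zero cycles all cycle-based measures are missing but mean velocity
is still computed.  The exact cycle definition behind the published
measures is not public; the zero-crossing segmentation, cutoff and peak
floor are this package's operationalization and are keyword-configurable.
The measures satisfy (and the tests enforce) scale equivariance, the
2A/π identity for sinusoids, peak/mean → π/2, and sign-flip of both
decrements under time reversal.

A directional variant (mean |v| restricted to the positive- or
negative-going half of the movement) is provided for research use only;
isolating direction does not improve agreement with clinician ratings,
so the standard measures use the whole signal.

## Quality control

Trials shorter than 12 s (strict inequality; exactly 12.0 s passes) fail
as incomplete.  "Sensor failure" is operationalized on the isolated axis
as flat-lining (> 50% of consecutive sample pairs identical) or
saturation (> 10% of samples at |v| ≥ the 2000 deg/s full scale); all
three thresholds are arguments.  QC classifies, never raises.  The
`first_trial` aggregation (the published model's input) has no fallback:
a QC-failed first trial is an explicit insufficient-data error, while
`mean_of_trials` averages measure-wise over the remaining passing trials.

## Pegboard

Time to place 25 keyed pegs, with pegs placed/dropped counts.  A 300-s
administrative cap is applied; incomplete boards are recorded *at* the
cap (no completion-time extrapolation), preserving the ceiling visible in
real cohort data.  Whether that ceiling is a protocol cap or analysis
truncation is unknowable from the outside; the cap constant is an
argument.

## Model development

- **Screening**: Spearman ρ between each candidate measure and its
  matched clinician subscore; selected iff the sign matches the expected
  clinical direction AND (|ρ| > 0.20 OR p < 0.05) — direction is
  mandatory, the weak-correlation/significance clauses are an OR.
  Expected directions: pegboard time and drops, and the coefficient of
  variation, positive; velocities, cycle rates, pegs placed negative; the
  decrement slopes negative (a steeper decrement is a more negative
  slope).  Fewer than 3 complete pairs marks a feature unevaluable.
- **Nonlinearity**: LOWESS (span 0.8, tricube weights — the span is this
  package's default, not a published value) with a curvature flag when
  the smooth departs from the best straight line by more than 0.5× the
  linear fit's residual SD (an invented, configurable operationalization
  of "the graph suggests curvature"), followed by a formal test keeping
  x² iff its OLS p < 0.05.
- **Collinearity**: VIF_j = 1/(1 − R²_j) by explicit auxiliary
  regression, threshold 2, with the hand-rotation linear/quadratic pair
  exempt (inherently correlated, both retained to capture the curved
  association).
- **Fit**: OLS with conventional normal-theory CIs and p-values
  (HC1 robust variances available but off by default, since the choice
  in the original analysis is unstated).  The fitted coefficients are
  emitted in the same JSON dialect the predictor loads.

## Validation

Empirical ROC over all distinct thresholds (≥ positive); AUC is the
trapezoidal area, identical to Mann–Whitney concordance with ties ½ (an
exhaustive pairwise oracle enforces this on every small instance).  The
default AUC interval is DeLong's asymptotic variance via midrank
placement values; a seeded, stratified, vectorized percentile bootstrap
(default 2000 replicates) is the sensitivity alternative — the two agree
within 0.03 on moderate samples and the bootstrap's empirical coverage
is ~95% at n = 200 (500-replicate check in the suite).  Intervals are
truncated to [0, 1]; degenerate variances (perfect separation at tiny n)
clamp with a warning.  Continuous agreement is Spearman ρ with a
Fisher-z interval using variance 1.06/(n − 3); the CI method behind the
published intervals is unstated, so this conventional choice is
documented rather than claimed as a reproduction.  Percentages are
reported to one decimal; raw proportions are kept internally.

## Synthetic data

`simulate_cohort` draws age (normal, truncated below at 41), pegboard
time (normal, capped at 300 s) and the two mean velocities (normal)
independently from community marginals — defaults are the training
community's (age 51.3 ± 8.2; pegboard 116.2 ± 47.6 s; rotation
614.2 ± 177.0; tapping 352.0 ± 115.6 deg/s) — and generates the
clinician score as the published equation's linear predictor plus
N(0, 5²) residual noise.  No residual variance is published; 5.0 points
is chosen to make the simulated score dispersion compatible with the
observed community SDs and is a profile field.  Because OLS is unbiased
conditional on any design, refitting on such a cohort is a clean
parameter-recovery experiment; the suite checks recovery within 3
Monte-Carlo SEs at n = 100,000 and exact recovery at residual SD 0.

Real predictors co-vary, so with independent draws the linear predictor's
mean (~7.6 under training marginals) does not reproduce a real
community's observed mean score.  A profile may therefore set a target
mean, implemented as a closed-form intercept offset (target minus the
analytic E[linear predictor], using the truncated-normal age mean, the
censored-normal pegboard mean and E[X²] = μ² + σ² for the squared term).
Slopes are never adjusted, so recovery and all rank-based validation are
unaffected; the default profile sets no target.  The paired-community
generator targets means 9.1 (n = 275) and 3.9 (n = 90).  For the same
reason, single-predictor (unadjusted) coefficients are *not* recovery
targets: they depend on the real, unpublished predictor correlations.

`simulate_trial_signal` writes a six-channel trial whose movement axis
carries A_k·sin(2πft + φ) with A_k = A₀(1 − d·k) decaying per cycle k,
plus optional tremor sinusoid and white noise; off-axis channels carry
low-amplitude noise.  Defaults approximate brisk task performance (3 Hz
tapping, 2 Hz rotation, amplitudes π/2 × the community-mean velocities).
When a target mean velocity is requested the first-cycle amplitude
compensates for the decay factor 1 − d(K−1)/2 so the realized mean |v|
hits the target.  Severity couples to the signal through amplitude:
participants drawn with lower mean velocities get proportionally smaller
oscillations (and thus higher predicted scores).

What the generator does **not** emulate: predictor–age correlations, the
half-point granularity of real clinician scores (optional rounding flag),
within-participant trial-to-trial learning/fatigue, hand asymmetry, and
any exposure–response structure.  The synthetic bradykinesia subscore is
a coarse monotone function of the latent score plus noise, sufficient to
exercise the screening stage, not a clinical model.  Passing tests
therefore demonstrate internal consistency of the pipeline under its own
generative assumptions, not field performance; the published field AUCs
(0.81–0.91) are properties of unreleased data and are deliberately not
test targets — the end-to-end rehearsal asserts only AUC > 0.7.

## Numerical and design choices

- Sample spacing is taken as uniform at the sidecar's sample rate; the
  CSV time column is informative only (validated monotone).
- Duration is sample count / sample rate, so a 640-row 64-Hz file is a
  readable 10-s trial that QC then rejects.
- Problem sizes in the suite (100,000-participant recovery; 500-replicate
  coverage checks; 1,000 small ROC instances) were chosen so each
  statistical check has Monte-Carlo error well inside its asserted
  tolerance while the whole suite stays quick.
- Community-mean checks average several replicate n = 275 draws because a
  single draw's mean has SD ≈ 0.36 points; the average tests the
  calibration property rather than one draw's luck.
- All randomness flows through `numpy.random.Generator` objects seeded at
  the call boundary; paired cohorts use spawned `SeedSequence` children.

## Known limitations

- The cycle definition, sensor-failure thresholds, LOWESS span and
  curvature tolerance are documented operationalizations of procedures
  whose exact published definitions are unavailable; results can shift
  slightly under other reasonable choices (all are exposed as arguments).
- The units of the kinematic inputs to the shipped coefficients are
  inferred (deg/s is the natural gyroscope output and matches the
  published descriptive magnitudes); the model JSON records units to keep
  this auditable.
- DeLong/Fisher-z intervals are asymptotic; at very small n prefer the
  bootstrap alternatives.
- Predictions for inputs far outside the observed ranges (rotation
  velocity > ~1255 deg/s) leave the monotone regime of the quadratic
  term and should not be interpreted.
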