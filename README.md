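# parkscreen

Rapid motor-task screening for parkinsonism in settings without access to
a neurologist.  The package predicts the UPDRS3 motor score — the standard
clinician-rated quantification of parkinsonian signs — from a <10-minute
battery of objective tests that trained non-clinicians can administer:
two wearable-gyroscope kinematic tasks (finger tapping and hand rotation),
the grooved pegboard, and age.  It also ships the full model-development
(feature screening, nonlinearity diagnostics, multicollinearity checks,
OLS fit) and ROC-validation pipeline, exercisable end to end on synthetic
cohorts and synthetic sensor signals.

## The model

For the **non-dominant hand, first trial**, with mean angular velocities
in deg/s and pegboard time in seconds:

```
UPDRS3^ = 13.8134 − 0.0251·HRmv + 0.00001·HRmv² − 0.0081·FTmv
          + 0.0374·pegboard_time + 0.0685·age
```

where `HRmv` and `FTmv` are the hand-rotation and finger-tapping mean
absolute angular velocities on the task's isolated gyroscope axis (y for
rotation, x for tapping) over a 12-s, 64-Hz trial.  An age-free variant
(intercept 17.0251; −0.0245, 0.00001, −0.0093, 0.0421) is provided for
settings where age may proxy for an exposure of interest.  Both
coefficient sets ship as versioned JSON (`parkscreen/data/`), so a
retrained model is a drop-in replacement.  A participant screens positive
when the predicted score reaches a chosen cut point (≥ convention;
default 9).

Six kinematic summary measures are computed per trial — mean velocity,
mean peak velocity, coefficient of variation of per-cycle peaks, relative
per-cycle decrement of peak velocity, cycles/second, and relative
per-cycle decrement of the cycle rate — of which the two mean velocities
feed the prediction equation.

## Worked example

```python
from parkscreen import classify, evaluate, load_published_model, summarize_pegboard

model = load_published_model("with_age")
pegboard = summarize_pegboard(raw_time_s=103.8, pegs_placed=25, pegs_dropped=0)
score = evaluate(model, 610.9, 347.3, pegboard.time_s, 50.0)
print(f"{score:.2f}", classify(score, 9.0))
```

prints `6.71 screen_negative`: a participant at the training-community
median on every test sits well below the screening cut.  A slower, older
participant (`evaluate(model, 420.0, 220.0, 210.0, 67.0)`) scores
`15.70` → `screen_positive`, above even the cut of 15 used to flag
functionally impairing parkinsonism.

The `examples/` directory holds one short script per capability:
single-participant prediction, feature extraction from a raw gyroscope
signal, the model-development diagnostics, and a full
train-on-one-community / validate-on-the-other rehearsal.  Running
`examples/train_and_validate.py` refits the equation on a simulated
higher-severity cohort (n=275) and reports, for the simulated
lower-severity cohort (n=90), an external AUC of 0.91 (95% CI 0.85,
0.97) for clinician score ≥ 10 with Spearman agreement 0.55 — numbers
printed by the script itself.

The same pipeline is available from a shell:

```
parkscreen simulate --community exposed --seed 17 --out cohort.csv
parkscreen train    --cohort cohort.csv --features cohort_features.csv --out model.json
parkscreen predict  --cohort other.csv --features other_features.csv --model model.json --out preds.csv
parkscreen validate --predictions preds.csv --cohort other.csv --gold-cut 10 --out roc.json
```

Every command writes a JSON provenance record (options, package version,
input digests) beside its output.

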