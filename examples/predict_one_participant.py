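"""Predict a UPDRS3 motor score for one participant from their test results.

Inputs are the non-dominant hand's first-trial mean angular velocities for
hand rotation and finger tapping (deg/s), the grooved pegboard time (s)
and age.  The printed score estimates the clinician-rated motor exam
total; the screen label dichotomizes it at the default cut point of 9.
"""

from parkscreen import (
    classify,
    evaluate,
    load_published_model,
    summarize_pegboard,
)

model = load_published_model("with_age")

# a typical participant: values near the training-community medians
hand_rotation_mv = 610.9   # deg/s
finger_tapping_mv = 347.3  # deg/s
pegboard = summarize_pegboard(raw_time_s=103.8, pegs_placed=25, pegs_dropped=0)
age = 50.0

score = evaluate(model, hand_rotation_mv, finger_tapping_mv, pegboard.time_s, age)
print(f"predicted UPDRS3: {score:.2f} points")
print(f"screen at cut point 9: {classify(score, 9.0)}")

# the same participant, slower and older: the score rises
slow = evaluate(model, 420.0, 220.0, 210.0, 67.0)
print(f"slower/older participant: {slow:.2f} points -> {classify(slow, 9.0)}")

# age-free variant for settings where age may proxy for exposure duration
age_free = load_published_model("age_free")
print(f"age-free model, same inputs: {evaluate(age_free, 420.0, 220.0, 210.0):.2f}")
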