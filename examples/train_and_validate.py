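"""Full rehearsal: simulate two communities, refit the model on one and
validate it externally on the other.

The higher-severity cohort (n=275, mean motor score ~9) plays the training
community; the lower-severity cohort (n=90, mean ~4) the external
validation community.  Reported: the refitted coefficients, the external
AUC for clinician score >= 10 with its DeLong CI, operating points at
example cut points, and rank agreement between predicted and simulated
clinician scores.
"""

import parkscreen as ps
from parkscreen.kinematic_features import pivot_model_inputs

communities = ps.simulate_two_communities(seed=17)
train_cohort, train_features = communities["exposed"]
ext_cohort, ext_features = communities["non_exposed"]

fit = ps.fit_final_model(
    train_cohort.merge(pivot_model_inputs(train_features), on="participant_id")
)
c = fit.coefficients
print(f"refit on n={fit.n}: intercept {c.intercept:.2f}, "
      f"HR {c.hand_rotation_mv:.4f}, HR^2 {c.hand_rotation_mv_squared:.6f}, "
      f"FT {c.finger_tapping_mv:.4f}, pegboard {c.pegboard_time:.4f}, "
      f"age {c.age:.4f}")

preds = ps.predict_cohort(ext_cohort, pivot_model_inputs(ext_features), c)
merged = preds.merge(
    ext_cohort[["participant_id", "updrs3_total"]], on="participant_id"
)
scores = merged["predicted_updrs3"].to_numpy()
labels = (merged["updrs3_total"] >= 10).astype(int).to_numpy()

roc = ps.roc_curve(scores, labels, gold_cut=10)
lo, hi = ps.auc_ci(scores, labels)
print(f"external AUC for UPDRS3 >= 10: {roc.auc:.2f} (95% CI {lo:.2f}, {hi:.2f})")
for cut in (4.0, 8.0, 9.0):
    sens, spec = ps.sens_spec_at(scores, labels, cut)
    print(f"  cut {cut:>4}: sensitivity {sens:5.1f}%  specificity {spec:5.1f}%")

agree = ps.spearman_agreement(scores, merged["updrs3_total"].to_numpy())
print(f"Spearman agreement: {agree.spearman_rho:.2f} "
      f"(95% CI {agree.ci_low:.2f}, {agree.ci_high:.2f})")
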