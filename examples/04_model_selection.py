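"""The 4-step prediction-model construction on a 40-patient cohort.

Median imputation -> cross-validated lasso screen -> enumeration of
uncorrelated predictor pairs -> AIC selection, followed by the confusion
matrix, accuracy/sensitivity/specificity and AUC of the winning
two-predictor logistic model (walking-dependent is the positive class).
"""

from slrwalk.prediction import build_prediction_model, null_model_aic, outcome_vector
from slrwalk.synthetic import PAPER_MISSINGNESS, CohortConfig, generate_feature_table

table = generate_feature_table(
    CohortConfig(n_per_group=20, seed=4, missingness=PAPER_MISSINGNESS))
report = build_prediction_model(table, seed=4)

print(f"imputed cells: {report.n_imputed}")
print(f"lasso optimal lambda: {report.screen.optimal_lambda:.3g}")
print(f"nonzero predictors: {report.screen.nonzero}")
print(f"intercept-only baseline AIC: {null_model_aic(outcome_vector(table)):.2f}\n")

print("candidate two-predictor models (AIC ascending):")
for cand in sorted(report.candidates, key=lambda c: c.aic)[:8]:
    flag = "  (separated)" if cand.separated else ""
    print(f"  {cand.pair[0]:>24} + {cand.pair[1]:<24} AIC {cand.aic:7.2f}{flag}")

best = report.best
print(f"\nselected: {best.pair}, AIC {best.aic:.2f}")
for name in ("intercept", *best.pair):
    print(f"  {name:<12} beta {best.params[name]:8.3f}   OR {best.odds_ratios[name]:8.3f}"
          f"   p {best.p_values[name]:.3f}")

e = report.evaluation
print(f"\nconfusion matrix (positive = WD): TP {e.tp}  FN {e.fn}  FP {e.fp}  TN {e.tn}")
print(f"accuracy {e.accuracy:.3f}  sensitivity {e.sensitivity:.3f}  "
      f"specificity {e.specificity:.3f}")
print(f"AUC {e.auc:.3f} (95% CI {e.auc_ci[0]:.3f}-{e.auc_ci[1]:.3f})")

# A low AIC relative to the ~57 intercept-only baseline, with the LEMS
# and contralateral-EO pair selected, mirrors the structure the cohort
# generator encodes: leg strength predicts independence, elevated
# contralateral trunk activation predicts dependence.
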