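"""Train linear and random-forest scoring functions on synthetic complexes.

Generates 600 synthetic complexes whose affinity surface is nonlinear in the
six Vina features, trains an OLS recalibration and a 3-seed random-forest
ensemble (OOB-selected mtry), and prints the scoring-power metrics of each on
a held-out test set.
"""

import pandas as pd

from vinarf import (
    LabelGenSpec,
    PredictionSet,
    RFConfig,
    compute_metrics,
    evaluate_ensemble,
    fit_mlr,
    fit_rf_ensemble,
    gen_dataset,
    predict,
)

table, y, _, _ = gen_dataset(
    600, seed=7, scheme="vina6",
    label_spec=LabelGenSpec(mechanism="nonlinear", noise_sd=0.5),
)
X_train, X_test = table.iloc[:500], table.iloc[500:]
y_train, y_test = y[:500], y[500:]

lm = fit_mlr(X_train, y_train)
mlr_report = compute_metrics(PredictionSet(predict(lm, X_test), y_test))

config = RFConfig(n_trees=100, mtry_grid=(1, 2, 3), seeds=(1, 2, 3))
ens = evaluate_ensemble(fit_rf_ensemble(X_train, y_train, config), X_test, y_test)
rf_report = ens.median_report

print(f"{'model':10s} {'RMSE':>6s} {'SD':>6s} {'Rp':>6s} {'Rs':>6s}")
print(f"{'MLR':10s} {mlr_report.rmse:6.3f} {mlr_report.sd:6.3f} "
      f"{mlr_report.rp:6.3f} {mlr_report.rs:6.3f}")
print(f"{'RF median':10s} {rf_report.rmse:6.3f} {rf_report.sd:6.3f} "
      f"{rf_report.rp:6.3f} {rf_report.rs:6.3f}")
print("selected mtry per seed:", {m.seed: m.selected_mtry for m in ens.models})
print("(the forest captures the feature interactions the linear model cannot,"
      " so its RMSE is lower and its correlations higher)")
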