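"""LOOCV evaluation of SVM, random forest and logistic regression.

Each subject is predicted by models trained on the remaining 98, with
training-only standardisation and an inner stratified grid search; a
single ROC is pooled from the held-out scores.  A small permutation
test illustrates the significance machinery (the study-scale protocol
uses 5000 permutations).
"""

from neurodc import simulate_feature_table
from neurodc.classify import ModelSpec, permutation_test, run_all_models

table = simulate_feature_table(n1=51, n2=48, seed=11)
grids = {"random_forest": {"n_estimators": [100], "max_depth": [None]}}
reports, comparison = run_all_models(
    table.matrix, table.y, table.region_names, seed=11, grids=grids
)
print(comparison.round(3).to_string())

spec = ModelSpec(model="svm_linear", hyperparameter_grid={"C": [1.0]}, seed=11)
p, summary = permutation_test(
    spec, table.matrix, table.y, n_permutations=99, seed=11
)
print(f"\nSVM pooled-LOOCV AUC {summary['observed']:.3f}, "
      f"permutation p = {p:.3f} ({summary['statistic']}, 99 shuffles)")
# AUCs in the 0.8-0.9 range are expected: the table is drawn from the
# published per-group feature parameters, which encode the reported
# separability (AUC 0.78), and drawing the features independently
# removes their real-data correlations, helping the classifiers a little.
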