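"""Discriminate experts from non-experts with nested repeated CV.

Runs the three classifiers (SVM, PCA-SVM, GBDT) on a study-sized cohort
under stratified nested 10x10-fold cross-validation (grid search in the
inner folds only), with a reduced repetition count so the example finishes
in a couple of minutes, then compares the paired accuracy distributions.
"""

import dataclasses

import mocapskill as m

cohort = m.generate_cohort(m.SyntheticCohortConfig(seed=42))  # 32/18/20
run_config = dataclasses.replace(m.RunConfig(), repetitions=3)
features = m.compute_features(cohort, run_config)

results = m.run_discrimination(features, "two_group", run_config)
for kind, res in results.items():
    lo, hi = res.iqr
    print(f"{kind:8s} median accuracy {res.median:.3f} (IQR {lo:.3f}-{hi:.3f})")

comparison = m.compare_models(results)
print(f"\nFriedman p = {comparison.friedman_p:.3g} across the three models")
print(
    "\nAccuracies well above the 0.543 majority-class rate show the "
    "kinematic metrics carry an expertise signal; with only 3 repetitions "
    "the model ranking is indicative, not stable (the pipeline default is "
    "100 repetitions)."
)
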