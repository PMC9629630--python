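"""Run the whole pipeline end to end and print the report.

simulate -> metrics -> screening/PCA -> classification, all governed by
one config and one seed, with artifact hashes recorded in a manifest so a
rerun is verifiably identical.  Uses a small cohort and tiny grids to
finish quickly; the same call scales to the full study configuration.
"""

import tempfile
from pathlib import Path

import mocapskill as m
from mocapskill.pipeline import run_pipeline

sim_config = m.SyntheticCohortConfig(
    n_experts=8, n_intermediates=8, n_novices=8, goals_per_trial=6, seed=5
)
run_config = m.RunConfig(
    repetitions=2, outer_k=4, inner_k=2,
    svm_grid={"C": [1.0, 10.0], "gamma": [0.01, 0.1]},
    pca_svm_grid={"retained_variance": [0.9], "C": [1.0, 10.0],
                  "gamma": [0.01, 0.1]},
    gbdt_grid={"learning_rate": [0.1], "n_estimators": [50], "num_leaves": [7]},
)

out = Path(tempfile.mkdtemp(prefix="mocapskill_run_"))
manifest = run_pipeline(sim_config, run_config, out, seed=5)
print(f"artifacts in {out}:")
for name, art in manifest["artifacts"].items():
    print(f"  {name:24s} sha256 {art['sha256'][:12]}...")

print("\n" + m.report(out))
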