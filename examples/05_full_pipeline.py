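"""Run the complete pipeline end to end on a synthetic cohort.

Generates a 107-patient cohort with the study's batch-level frequencies,
writes the CSV trio, and executes harmonize -> cluster -> survive via
the orchestration layer, leaving all artifacts (harmonized features,
phenotypes, model table, plots, provenance) in an output directory.
"""

import json
from pathlib import Path

import pandas as pd

import radiophen as rp
from radiophen.pipeline import PipelineConfig, run_pipeline

workdir = Path("scratch/example_pipeline")
cohort = rp.simulate_feature_cohort(rp.default_cohort_spec(seed=7))
paths = rp.write_cohort(cohort, workdir / "cohort")

config = PipelineConfig(
    features_csv=str(paths["features"]),
    clinical_csv=str(paths["clinical"]),
    batches_csv=str(paths["batches"]),
    out_dir=str(workdir / "out"),
    n_resamples=300,
    n_sim=500,
    iterations=50,
    seed=7,
)
out = run_pipeline(config)

report = json.load(open(out / "report.json"))
print(f"selected harmonization ordering: {report['selected_permutation']}")
print(f"robust features: {report['n_robust']} / 102 "
      f"({100 * report['robust_fraction']:.1f}%)")
cons = json.load(open(out / "consensus.json"))
print(f"phenotypes: k = {cons['selected_k']}")
from sklearn.metrics import adjusted_rand_score

phen = pd.read_csv(out / "phenotypes.csv", index_col=0).iloc[:, 0]
ari = adjusted_rand_score(cohort.cluster_truth, phen)
print(f"adjusted Rand index vs planted truth: {ari:.2f}")
print("\nmodel table (models.csv):")
print(pd.read_csv(out / "models.csv", index_col=0).round(3).to_string())
print(f"\nall artifacts in {out}/ (provenance.json records config + seeds)")
print("This cohort carries strong planted batch effects (gamma 1.5, "
      "delta 2) over 102 features, so phenotype recovery is partial "
      "after harmonization; the stability/significance selection may "
      "then resolve residual substructure (k > 2), unlike the clean "
      "low-dimensional cohort of example 03.")
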