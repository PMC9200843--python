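"""Discover radiomic phenotypes by consensus Ward clustering + SigClust.

Simulates a cohort with two planted phenotypes separated by 6 SD in the
standardized feature space, then runs the full discovery procedure:
z-score, consensus clustering over subsamples for k = 2..5, area under
the consensus CDF for stability, SigClust for the significance of every
binary split, and a final Ward cut at the selected k.
"""

from sklearn.metrics import adjusted_rand_score

import radiophen as rp
from radiophen.synthetic import ClusterDef, SurvivalDef, SyntheticSpec

spec = SyntheticSpec(
    n_samples=100, n_features=10, batch_defs=[],
    cluster_def=ClusterDef(2, (0.5, 0.5), separation=6.0),
    survival_def=SurvivalDef(cluster_log_hr=(0.0, 0.0)),
    seed=0,
)
cohort = rp.simulate_feature_cohort(spec)

labels, selection, consensus = rp.discover_phenotypes(
    cohort.features, ks=range(2, 6), n_resamples=500, n_sim=1000, seed=0
)

print("area under consensus CDF per k:",
      {k: round(v, 3) for k, v in consensus.areas.items()})
print("SigClust p-value per split:",
      {k: round(v, 4) for k, v in selection.sigclust_pvalues.items()})
print(f"selected k = {selection.k} "
      f"(significant structure: {selection.significant_structure})")
print("phenotype sizes:", labels.value_counts().to_dict())
ari = adjusted_rand_score(cohort.cluster_truth, labels)
print(f"adjusted Rand index vs planted truth: {ari:.3f}")
print("\nThe k=2 split is highly significant while splits of the pure "
      "within-phenotype Gaussians are not, so k=2 is selected and the "
      "partition matches the planted truth exactly (ARI 1.0).")
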