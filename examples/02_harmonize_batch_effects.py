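"""Remove planted acquisition batch effects with nested ComBat.

Simulates a 200-patient cohort whose features carry location (+1.5 SD)
and scale (x2) shifts for the minority level of two batch variables
(contrast enhancement and reconstruction kernel), then harmonizes
sequentially in every ordering and keeps the ordering leaving the fewest
features with batch-dependent distributions (k-sample Anderson-Darling
test at alpha = 0.05).
"""

import numpy as np

import radiophen as rp
from radiophen.synthetic import BatchDef, ClusterDef, SurvivalDef, SyntheticSpec

spec = SyntheticSpec(
    n_samples=200,
    n_features=50,
    batch_defs=[
        BatchDef("contrast", ("enhanced", "non_enhanced"), (0.75, 0.25),
                 (0.0, 1.5), (1.0, 2.0)),
        BatchDef("kernel", ("soft_tissue", "lung"), (0.85, 0.15),
                 (0.0, 1.5), (1.0, 2.0)),
    ],
    cluster_def=ClusterDef(1, (1.0,), 0.0),
    survival_def=SurvivalDef(cluster_log_hr=(0.0,)),
    seed=0,
)
cohort = rp.simulate_feature_cohort(spec)

for var in cohort.batches.columns:
    count, _ = rp.ad_significant_count(cohort.features, cohort.batches[var])
    print(f"before harmonization: {count}/50 features differ across {var}")

harmonized, report = rp.nested_combat(cohort.features, cohort.batches)
print(f"\norderings evaluated: {report.permutations}")
print(f"residual batch-dependent totals per ordering: {report.total_counts}")
print(f"selected ordering: {report.selected}")

robust, dropped = rp.drop_nonrobust(harmonized, cohort.batches)
print(f"non-robust features dropped: {len(dropped)} "
      f"({robust.shape[1]}/50 retained)")

# parameter recovery is cleanest on a single-variable fit of the
# original features (inside the nested sequence, later steps see data
# already rescaled by earlier ones)
_, est = rp.combat(cohort.features, cohort.batches["contrast"])
hi = est.levels.index("non_enhanced")
lo = est.levels.index("enhanced")
rec = (est.gamma_star[hi] - est.gamma_star[lo]) * est.sigma
rec /= cohort.feature_sd.values
print(f"\nplanted location shift: 1.50 SD; "
      f"recovered (mean over features): {np.mean(rec):.3f} SD")
print("Nearly every feature is flagged before harmonization and almost "
      "none after; the empirical-Bayes location estimates recover the "
      "planted shift.")
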