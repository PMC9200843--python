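"""Evaluate the prognostic model menu with cross-validated Cox models.

Simulates a 107-patient cohort with a prognostic phenotype (log HR 0.4
for phenotype 2) and clinical covariates, then evaluates each predictor
set by repeated five-fold cross-validated Harrell concordance and by the
log-rank test on Kaplan-Meier curves split at the median risk score.
"""

import pandas as pd

import radiophen as rp
from radiophen.survival import MODEL_MENU, build_design

cohort = rp.simulate_feature_cohort(rp.default_cohort_spec(seed=0))
clinical = cohort.clinical
survival = clinical[["pfs_days", "event"]]
# in a full run phenotypes come from harmonized-feature clustering; here
# the planted labels stand in to isolate the survival stage
phenotypes = cohort.cluster_truth.rename("phenotype")
volume = clinical["tumor_volume_cm3"]

rows = []
for i, model in enumerate(MODEL_MENU):
    design = build_design(model, clinical, phenotypes, volume)
    cv = rp.cv_concordance(survival, design, folds=5, iterations=50, seed=i)
    _, risk = rp.fit_cox(survival, design)
    km = rp.median_split_km(risk, survival)
    rows.append({"model": model, "mean_c": round(cv.mean, 3),
                 "ci": f"[{cv.ci_low:.2f}, {cv.ci_high:.2f}]",
                 "logrank_p": f"{km.pvalue:.3g}"})

print(pd.DataFrame(rows).set_index("model").to_string())
print("\nmean_c is the cross-validated concordance (0.5 = chance); the "
      "log-rank p tests the separation of the two median-split risk "
      "groups. The planted effects are modest at n = 107, so the "
      "covariate-bearing models separate risk groups clearly (small "
      "log-rank p) while their cross-validated concordance gains over "
      "chance are small and partly masked by fold noise.")
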