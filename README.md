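# radiophen

Radiomic phenotype discovery and prognostic modeling for segmented CT
tumor volumes, built for cohorts — such as advanced NSCLC patients on
first-line immunotherapy — whose scans were acquired with heterogeneous
protocols (contrast enhancement, reconstruction kernel, voxel spacing).

Radiomic features are sensitive to acquisition settings, so naive
clustering of a multi-protocol cohort discovers scanners, not biology.
`radiophen` implements the full chain needed to get from images to a
prognostic imaging biomarker:

1. **Feature extraction** — image/mask pairs are resampled to the
   cohort-minimum voxel spacing and a 102-feature descriptor set is
   extracted in 8 families (first-order intensity, discretized
   histogram, intensity–volume histogram, morphology, GLRLM, NGTDM,
   GLSZM, slice-wise rotation-invariant uniform LBP), following IBSI
   conventions.
2. **Nested ComBat harmonization** — ComBat models feature *g* of
   sample *j* in batch level *i* as
   `y_ijg = α_g + x_j'β_g + γ_ig + δ_ig ε_ijg`
   and removes the per-level location/scale terms (γ\*, δ\*) after
   empirical-Bayes shrinkage, while *protecting* biological covariates
   in the design. Several batch variables are handled by harmonizing
   sequentially in every ordering and keeping the ordering that leaves
   the fewest features with batch-dependent distributions (k-sample
   Anderson–Darling test, α = 0.05); features still affected afterwards
   are discarded as non-robust.
3. **Phenotype discovery** — Ward (squared-Euclidean) hierarchical
   clustering of z-scored robust features; stability by consensus
   clustering (co-clustering proportions over subsamples, area under the
   consensus CDF); significance by SigClust (cluster index
   CI = within-cluster SS / total SS against a Gaussian null fitted to
   the data).
4. **Survival association** — each predictor set of the model menu
   (tumor volume, phenotype, clinical covariates, and combinations) is
   scored by repeated five-fold cross-validated Cox
   proportional-hazards concordance (Harrell's c, 200 iterations,
   percentile 95% CI) and by the log-rank test on Kaplan–Meier curves
   split at the median risk score, with therapy-line stratification and
   phenotype–covariate association tests (chi-square, random-forest
   PD-L1 prediction AUC).

Because cohorts like this are rarely shareable, the package ships a
first-class synthetic-cohort generator (`radiophen.synthetic`) that
plants every ingredient the analysis assumes — location/scale batch
shifts, cluster structure of controlled standardized separation,
proportional-hazards PFS with censoring, and small textured ellipsoid
"tumor" volumes — so the entire pipeline is testable with known ground
truth.

## Worked example

```python
import radiophen as rp

# a synthetic 107-patient cohort with the study-like batch frequencies
cohort = rp.simulate_feature_cohort(rp.default_cohort_spec(seed=0))

count, _ = rp.ad_significant_count(cohort.features, cohort.batches["contrast"])
print(f"{count}/102 features differ across contrast levels before harmonization")

harmonized, report = rp.nested_combat(cohort.features, cohort.batches)
print("selected ordering:", report.selected)
print("residual batch-dependent features:", report.selected_total)
```

prints

```
91/102 features differ across contrast levels before harmonization
selected ordering: ('kernel', 'contrast')
residual batch-dependent features: 3
```

91 of 102 features carry the planted contrast-level batch effect
(+1.5 SD location, ×2 scale on the minority level); after nested ComBat
— here the kernel-first ordering wins — only 3 of the 204
feature-by-batch-variable tests remain significant at α = 0.05, close
to the false-positive rate expected by chance.

The `examples/` directory contains one short script per capability
(feature extraction, harmonization, phenotype discovery, survival
models, full pipeline); each prints the quantities it computes and a
line on how to read them. A thin CLI mirrors the stages:

```bash
radiophen simulate --n-samples 107 --seed 0 --out cohort/
radiophen harmonize --features cohort/features.csv --batches cohort/batches.csv \
    --clinical cohort/clinical.csv --out harm/
radiophen cluster --features harm/harmonized_features.csv --out clust/
radiophen run-all --config pipeline.json
```

## Layout

```
src/radiophen/
  manifest.py        102-feature manifest (8 families, versioned)
  features/          resampling, discretization, all feature families
  harmonization.py   ComBat, nested ComBat, AD screening, robustness filter
  phenotyping.py     Ward, consensus clustering, SigClust, k selection
  survival.py        Cox CV concordance, KM/log-rank, associations
  synthetic.py       cohort / survival / tumor-volume generators
  pipeline.py, io.py, cli.py
docs/methods.md      model assumptions, parameter choices, limitations
```
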