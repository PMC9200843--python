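"""Extract the 102-feature radiomic descriptor set from simulated tumors.

Builds three small textured ellipsoid image/mask pairs with different
voxel spacings, resamples them to the cohort minimum spacing (the same
convention used for heterogeneous CT cohorts), and extracts all eight
feature families from each.
"""

import radiophen as rp
from radiophen import manifest

pairs = []
for sid, spacing, texture, seed in [
    ("tumor_a", (0.7, 0.7, 1.25), "smooth", 1),
    ("tumor_b", (0.54, 0.54, 0.8), "coarse", 2),
    ("tumor_c", (0.9, 0.9, 1.5), "smooth", 3),
]:
    img, msk = rp.simulate_tumor_volume(
        radii=(7, 6, 5), grid_shape=(24, 24, 24),
        spacing=spacing, texture=texture, seed=seed,
    )
    pairs.append((sid, img, msk))

target = rp.compute_min_spacing([img.spacing for _, img, _ in pairs])
print(f"cohort minimum spacing: {target} mm")

config = rp.ExtractionConfig(target_spacing=target, n_levels=32)
table = rp.extract_cohort(pairs, config)
print(f"\nfeature table: {table.shape[0]} samples x {table.shape[1]} features")
counts = {}
for name in table.columns:
    fam = manifest.FEATURE_FAMILY[name]
    counts[fam] = counts.get(fam, 0) + 1
print("features per family:", counts)

print("\nselected columns:")
cols = ["int_mean", "morph_volume_cm3", "morph_sphericity",
        "glrlm_sre", "ngtdm_coarseness"]
print(table[cols].round(3).to_string())
print("\nThe coarse-textured tumor_b shows a lower in-mask mean intensity "
      "and different run-length/coarseness values than the smooth tumors; "
      "volumes differ because the same voxel-space ellipsoid occupies "
      "different physical extents at each native spacing.")
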