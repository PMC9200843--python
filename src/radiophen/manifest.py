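"""Radiomic feature manifest.

The descriptor set comprises 102 named features in 8 families (intensity
first-order statistics, discretized-histogram statistics, intensity-volume
histogram "volumetric" features, morphology, GLRLM, GLSZM, NGTDM and local
binary patterns).  Formulas follow the Image Biomarker Standardisation
Initiative (IBSI) conventions; the manifest is versioned so that feature
tables produced by different releases are comparable.
"""

from __future__ import annotations

MANIFEST_VERSION = "1.0"

FAMILIES = (
    "intensity",
    "histogram",
    "volumetric",
    "morphologic",
    "GLRLM",
    "NGTDM",
    "GLSZM",
    "LBP",
)

_INTENSITY = [
    "int_mean", "int_variance", "int_std", "int_skewness", "int_kurtosis",
    "int_median", "int_min", "int_max", "int_range", "int_energy",
    "int_rms", "int_mad", "int_p10", "int_p90",
]

_HISTOGRAM = [
    "hist_entropy", "hist_uniformity", "hist_mean", "hist_variance",
    "hist_skewness", "hist_kurtosis", "hist_median", "hist_mode",
    "hist_min", "hist_max", "hist_range", "hist_iqr", "hist_p10", "hist_p90",
]

_VOLUMETRIC = (
    [f"ivh_v{p}" for p in (10, 20, 30, 40, 50, 60, 70, 80, 90)]
    + [f"ivh_i{p}" for p in (10, 25, 50, 75, 90)]
    + ["ivh_v10_minus_v90", "ivh_i10_minus_i90"]
)

_MORPHOLOGIC = [
    "morph_volume_cm3", "morph_voxel_count", "morph_surface_area_mm2",
    "morph_surface_to_volume_ratio", "morph_sphericity",
    "morph_compactness1", "morph_compactness2",
    "morph_spherical_disproportion", "morph_max_3d_diameter_mm",
    "morph_elongation", "morph_flatness",
]

_GLRLM = [
    "glrlm_sre", "glrlm_lre", "glrlm_gln", "glrlm_glnn", "glrlm_rln",
    "glrlm_rlnn", "glrlm_rp", "glrlm_lgre", "glrlm_hgre", "glrlm_srlge",
    "glrlm_srhge", "glrlm_lrlge", "glrlm_lrhge", "glrlm_glv", "glrlm_rlv",
    "glrlm_re",
]

_NGTDM = [
    "ngtdm_coarseness", "ngtdm_contrast", "ngtdm_busyness",
    "ngtdm_complexity", "ngtdm_strength",
]

_GLSZM = [
    "glszm_sae", "glszm_lae", "glszm_gln", "glszm_glnn", "glszm_szn",
    "glszm_sznn", "glszm_zp", "glszm_lgze", "glszm_hgze", "glszm_salge",
    "glszm_sahge", "glszm_lalge", "glszm_lahge", "glszm_glv", "glszm_zv",
    "glszm_ze",
]

_LBP = [f"lbp_bin_{i:02d}" for i in range(10)]

#: mapping family -> ordered feature names
FAMILY_FEATURES: dict[str, list[str]] = {
    "intensity": _INTENSITY,
    "histogram": _HISTOGRAM,
    "volumetric": _VOLUMETRIC,
    "morphologic": _MORPHOLOGIC,
    "GLRLM": _GLRLM,
    "NGTDM": _NGTDM,
    "GLSZM": _GLSZM,
    "LBP": _LBP,
}

#: ordered feature names across all families
FEATURE_NAMES: list[str] = [n for f in FAMILIES for n in FAMILY_FEATURES[f]]

#: mapping feature name -> family
FEATURE_FAMILY: dict[str, str] = {
    n: f for f in FAMILIES for n in FAMILY_FEATURES[f]
}

N_FEATURES = len(FEATURE_NAMES)

assert N_FEATURES == 102, "manifest must define exactly 102 features"
assert len(set(FEATURE_NAMES)) == N_FEATURES, "feature names must be unique"
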