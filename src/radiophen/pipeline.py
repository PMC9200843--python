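"""End-to-end orchestration: harmonize -> phenotype -> survival models.

One global seed fans out to per-stage seeds by fixed offsets so that each
stage is individually reproducible from a single knob.  Every run writes
a provenance record (config echo, seeds, per-stage counts) next to its
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .harmonization import (
    DEFAULT_PROTECTED,
    ad_significant_count,
    drop_nonrobust,
    encode_covariates,
    nested_combat,
)
from .phenotyping import discover_phenotypes
from .survival import (
    MODEL_MENU,
    build_design,
    chi_square_assoc,
    cv_concordance,
    fit_cox,
    median_split_km,
    robust_risk_scores,
    phenotype_predicts_pdl1,
    stratified_by_therapy,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

# fixed per-stage seed offsets
_SEED_HARMONIZE = 101
_SEED_CLUSTER = 202
_SEED_SURVIVAL = 303


@dataclass
class PipelineConfig:
    features_csv: str = "features.csv"
    clinical_csv: str = "clinical.csv"
    batches_csv: str = "batches.csv"
    out_dir: str = "out"
    # harmonization
    batch_variables: list[str] | None = None       # default: all batch columns
    protected: list[str] = field(default_factory=lambda: list(DEFAULT_PROTECTED))
    alpha: float = 0.05
    harmonize: bool = True                          # False = passthrough comparison
    # clustering
    k_min: int = 2
    k_max: int = 6
    n_resamples: int = 1000
    subsample_fraction: float = 0.8
    n_sim: int = 10_000
    # survival
    models: list[str] = field(default_factory=lambda: list(MODEL_MENU))
    folds: int = 5
    iterations: int = 200
    therapy_column: str = "therapy"
    volume_column: str = "tumor_volume_cm3"
    pdl1_column: str = "pdl1_pct"
    make_plots: bool = True
    seed: int = 0

    def validate(self) -> None:
        unknown = [m for m in self.models if m not in MODEL_MENU]
        if unknown:
            raise ValueError(
                f"unknown model name(s) {unknown}; valid: {list(MODEL_MENU)}"
            )
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _km_plot(km, path: Path, title: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, curve in km.curves.items():
        ax.step(curve.index, curve.iloc[:, 0], where="post", label=name)
    ax.set_xlabel("days")
    ax.set_ylabel("PFS probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    ax.set_title(f"{title} (log-rank p = {km.pvalue:.3g})")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _cdf_plot(cons, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for k in cons.ks:
        ax.plot(cons.cdf_grid, cons.cdfs[k], label=f"k={k}")
    ax.set_xlabel("consensus value")
    ax.set_ylabel("CDF")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute harmonize -> cluster -> survive -> report; returns the
    output directory.  Deterministic for a fixed config and seed."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    provenance: dict = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "stages": {},
    }

    from .io import read_feature_table, read_table

    features = read_feature_table(config.features_csv)
    clinical = read_table(config.clinical_csv)
    batches = read_table(config.batches_csv)
    if config.batch_variables:
        batches = batches[config.batch_variables]
    common = features.index.intersection(clinical.index).intersection(batches.index)
    features, clinical, batches = (
        features.loc[common], clinical.loc[common], batches.loc[common]
    )
    provenance["stages"]["load"] = {
        "n_samples": int(len(common)),
        "n_features": int(features.shape[1]),
        "batch_variables": list(batches.columns),
    }

    # --- harmonization -------------------------------------------------
    stage_t = time.time()
    protected_cols = [c for c in config.protected if c in clinical.columns]
    covariates = (
        encode_covariates(clinical[protected_cols]) if protected_cols else None
    )
    pre_counts = {
        var: ad_significant_count(
            features, batches[var], config.alpha, seed=config.seed + _SEED_HARMONIZE
        )[0]
        for var in batches.columns
    }
    if config.harmonize:
        harmonized, report = nested_combat(
            features, batches, covariates, config.alpha,
            seed=config.seed + _SEED_HARMONIZE,
        )
        robust, dropped = drop_nonrobust(
            harmonized, batches, config.alpha, seed=config.seed + _SEED_HARMONIZE
        )
        report_json = {
            "permutations": [list(p) for p in report.permutations],
            "counts_per_variable": report.counts_per_variable,
            "total_counts": report.total_counts,
            "selected_permutation": list(report.selected),
            "alpha": report.alpha,
            "pre_harmonization_counts": pre_counts,
            "dropped_nonrobust": dropped,
            "n_robust": int(robust.shape[1]),
            "robust_fraction": robust.shape[1] / features.shape[1],
        }
    else:
        harmonized, robust, dropped = features, features, []
        report_json = {
            "harmonization": "disabled (passthrough comparison)",
            "pre_harmonization_counts": pre_counts,
        }
    harmonized.to_csv(out / "harmonized_features.csv")
    with open(out / "report.json", "w") as fh:
        json.dump(report_json, fh, indent=2)
    provenance["stages"]["harmonize"] = {
        "seconds": round(time.time() - stage_t, 2),
        "n_robust_features": int(robust.shape[1]),
        "n_dropped": len(dropped),
    }
    logger.info("harmonization done: %d/%d robust features",
                robust.shape[1], features.shape[1])

    # --- phenotyping ----------------------------------------------------
    stage_t = time.time()
    phenotypes, selection, cons = discover_phenotypes(
        robust,
        ks=range(config.k_min, config.k_max + 1),
        n_resamples=config.n_resamples,
        subsample_fraction=config.subsample_fraction,
        n_sim=config.n_sim,
        alpha=config.alpha,
        seed=config.seed + _SEED_CLUSTER,
    )
    phenotypes.to_frame().to_csv(out / "phenotypes.csv")
    with open(out / "consensus.json", "w") as fh:
        json.dump(
            {
                "areas": {str(k): v for k, v in cons.areas.items()},
                "delta_areas": {str(k): v for k, v in selection.delta_areas.items()},
                "sigclust_pvalues": {
                    str(k): v for k, v in selection.sigclust_pvalues.items()
                },
                "selected_k": selection.k,
                "significant_structure": selection.significant_structure,
                "notes": selection.notes,
            },
            fh,
            indent=2,
        )
    if config.make_plots:
        _cdf_plot(cons, out / "consensus_cdf.png")
    provenance["stages"]["cluster"] = {
        "seconds": round(time.time() - stage_t, 2),
        "k": selection.k,
        "cluster_sizes": phenotypes.value_counts().sort_index().tolist(),
    }

    # --- survival models ------------------------------------------------
    stage_t = time.time()
    survival = clinical[["pfs_days", "event"]]
    volume = (
        clinical[config.volume_column]
        if config.volume_column in clinical.columns
        else None
    )
    rows = []
    stats_json: dict = {}
    for i, model in enumerate(config.models):
        design = build_design(model, clinical, phenotypes, volume)
        cv = cv_concordance(
            survival, design, config.folds, config.iterations,
            seed=config.seed + _SEED_SURVIVAL + i,
        )
        lp = robust_risk_scores(survival, design)
        km = median_split_km(lp, survival)
        rows.append(
            {
                "model": model,
                "mean_c": cv.mean,
                "ci_low": cv.ci_low,
                "ci_high": cv.ci_high,
                "logrank_p": km.pvalue,
                "n_low": km.group_sizes["low_risk"],
                "n_high": km.group_sizes["high_risk"],
            }
        )
        if config.make_plots:
            _km_plot(km, out / f"km_{model.replace('+', '_')}.png", model)
    models_df = pd.DataFrame(rows).set_index("model")
    models_df.to_csv(out / "models.csv")

    # therapy-line stratification of the full (phenotype+clinical) model
    if (
        config.therapy_column in clinical.columns
        and "phenotype+clinical" in config.models
    ):
        design = build_design("phenotype+clinical", clinical, phenotypes, volume)
        strata = stratified_by_therapy(
            survival, design, clinical[config.therapy_column],
            config.folds, config.iterations, seed=config.seed + _SEED_SURVIVAL,
        )
        stats_json["therapy_strata"] = {
            level: {
                "mean_c": cv.mean,
                "ci": [cv.ci_low, cv.ci_high],
                "logrank_p": km.pvalue,
            }
            for level, (cv, km) in strata.items()
        }

    # phenotype-covariate association
    assoc = {}
    from .survival import _categorize

    cat_clin = _categorize(clinical)
    for var in ("pdl1_cat", "bmi_cat", "smoking", "ecog"):
        if var in cat_clin.columns:
            chi2, p = chi_square_assoc(phenotypes, cat_clin[var].astype(str))
            assoc[var] = {"chi2": chi2, "p": p}
    stats_json["phenotype_associations"] = assoc
    if config.pdl1_column in clinical.columns:
        try:
            cv_auc, holdout_auc = phenotype_predicts_pdl1(
                phenotypes, clinical[config.pdl1_column],
                seed=config.seed + _SEED_SURVIVAL,
            )
            stats_json["pdl1_prediction"] = {
                "cv_auc": cv_auc, "holdout_auc": holdout_auc
            }
        except ValueError as exc:
            stats_json["pdl1_prediction"] = {"error": str(exc)}
    with open(out / "stats.json", "w") as fh:
        json.dump(stats_json, fh, indent=2)
    provenance["stages"]["survive"] = {
        "seconds": round(time.time() - stage_t, 2),
        "models": list(models_df.index),
    }

    provenance["total_seconds"] = round(time.time() - t0, 2)
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    return out
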