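"""Synthetic cohort generation.

The downstream analysis assumes a specific statistical structure: feature
tables following the location/scale batch-effect model that ComBat
corrects, planted cluster (phenotype) structure of configurable
separation, proportional-hazards progression-free survival linked to
cluster and covariates, and small textured "tumor" image/mask pairs for
exercising feature extraction.  This module plants all of it with known
parameters so every stage of the pipeline is testable without patient
data.

Generative model for feature g of sample j (batch level i, cluster c):

    y_gj = mu_g + m_cg * sigma_g + sum_v beta_v x_vj * sigma_g
           + gamma_ig * sigma_g + delta_ig * sigma_g * eps_gj

with eps standard normal, per-feature scales sigma_g log-uniform in
[0.5, 2] (radiomic features have heterogeneous dynamic range), gamma/delta
the planted per-batch-level location shift (in SD units) and scale factor,
and cluster mean vectors m_c placed on mutually orthogonal directions so
that every pair of cluster centroids is ``separation`` SDs apart in
standardized Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .features.preprocess import ImageVolume, SegmentationMask

__all__ = [
    "BatchDef",
    "ClusterDef",
    "CovariateDef",
    "SurvivalDef",
    "SyntheticSpec",
    "SyntheticCohort",
    "TextureClass",
    "TEXTURE_CLASSES",
    "default_cohort_spec",
    "simulate_feature_cohort",
    "simulate_survival",
    "simulate_tumor_volume",
    "write_cohort",
]


@dataclass
class BatchDef:
    """One batch variable: named levels with sampling proportions and
    planted per-level location shift gamma (in units of the feature SD)
    and scale factor delta (> 0)."""

    name: str
    levels: tuple[str, ...]
    proportions: tuple[float, ...]
    gamma: tuple[float, ...]
    delta: tuple[float, ...]

    def validate(self) -> None:
        k = len(self.levels)
        if not (len(self.proportions) == len(self.gamma) == len(self.delta) == k):
            raise ValueError(f"batch '{self.name}': per-level lists disagree in length")
        if abs(sum(self.proportions) - 1.0) > 1e-8:
            raise ValueError(f"batch '{self.name}': proportions must sum to 1")
        if any(d <= 0 for d in self.delta):
            raise ValueError(f"batch '{self.name}': scale factors must be > 0")


@dataclass
class ClusterDef:
    """Planted phenotype structure: k clusters, mixing proportions, and the
    pairwise centroid separation in standardized Euclidean SD units.

    Separation is defined on the scale clustering operates on: after
    per-feature z-scoring (whose SD includes the between-cluster
    variance), the smallest pairwise distance between cluster centroids
    equals ``separation``.  Because standardization caps the achievable
    standardized distance at a finite asymptote for a given feature
    count, an unattainable separation raises an error suggesting more
    features.
    """

    k: int = 2
    proportions: tuple[float, ...] = (0.5, 0.5)
    separation: float = 6.0

    def validate(self) -> None:
        if self.k < 1 or len(self.proportions) != self.k:
            raise ValueError("cluster proportions must have length k")
        if abs(sum(self.proportions) - 1.0) > 1e-8:
            raise ValueError("cluster proportions must sum to 1")


@dataclass
class CovariateDef:
    """A clinical covariate, its sampling law, its planted effect on
    features (slope per SD, on the standardized covariate) and its planted
    log hazard ratio (per SD for continuous, per level step for
    categorical)."""

    name: str
    kind: str = "continuous"                      # 'continuous' | 'categorical'
    mean: float = 0.0
    sd: float = 1.0
    levels: tuple[str, ...] = ()
    proportions: tuple[float, ...] = ()
    feature_effect: float = 0.0
    log_hr: float = 0.0


@dataclass
class SurvivalDef:
    """Exponential PFS model: hazard = baseline_rate * exp(linear
    predictor); independent uniform censoring on [0, censoring_window]
    (None disables censoring)."""

    baseline_rate: float = np.log(2) / 270.0      # median 270 days at lp = 0
    cluster_log_hr: tuple[float, ...] = (0.0, 0.4)
    censoring_window: float | None = 1460.0

    def validate(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline hazard rate must be > 0")
        if self.censoring_window is not None and self.censoring_window <= 0:
            raise ValueError("censoring window must be > 0 (or None)")


@dataclass
class SyntheticSpec:
    n_samples: int = 107
    n_features: int = 102
    batch_defs: list[BatchDef] = field(default_factory=list)
    cluster_def: ClusterDef = field(default_factory=ClusterDef)
    covariate_defs: list[CovariateDef] = field(default_factory=list)
    survival_def: SurvivalDef = field(default_factory=SurvivalDef)
    #: probability of forcing a sample's first-batch level to follow its
    #: cluster (stress knob for cluster-batch confounding); 0 = independent
    cluster_batch_confounding: float = 0.0
    sigma_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        for b in self.batch_defs:
            b.validate()
        self.cluster_def.validate()
        self.survival_def.validate()
        if len(self.survival_def.cluster_log_hr) < self.cluster_def.k:
            raise ValueError("cluster_log_hr must cover every cluster")


@dataclass
class SyntheticCohort:
    """All tables share the same sample ordering (index = sample id)."""

    features: pd.DataFrame
    batches: pd.DataFrame
    covariates: pd.DataFrame
    cluster_truth: pd.Series
    survival: pd.DataFrame           # columns: pfs_days, event
    feature_mean: pd.Series          # planted mu_g
    feature_sd: pd.Series            # planted sigma_g
    linear_predictor: pd.Series

    @property
    def clinical(self) -> pd.DataFrame:
        """Covariates joined with the survival outcome (pipeline dialect)."""
        return self.covariates.join(self.survival)


def default_cohort_spec(
    n_samples: int = 107,
    n_features: int = 102,
    gamma: float = 1.5,
    delta: float = 2.0,
    separation: float = 6.0,
    seed: int = 0,
) -> SyntheticSpec:
    """Cohort emulating the target study: two batch variables with the
    observed level frequencies (contrast enhancement 80/27, reconstruction
    kernel 90/17 of 107), realistic clinical covariate mixes, two planted
    phenotypes, and exponential PFS with median 270 days."""
    batch_defs = [
        BatchDef(
            "contrast", ("enhanced", "non_enhanced"),
            (80 / 107, 27 / 107), (0.0, gamma), (1.0, delta),
        ),
        BatchDef(
            "kernel", ("soft_tissue", "lung"),
            (90 / 107, 17 / 107), (0.0, gamma), (1.0, delta),
        ),
    ]
    covariate_defs = [
        CovariateDef("age", "continuous", mean=67.0, sd=10.0),
        CovariateDef("sex", "categorical", levels=("male", "female"),
                     proportions=(0.486, 0.514)),
        CovariateDef("race", "categorical", levels=("white", "black", "other"),
                     proportions=(0.682, 0.271, 0.047)),
        CovariateDef("pdl1_pct", "continuous", mean=34.0, sd=30.0, log_hr=-0.2),
        CovariateDef("ecog", "categorical", levels=("0", "1", "2", "3"),
                     proportions=(0.327, 0.486, 0.140, 0.047), log_hr=0.25),
        CovariateDef("bmi", "continuous", mean=26.7, sd=4.5),
        CovariateDef("smoking", "categorical",
                     levels=("former", "current", "never"),
                     proportions=(0.505, 0.364, 0.131), log_hr=0.1),
        CovariateDef("therapy", "categorical",
                     levels=("combination", "monotherapy"),
                     proportions=(0.711, 0.289), log_hr=0.3),
    ]
    return SyntheticSpec(
        n_samples=n_samples,
        n_features=n_features,
        batch_defs=batch_defs,
        cluster_def=ClusterDef(2, (0.5, 0.5), separation),
        covariate_defs=covariate_defs,
        survival_def=SurvivalDef(),
        seed=seed,
    )


def _orthogonal_directions(k: int, d: int, rng: np.random.Generator) -> np.ndarray:
    """k mutually orthogonal unit directions in R^d (k <= d)."""
    if k > d:
        raise ValueError("more clusters than features")
    q, _ = np.linalg.qr(rng.standard_normal((d, k)))
    return q.T


def _standardized_separation(centers: np.ndarray, pi: np.ndarray) -> float:
    """Smallest pairwise centroid distance after population z-scoring
    (per-feature variance = within-cluster 1 + between-cluster)."""
    mbar = pi @ centers
    between = pi @ (centers - mbar) ** 2
    v = 1.0 + between
    k = centers.shape[0]
    dists = [
        np.sqrt((((centers[a] - centers[b]) ** 2) / v).sum())
        for a in range(k)
        for b in range(a + 1, k)
    ]
    return float(min(dists))


def _separation_scale(
    base: np.ndarray, pi: np.ndarray, target: float
) -> float:
    """Scale factor t such that centers t*base reach the requested
    standardized separation (bisection; saturates at a finite asymptote)."""
    hi = 1.0
    while _standardized_separation(base * hi, pi) < target:
        hi *= 2.0
        if hi > 1e6:
            reachable = _standardized_separation(base * 1e6, pi)
            raise ValueError(
                f"standardized separation {target} not achievable with "
                f"{base.shape[1]} features (asymptote ~{reachable:.2f}); "
                "increase n_features or lower the separation"
            )
    lo = 0.0
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if _standardized_separation(base * mid, pi) < target:
            lo = mid
        else:
            hi = mid
    return hi


def simulate_feature_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Draw a full synthetic cohort (features, batches, covariates,
    planted clusters and survival).  Bit-identical for a fixed seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.n_features
    ids = [f"S{i + 1:04d}" for i in range(n)]

    lo, hi = spec.sigma_range
    sigma = np.exp(rng.uniform(np.log(lo), np.log(hi), size=d))
    mu = rng.normal(0.0, 5.0, size=d)

    # planted clusters
    cdef = spec.cluster_def
    cluster = rng.choice(cdef.k, size=n, p=cdef.proportions)
    if cdef.k > 1 and cdef.separation > 0:
        base = _orthogonal_directions(cdef.k, d, rng) / np.sqrt(2.0)
        centers = base * _separation_scale(
            base, np.asarray(cdef.proportions), cdef.separation
        )
    else:
        centers = np.zeros((cdef.k, d))

    # batch assignments (optionally confounded with cluster on the first
    # batch variable)
    batch_levels: dict[str, np.ndarray] = {}
    for bi, bdef in enumerate(spec.batch_defs):
        lev = rng.choice(len(bdef.levels), size=n, p=bdef.proportions)
        if bi == 0 and spec.cluster_batch_confounding > 0:
            force = rng.random(n) < spec.cluster_batch_confounding
            lev[force] = cluster[force] % len(bdef.levels)
        counts = np.bincount(lev, minlength=len(bdef.levels))
        for li, c in enumerate(counts):
            if c < 2:
                raise ValueError(
                    f"batch '{bdef.name}' level '{bdef.levels[li]}' received "
                    f"{c} sample(s); need >= 2"
                )
        batch_levels[bdef.name] = lev

    # covariates
    cov_cols: dict[str, np.ndarray] = {}
    cov_numeric: dict[str, np.ndarray] = {}   # standardized, for effects
    for cv in spec.covariate_defs:
        if cv.kind == "continuous":
            x = rng.normal(cv.mean, cv.sd, size=n)
            cov_cols[cv.name] = x
            cov_numeric[cv.name] = (x - cv.mean) / cv.sd
        elif cv.kind == "categorical":
            li = rng.choice(len(cv.levels), size=n, p=cv.proportions)
            cov_cols[cv.name] = np.asarray(cv.levels)[li]
            cov_numeric[cv.name] = li.astype(float)
        else:
            raise ValueError(f"unknown covariate kind '{cv.kind}'")

    # assemble features
    y = mu[None, :] + centers[cluster] * sigma[None, :]
    for cv in spec.covariate_defs:
        if cv.feature_effect != 0.0:
            y = y + cv.feature_effect * cov_numeric[cv.name][:, None] * sigma[None, :]
    gamma_tot = np.zeros(n)
    delta_tot = np.ones(n)
    for bdef in spec.batch_defs:
        lev = batch_levels[bdef.name]
        gamma_tot = gamma_tot + np.asarray(bdef.gamma)[lev]
        delta_tot = delta_tot * np.asarray(bdef.delta)[lev]
    eps = rng.standard_normal((n, d))
    y = y + (gamma_tot[:, None] + delta_tot[:, None] * eps) * sigma[None, :]

    # survival from the planted linear predictor
    lp = np.asarray(spec.survival_def.cluster_log_hr)[cluster].astype(float)
    for cv in spec.covariate_defs:
        if cv.log_hr != 0.0:
            lp = lp + cv.log_hr * cov_numeric[cv.name]
    surv = simulate_survival(
        lp, spec.survival_def, seed=int(rng.integers(0, 2**31 - 1))
    )
    surv.index = pd.Index(ids, name="sample_id")

    # tumor volume covariate linked to cluster (larger second phenotype)
    log_vol = rng.normal(3.0 + 1.0 * (cluster == cdef.k - 1), 0.6)
    cov_cols["tumor_volume_cm3"] = np.exp(log_vol)

    idx = pd.Index(ids, name="sample_id")
    features = pd.DataFrame(
        y, index=idx, columns=[f"feature_{g + 1:04d}" for g in range(d)]
    )
    batches = pd.DataFrame(
        {b.name: np.asarray(b.levels)[batch_levels[b.name]] for b in spec.batch_defs},
        index=idx,
    )
    covariates = pd.DataFrame(cov_cols, index=idx)
    return SyntheticCohort(
        features=features,
        batches=batches,
        covariates=covariates,
        cluster_truth=pd.Series(cluster + 1, index=idx, name="cluster"),
        survival=surv,
        feature_mean=pd.Series(mu, index=features.columns),
        feature_sd=pd.Series(sigma, index=features.columns),
        linear_predictor=pd.Series(lp, index=idx, name="linear_predictor"),
    )


def simulate_survival(
    linear_predictor: np.ndarray | pd.Series,
    survival_def: SurvivalDef,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential event times with hazard ``rate * exp(lp)``, censored at
    an independent uniform time (event = 0 iff censoring comes first)."""
    survival_def.validate()
    lp = np.asarray(linear_predictor, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictor contains non-finite values")
    rng = np.random.default_rng(seed)
    rate = survival_def.baseline_rate * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    if survival_def.censoring_window is None:
        time, event = t_event, np.ones(len(lp), dtype=int)
    else:
        t_cens = rng.uniform(0.0, survival_def.censoring_window, size=len(lp))
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    time = np.maximum(time, 1e-6)
    out = pd.DataFrame({"pfs_days": time, "event": event})
    if isinstance(linear_predictor, pd.Series):
        out.index = linear_predictor.index
    return out


@dataclass
class TextureClass:
    """In-mask intensity model: mean HU plus Gaussian-correlated noise of
    given amplitude and correlation length (voxels)."""

    name: str
    mean: float
    amplitude: float = 0.0
    correlation_length: float = 1.0


TEXTURE_CLASSES: dict[str, TextureClass] = {
    "constant": TextureClass("constant", mean=50.0, amplitude=0.0),
    "smooth": TextureClass("smooth", mean=40.0, amplitude=25.0,
                           correlation_length=2.5),
    "coarse": TextureClass("coarse", mean=-20.0, amplitude=60.0,
                           correlation_length=0.8),
}


def simulate_tumor_volume(
    radii: tuple[float, float, float] = (8.0, 6.0, 5.0),
    texture: str | TextureClass = "smooth",
    grid_shape: tuple[int, int, int] = (32, 32, 32),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
) -> tuple[ImageVolume, SegmentationMask]:
    """A discretized ellipsoid "tumor" with class-specific texture inside
    the mask and lung-like background noise outside."""
    if isinstance(texture, str):
        try:
            texture = TEXTURE_CLASSES[texture]
        except KeyError:
            raise ValueError(
                f"unknown texture class '{texture}'; "
                f"available: {sorted(TEXTURE_CLASSES)}"
            ) from None
    radii = tuple(float(r) for r in radii)
    if any(r < 2 for r in radii):
        raise ValueError("ellipsoid radii must be >= 2 voxels on each axis")
    if any(2 * r + 1 > s for r, s in zip(radii, grid_shape)):
        raise ValueError(f"radii {radii} exceed grid {grid_shape}")

    rng = np.random.default_rng(seed)
    center = [(s - 1) / 2.0 for s in grid_shape]
    xx, yy, zz = np.meshgrid(
        *[np.arange(s, dtype=float) for s in grid_shape], indexing="ij"
    )
    ell = (
        ((xx - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((zz - center[2]) / radii[2]) ** 2
    )
    mask = (ell <= 1.0).astype(np.uint8)

    background = -300.0 + 30.0 * rng.standard_normal(grid_shape)
    if texture.amplitude > 0:
        noise = rng.standard_normal(grid_shape)
        noise = ndimage.gaussian_filter(noise, sigma=texture.correlation_length)
        sd = noise.std()
        if sd > 0:
            noise = noise / sd
        inside = texture.mean + texture.amplitude * noise
    else:
        inside = np.full(grid_shape, texture.mean)
    intensities = np.where(mask > 0, inside, background)
    return (
        ImageVolume(intensities, spacing),
        SegmentationMask(mask, spacing),
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort as the pipeline's CSV trio plus the planted truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": out / "features.csv",
        "clinical": out / "clinical.csv",
        "batches": out / "batches.csv",
        "truth": out / "truth.csv",
    }
    cohort.features.to_csv(paths["features"])
    cohort.clinical.to_csv(paths["clinical"])
    cohort.batches.to_csv(paths["batches"])
    pd.DataFrame(
        {"cluster": cohort.cluster_truth, "linear_predictor": cohort.linear_predictor}
    ).to_csv(paths["truth"])
    return paths
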