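"""Radiomic phenotype discovery.

Intrinsic phenotypes are found by agglomerative Ward clustering (squared
Euclidean merge cost) on column-z-scored features.  Cluster number
selection combines two checks: stability, via consensus clustering
(subsample, recluster, accumulate pairwise co-clustering proportions, and
measure the area under the CDF of consensus values), and significance,
via the SigClust test comparing the observed 2-cluster index

    CI = within-cluster SS / total SS

to its distribution under a Gaussian null fitted to the data (covariance
eigenvalues floored at a background-noise variance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.covariance import LedoitWolf

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeAssignment",
    "ConsensusResult",
    "SigClustResult",
    "KSelection",
    "zscore",
    "ward_cluster",
    "consensus_cluster",
    "sigclust",
    "select_k",
    "discover_phenotypes",
]


@dataclass
class PhenotypeAssignment:
    labels: np.ndarray          # 1..k per sample
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if present.min() < 1 or present.max() > self.k:
            raise ValueError("labels out of range 1..k")
        if len(present) != self.k:
            raise ValueError("every cluster must be non-empty")


@dataclass
class ConsensusResult:
    """Per-k consensus matrices with their CDFs and areas."""

    ks: list[int]
    consensus: dict[int, np.ndarray]
    cdf_grid: np.ndarray
    cdfs: dict[int, np.ndarray]
    areas: dict[int, float]
    n_resamples: int
    subsample_fraction: float
    n_never_cosampled: int = 0


@dataclass
class SigClustResult:
    ci: float
    null_ci: np.ndarray
    pvalue: float
    n_sim: int


@dataclass
class KSelection:
    k: int
    delta_areas: dict[int, float]
    sigclust_pvalues: dict[int, float]
    significant_structure: bool
    threshold: float
    notes: list[str] = field(default_factory=list)


def zscore(features: pd.DataFrame | np.ndarray) -> np.ndarray:
    x = np.asarray(features, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def ward_cluster(x: np.ndarray, k: int) -> PhenotypeAssignment:
    """Cut the Ward (squared-Euclidean merge cost) dendrogram at k
    clusters.  Features are expected z-scored upstream."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if k == 1:
        return PhenotypeAssignment(np.ones(n, dtype=int), 1)
    if k == n:
        return PhenotypeAssignment(np.arange(1, n + 1), n)
    Z = linkage(x, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return PhenotypeAssignment(labels, k)


def consensus_cluster(
    x: np.ndarray,
    ks: range | list[int] = range(2, 7),
    n_resamples: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus clustering over subsamples.

    For each k the dataset is repeatedly subsampled without replacement,
    Ward-clustered, and pairwise co-clustering counts accumulated; the
    consensus of a pair is its co-clustering count divided by its
    co-sampling count.  Stability per k is summarized by the area under
    the empirical CDF of the upper-triangular consensus values
    (never-co-sampled pairs are excluded and logged).
    """
    if n_resamples < 2:
        raise ValueError("need at least 2 resamples")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample fraction must be in (0, 1]")
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    m = max(2, int(round(subsample_fraction * n)))
    rng = np.random.default_rng(seed)
    ks = list(ks)

    # co-sampling counts are shared across k for a fixed seed sequence
    draws = [
        np.sort(rng.choice(n, size=m, replace=False))
        if subsample_fraction < 1
        else np.arange(n)
        for _ in range(n_resamples)
    ]
    cosample = np.zeros((n, n))
    for idx in draws:
        cosample[np.ix_(idx, idx)] += 1

    grid = np.linspace(0, 1, 101)
    consensus: dict[int, np.ndarray] = {}
    cdfs: dict[int, np.ndarray] = {}
    areas: dict[int, float] = {}
    iu = np.triu_indices(n, k=1)
    never = int((cosample[iu] == 0).sum())
    if never:
        logger.warning("%d sample pairs were never co-sampled; excluded "
                       "from consensus CDFs", never)
    for k in ks:
        cocluster = np.zeros((n, n))
        for idx in draws:
            labels = ward_cluster(x[idx], min(k, len(idx))).labels
            same = labels[:, None] == labels[None, :]
            cocluster[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore", divide="ignore"):
            cons = np.where(cosample > 0, cocluster / np.maximum(cosample, 1), np.nan)
        np.fill_diagonal(cons, 1.0)
        vals = cons[iu]
        vals = vals[~np.isnan(vals)]
        cdf = np.array([(vals <= g).mean() for g in grid])
        consensus[k] = cons
        cdfs[k] = cdf
        areas[k] = float(np.trapezoid(cdf, grid))
    return ConsensusResult(
        ks=ks,
        consensus=consensus,
        cdf_grid=grid,
        cdfs=cdfs,
        areas=areas,
        n_resamples=n_resamples,
        subsample_fraction=subsample_fraction,
        n_never_cosampled=never,
    )


def _two_means_ci(x: np.ndarray, n_restarts: int, rng: np.random.Generator) -> float:
    """Cluster index of the best 2-means partition (within-cluster SS over
    total SS), by Lloyd's algorithm with seeded random restarts."""
    n = x.shape[0]
    total = float(((x - x.mean(axis=0)) ** 2).sum())
    if total <= 0:
        return 1.0
    best = np.inf
    for _ in range(n_restarts):
        c = x[rng.choice(n, size=2, replace=False)].copy()
        prev = None
        for _ in range(100):
            d0 = ((x - c[0]) ** 2).sum(axis=1)
            d1 = ((x - c[1]) ** 2).sum(axis=1)
            assign = d1 < d0
            if prev is not None and np.array_equal(assign, prev):
                break
            prev = assign
            if assign.all() or (~assign).all():
                break
            c[0] = x[~assign].mean(axis=0)
            c[1] = x[assign].mean(axis=0)
        within = float(((x[~assign] - c[0]) ** 2).sum() + ((x[assign] - c[1]) ** 2).sum())
        best = min(best, within)
    return best / total


def sigclust(
    x: np.ndarray,
    n_sim: int = 10_000,
    seed: int = 0,
    floor_eigenvalues: bool = True,
    n_restarts: int = 10,
) -> SigClustResult:
    """Significance of 2-cluster structure against a Gaussian null.

    The null is a zero-mean Gaussian whose covariance eigenvalues are
    estimated from the data and floored (by default) at a background-noise
    variance taken robustly from the median absolute deviation of the
    column-standardized entries.  Eigenvalues come from a Ledoit-Wolf
    shrunk covariance: raw sample eigenvalues overstate anisotropy at
    moderate n/d (the null would then look more clusterable than the data,
    making the test severely conservative), and shrinkage toward the
    spherical target corrects this while preserving genuine structure.
    The p-value is the fraction of null cluster indices at or below the
    observed one.
    """
    x = np.asarray(x, dtype=float)
    n, d = x.shape
    if n < 4:
        raise ValueError("need at least 4 samples")
    if n_sim < 100:
        raise ValueError("need at least 100 null simulations")
    rng = np.random.default_rng(seed)

    ci_obs = _two_means_ci(x, n_restarts, rng)

    cov = LedoitWolf(assume_centered=False).fit(x).covariance_
    eig = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
    if floor_eigenvalues:
        # background noise on the same scale as the eigenvalues: pooled
        # MAD of the column-centered entries
        resid = x - x.mean(axis=0)
        sigma_bg = np.median(np.abs(resid - np.median(resid))) / 0.6744897501960817
        eig = np.maximum(eig, sigma_bg**2)
    sd = np.sqrt(eig)

    null_ci = np.empty(n_sim)
    for s in range(n_sim):
        sim = rng.standard_normal((n, d)) * sd[None, :]
        null_ci[s] = _two_means_ci(sim, n_restarts, rng)
    p = float((null_ci <= ci_obs).mean())
    return SigClustResult(ci=float(ci_obs), null_ci=null_ci, pvalue=p, n_sim=n_sim)


def _split_members(x: np.ndarray, k: int) -> np.ndarray:
    """Member mask of the parent cluster that splits when moving from k-1
    to k Ward clusters (the whole cohort for k = 2)."""
    if k == 2:
        return np.ones(x.shape[0], dtype=bool)
    prev = ward_cluster(x, k - 1).labels
    cur = ward_cluster(x, k).labels
    for lab in np.unique(prev):
        sel = prev == lab
        if len(np.unique(cur[sel])) > 1:
            return sel
    return np.ones(x.shape[0], dtype=bool)


def select_k(
    x: np.ndarray,
    consensus: ConsensusResult,
    n_sim: int = 1000,
    alpha: float = 0.05,
    delta_area_threshold: float = 0.1,
    seed: int = 0,
) -> KSelection:
    """Choose the number of phenotypes.

    Returns the largest k whose relative increase in consensus-CDF area
    exceeds the threshold and whose every binary split up to k is
    SigClust-significant at ``alpha``; falls back to k = 2 (flagged) when
    no k qualifies.
    """
    ks = sorted(consensus.ks)
    if ks[0] != 2:
        raise ValueError("k range must start at 2")
    areas = consensus.areas
    deltas: dict[int, float] = {ks[0]: areas[ks[0]]}
    for prev, cur in zip(ks, ks[1:]):
        deltas[cur] = (areas[cur] - areas[prev]) / areas[prev] if areas[prev] > 0 else 0.0

    pvals: dict[int, float] = {}
    notes: list[str] = []
    candidates = []
    for j, k in enumerate(ks):
        members = _split_members(x, k)
        if members.sum() < 4:
            pvals[k] = 1.0
            notes.append(f"k={k}: split cluster too small for SigClust")
        else:
            pvals[k] = sigclust(x[members], n_sim=n_sim, seed=seed + k).pvalue
        stable = deltas[k] > delta_area_threshold
        significant = all(pvals[kk] < alpha for kk in ks[: j + 1])
        if stable and significant:
            candidates.append(k)

    if candidates:
        k_opt = max(candidates)
        flag = True
    else:
        k_opt = 2
        flag = False
        notes.append("no significant stable structure; falling back to k=2")
        logger.warning("no significant cluster structure detected (k=2 fallback)")
    return KSelection(
        k=k_opt,
        delta_areas=deltas,
        sigclust_pvalues=pvals,
        significant_structure=flag,
        threshold=delta_area_threshold,
        notes=notes,
    )


def discover_phenotypes(
    features: pd.DataFrame,
    ks: range | list[int] = range(2, 7),
    n_resamples: int = 1000,
    subsample_fraction: float = 0.8,
    n_sim: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[pd.Series, KSelection, ConsensusResult]:
    """End-to-end phenotype discovery on a harmonized feature table:
    z-score, consensus-cluster, select k, and return final Ward labels."""
    x = zscore(features)
    cons = consensus_cluster(x, ks, n_resamples, subsample_fraction, seed)
    sel = select_k(x, cons, n_sim=n_sim, alpha=alpha, seed=seed)
    labels = ward_cluster(x, sel.k).labels
    return (
        pd.Series(labels, index=features.index, name="phenotype"),
        sel,
        cons,
    )
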