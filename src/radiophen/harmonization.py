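"""ComBat empirical-Bayes batch-effect harmonization, the nested
multi-batch variant, and non-robust feature removal.

ComBat models feature g of sample j in batch level i as

    y_ijg = alpha_g + x_j' beta_g + gamma_ig + delta_ig eps_ijg

and removes the per-level location/scale terms (gamma, delta) after
shrinking their feature-wise estimates toward batch-level priors by
parametric empirical Bayes (normal prior on location, inverse-gamma on
scale, moment-matched hyperparameters, iterated to convergence).
Biological covariates supplied as "protected" enter the design matrix so
their variation survives harmonization.

Nested ComBat handles several batch variables by harmonizing sequentially
in every possible order and keeping the order that leaves the fewest
features with batch-dependent distributions, as flagged per feature by the
k-sample Anderson-Darling test.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CombatEstimates",
    "NestedHarmonizationReport",
    "encode_covariates",
    "combat",
    "ad_significant_count",
    "nested_combat",
    "drop_nonrobust",
]

#: covariates the target analysis protects during harmonization.  Note that
#: protecting outcome variables (event, PFS time) follows the published
#: procedure but lets outcome information shape the harmonized features;
#: see docs/methods.md.  Pass ``covariates=None`` to harmonize unprotected.
DEFAULT_PROTECTED = (
    "age", "sex", "race", "pdl1_pct", "ecog", "bmi", "smoking",
    "event", "pfs_days",
)


@dataclass
class CombatEstimates:
    """Empirical-Bayes estimates for one ComBat fit.

    gamma_hat/gamma_star are per (batch level x feature) location
    estimates in pooled-standardized units; delta2_hat/delta2_star the
    corresponding squared scales.  Hyperparameters are per batch level.
    """

    levels: list[str]
    features: list[str]
    gamma_hat: np.ndarray
    delta2_hat: np.ndarray
    gamma_star: np.ndarray
    delta2_star: np.ndarray
    gamma_bar: np.ndarray
    tau2: np.ndarray
    lambda_prior: np.ndarray
    theta_prior: np.ndarray
    alpha: np.ndarray          # grand location per feature
    sigma: np.ndarray          # pooled SD per feature
    n_iterations: int = 0


@dataclass
class NestedHarmonizationReport:
    permutations: list[tuple[str, ...]]
    counts_per_variable: list[dict[str, int]]
    total_counts: list[int]
    selected: tuple[str, ...]
    alpha: float
    estimates: dict[str, CombatEstimates] = field(default_factory=dict)
    dropped_zero_variance: list[str] = field(default_factory=list)

    @property
    def selected_total(self) -> int:
        return self.total_counts[self.permutations.index(self.selected)]


def encode_covariates(
    covariates: pd.DataFrame,
    categorical: list[str] | None = None,
    continuous: list[str] | None = None,
) -> pd.DataFrame:
    """Design columns for protected covariates: categorical variables are
    reference-coded (first observed level dropped), continuous variables
    standardized.  Raises if the encoded design is column-rank deficient."""
    if categorical is None or continuous is None:
        auto_cat = [
            c for c in covariates.columns
            if covariates[c].dtype == object or str(covariates[c].dtype) == "category"
        ]
        categorical = auto_cat if categorical is None else categorical
        continuous = (
            [c for c in covariates.columns if c not in auto_cat]
            if continuous is None
            else continuous
        )
    parts = []
    for c in categorical:
        d = pd.get_dummies(covariates[c].astype(str), prefix=c, drop_first=True)
        parts.append(d.astype(float))
    for c in continuous:
        x = covariates[c].astype(float)
        sd = x.std(ddof=0)
        parts.append(((x - x.mean()) / sd if sd > 0 else x * 0.0).to_frame(c))
    if not parts:
        return pd.DataFrame(index=covariates.index)
    X = pd.concat(parts, axis=1)
    if np.linalg.matrix_rank(X.to_numpy(float)) < X.shape[1]:
        raise ValueError("protected covariate design is rank deficient after encoding")
    return X


def _design(batch: pd.Series, covariates: pd.DataFrame | None):
    levels = list(pd.unique(batch))
    B = np.column_stack([(batch == lv).to_numpy(float) for lv in levels])
    counts = B.sum(axis=0)
    if (counts < 2).any():
        small = [lv for lv, c in zip(levels, counts) if c < 2]
        raise ValueError(f"batch level(s) with < 2 samples: {small}")
    if covariates is not None and covariates.shape[1] > 0:
        C = covariates.to_numpy(float)
        X = np.hstack([B, C])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                "design matrix singular: a protected covariate is confounded "
                "with the batch variable"
            )
    else:
        C = np.zeros((len(batch), 0))
        X = B
    return levels, B, C, X


def combat(
    features: pd.DataFrame,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
    parametric: bool = True,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[pd.DataFrame, CombatEstimates]:
    """Harmonize a samples x features table across the levels of one batch
    variable, preserving protected covariate effects.

    ``covariates`` must already be encoded (see :func:`encode_covariates`).
    Returns the adjusted table and the EB estimates.  Features with zero
    variance are rejected (they cannot be standardized).
    """
    if not parametric:
        raise NotImplementedError("only the parametric EB variant is implemented")
    batch = batch.loc[features.index]
    if covariates is not None:
        covariates = covariates.loc[features.index]
    Y = features.to_numpy(float)
    n, d = Y.shape
    zero_var = features.columns[Y.std(axis=0) == 0]
    if len(zero_var):
        raise ValueError(f"zero-variance feature(s): {list(zero_var)}")

    levels, B, C, X = _design(batch, covariates)
    n_levels = len(levels)
    n_i = B.sum(axis=0)

    beta_full, *_ = np.linalg.lstsq(X, Y, rcond=None)
    batch_coef = beta_full[:n_levels]            # per-level locations
    cov_coef = beta_full[n_levels:]
    alpha = (n_i / n) @ batch_coef               # size-weighted grand location
    cov_part = C @ cov_coef if C.shape[1] else 0.0

    resid = Y - X @ beta_full
    sigma = np.sqrt((resid**2).mean(axis=0))
    sigma = np.where(sigma <= 0, 1e-12, sigma)

    Z = (Y - alpha[None, :] - cov_part) / sigma[None, :]

    gamma_hat = np.empty((n_levels, d))
    delta2_hat = np.empty((n_levels, d))
    for i in range(n_levels):
        zi = Z[B[:, i] > 0]
        gamma_hat[i] = zi.mean(axis=0)
        delta2_hat[i] = zi.var(axis=0, ddof=1)

    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    m = delta2_hat.mean(axis=1)
    s2 = delta2_hat.var(axis=1, ddof=1)
    lam = (2 * s2 + m**2) / np.maximum(s2, 1e-12)          # inverse-gamma shape
    theta = (m * s2 + m**3) / np.maximum(s2, 1e-12)        # inverse-gamma scale

    gamma_star = gamma_hat.copy()
    delta2_star = delta2_hat.copy()
    n_it = 0
    for i in range(n_levels):
        ni = n_i[i]
        zi = Z[B[:, i] > 0]
        g, d2 = gamma_hat[i].copy(), delta2_hat[i].copy()
        for n_it in range(1, max_iter + 1):
            g_new = (ni * tau2[i] * gamma_hat[i] + d2 * gamma_bar[i]) / (
                ni * tau2[i] + d2
            )
            ss = ((zi - g_new[None, :]) ** 2).sum(axis=0)
            d2_new = (theta[i] + 0.5 * ss) / (ni / 2.0 + lam[i] - 1.0)
            change = max(
                np.abs(g_new - g).max(), np.abs(d2_new - d2).max()
            )
            g, d2 = g_new, d2_new
            if change < tol:
                break
        gamma_star[i] = g
        delta2_star[i] = d2

    adj = Z.copy()
    for i in range(n_levels):
        sel = B[:, i] > 0
        adj[sel] = (Z[sel] - gamma_star[i][None, :]) / np.sqrt(delta2_star[i])[None, :]
    Y_adj = adj * sigma[None, :] + alpha[None, :] + cov_part

    est = CombatEstimates(
        levels=[str(lv) for lv in levels],
        features=list(features.columns),
        gamma_hat=gamma_hat,
        delta2_hat=delta2_hat,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        gamma_bar=gamma_bar,
        tau2=tau2,
        lambda_prior=lam,
        theta_prior=theta,
        alpha=alpha,
        sigma=sigma,
        n_iterations=n_it,
    )
    out = pd.DataFrame(Y_adj, index=features.index, columns=features.columns)
    return out, est


def ad_significant_count(
    features: pd.DataFrame,
    batch: pd.Series,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[int, pd.Series]:
    """Per-feature k-sample Anderson-Darling test across batch levels.

    Uses the Scholz-Stephens asymptotic p-value; if any level has fewer
    than 5 samples, falls back (with a warning) to an exact permutation
    p-value with 2000 seeded resamples.  Returns the count of features
    with p < alpha and the per-feature p-values.
    """
    batch = batch.loc[features.index]
    levels = pd.unique(batch)
    if len(levels) < 2:
        raise ValueError("need at least 2 batch levels")
    groups_idx = [batch == lv for lv in levels]
    sizes = [int(g.sum()) for g in groups_idx]
    method = None
    if min(sizes) < 5:
        warnings.warn(
            f"batch level with < 5 samples (sizes {sizes}); using exact "
            "permutation p-values",
            stacklevel=2,
        )
        method = stats.PermutationMethod(
            n_resamples=2000, rng=np.random.default_rng(seed)
        )
    pvals = {}
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*p-value capped.*|.*p-value floored.*"
        )
        for col in features.columns:
            samples = [features.loc[g, col].to_numpy(float) for g in groups_idx]
            if all(np.ptp(s) == 0 for s in samples) and len(
                set(s[0] for s in samples)
            ) == 1:
                pvals[col] = 1.0
                continue
            res = stats.anderson_ksamp(samples, variant="midrank", method=method)
            pvals[col] = float(res.pvalue)
    p = pd.Series(pvals, name="ad_pvalue")
    return int((p < alpha).sum()), p


def nested_combat(
    features: pd.DataFrame,
    batches: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, NestedHarmonizationReport]:
    """Sequential ComBat over every ordering of the batch variables.

    Each permutation starts from the original features and harmonizes by
    each batch variable in turn; each fully harmonized set is scored by
    the total number of AD-significant features summed over all batch
    variables, and the minimizing permutation is returned (ties keep the
    ordering closest to the supplied column order).
    """
    batch_vars = list(batches.columns)
    if not batch_vars:
        raise ValueError("need at least one batch variable")
    zero_var = list(features.columns[features.std(axis=0, ddof=0) == 0])
    if zero_var:
        warnings.warn(
            f"removing zero-variance feature(s) before harmonization: {zero_var}",
            stacklevel=2,
        )
        features = features.drop(columns=zero_var)

    perms = list(itertools.permutations(batch_vars))
    results: list[pd.DataFrame] = []
    counts_per_var: list[dict[str, int]] = []
    totals: list[int] = []
    est_by_perm: list[dict[str, CombatEstimates]] = []
    for perm in perms:
        data = features
        ests: dict[str, CombatEstimates] = {}
        for step, var in enumerate(perm):
            try:
                data, ests[var] = combat(data, batches[var], covariates)
            except Exception as exc:
                raise RuntimeError(
                    f"ComBat failed in permutation {perm} at step {step} "
                    f"(batch variable '{var}'): {exc}"
                ) from exc
        per_var = {
            var: ad_significant_count(data, batches[var], alpha, seed=seed)[0]
            for var in batch_vars
        }
        results.append(data)
        counts_per_var.append(per_var)
        totals.append(sum(per_var.values()))
        est_by_perm.append(ests)
        logger.info("permutation %s: AD-significant %s (total %d)",
                    perm, per_var, totals[-1])

    best = int(np.argmin(totals))  # first minimum; perms[0] is supplied order
    report = NestedHarmonizationReport(
        permutations=perms,
        counts_per_variable=counts_per_var,
        total_counts=totals,
        selected=perms[best],
        alpha=alpha,
        estimates=est_by_perm[best],
        dropped_zero_variance=zero_var,
    )
    return results[best], report


def drop_nonrobust(
    harmonized: pd.DataFrame,
    batches: pd.DataFrame,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Discard features whose distribution still differs across the levels
    of any batch variable after harmonization (AD p < alpha)."""
    dropped: set[str] = set()
    for var in batches.columns:
        _, p = ad_significant_count(harmonized, batches[var], alpha, seed=seed)
        dropped.update(p.index[p < alpha])
    if len(dropped) == harmonized.shape[1]:
        raise ValueError(
            "all features flagged as non-robust; nothing left to analyze"
        )
    kept = harmonized.drop(columns=sorted(dropped))
    return kept, sorted(dropped)
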