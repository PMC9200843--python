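"""Prognostic survival modeling and phenotype-covariate association.

The model menu mirrors the target analysis: tumor volume, radiomic
phenotype, clinical covariates (PD-L1, ECOG, BMI, smoking), and their
combinations, each evaluated by repeated five-fold cross-validated Cox
proportional-hazards concordance (Harrell's c on pooled out-of-fold risk
scores, one value per iteration; 95% CI as 2.5/97.5 percentiles over
iterations) and by Kaplan-Meier curves split at the median risk score
with the log-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

logger = logging.getLogger(__name__)

__all__ = [
    "CoxCVResult",
    "KMResult",
    "MODEL_MENU",
    "encode_clinical",
    "build_design",
    "fit_cox",
    "cv_concordance",
    "median_split_km",
    "stratified_by_therapy",
    "chi_square_assoc",
    "phenotype_predicts_pdl1",
]

#: predictor sets of the standard model menu
MODEL_MENU: dict[str, list[str]] = {
    "volume": ["volume"],
    "phenotype": ["phenotype"],
    "clinical": ["clinical"],
    "volume+clinical": ["volume", "clinical"],
    "phenotype+clinical": ["phenotype", "clinical"],
}

#: clinical covariates entering the prognostic models, with their
#: category boundaries (reference level listed first)
CLINICAL_CATEGORIES: dict[str, list[str]] = {
    "pdl1_cat": ["lt10", "10to50", "ge50"],
    "bmi_cat": ["underweight", "normal", "overweight", "obese"],
    "smoking": ["former", "current", "never"],
    "ecog": ["0", "1", "2", "3"],
}


@dataclass
class CoxCVResult:
    concordances: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    folds: int
    iterations: int
    seed: int


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]
    logrank_statistic: float
    pvalue: float
    group_sizes: dict[str, int]
    threshold: float


def _categorize(clinical: pd.DataFrame) -> pd.DataFrame:
    """Derive the categorical clinical covariates from raw values where
    needed (PD-L1 % -> 3 categories, BMI -> 4 categories)."""
    out = clinical.copy()
    if "pdl1_cat" not in out.columns and "pdl1_pct" in out.columns:
        p = out["pdl1_pct"].astype(float)
        out["pdl1_cat"] = np.select(
            [p < 10, p < 50], ["lt10", "10to50"], default="ge50"
        )
    if "bmi_cat" not in out.columns and "bmi" in out.columns:
        b = out["bmi"].astype(float)
        out["bmi_cat"] = np.select(
            [b < 18.5, b <= 24.9, b <= 29.9],
            ["underweight", "normal", "overweight"],
            default="obese",
        )
    return out


def encode_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Reference-coded design columns for the prognostic clinical
    covariates (PD-L1 category, BMI category, smoking status, ECOG)."""
    cat = _categorize(clinical)
    parts = []
    for var, levels in CLINICAL_CATEGORIES.items():
        if var not in cat.columns:
            continue
        col = cat[var].astype(str)
        present = [lv for lv in levels if (col == lv).any()]
        for lv in present[1:]:  # first present level is the reference
            parts.append((col == lv).astype(float).rename(f"{var}_{lv}"))
    if not parts:
        raise ValueError("no clinical covariates found to encode")
    return pd.concat(parts, axis=1)


def build_design(
    model: str,
    clinical: pd.DataFrame,
    phenotypes: pd.Series | None = None,
    volume: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble the predictor matrix for one entry of the model menu."""
    if model not in MODEL_MENU:
        raise ValueError(f"unknown model '{model}'; choose from {list(MODEL_MENU)}")
    parts = []
    for component in MODEL_MENU[model]:
        if component == "clinical":
            parts.append(encode_clinical(clinical))
        elif component == "phenotype":
            if phenotypes is None:
                raise ValueError("model requires phenotype labels")
            ph = phenotypes.astype("category")
            dummies = pd.get_dummies(ph, prefix="phenotype", drop_first=True)
            parts.append(dummies.astype(float))
        elif component == "volume":
            if volume is None:
                raise ValueError("model requires tumor volume")
            parts.append(np.log(volume.astype(float)).rename("log_volume"))
    return pd.concat(parts, axis=1)


def _surv_frame(survival: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    df = design.copy()
    df["pfs_days"] = survival["pfs_days"].astype(float)
    df["event"] = survival["event"].astype(int)
    return df


def fit_cox(
    survival: pd.DataFrame, predictors: pd.DataFrame
) -> tuple[pd.Series, pd.Series]:
    """Cox proportional-hazards fit (Efron tie handling).

    Returns (coefficients, per-sample linear predictor).
    """
    if int(survival["event"].sum()) < 2:
        raise ValueError("need at least 2 events")
    df = _surv_frame(survival, predictors)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="pfs_days", event_col="event")
    except Exception as exc:
        raise RuntimeError(
            "Cox fit failed (possible monotone likelihood / perfect "
            "separation; consider removing or coarsening the offending "
            f"predictor): {exc}"
        ) from exc
    lp = pd.Series(
        cph.predict_log_partial_hazard(df).to_numpy().ravel(),
        index=predictors.index,
        name="risk_score",
    )
    return cph.params_, lp


def _fit_fold(survival: pd.DataFrame, X: pd.DataFrame) -> np.ndarray:
    """Cox fit for one training fold; a light ridge penalty (escalated on
    convergence failure) stabilizes sparse categorical levels in small
    folds without materially changing risk-score orderings."""
    df = _surv_frame(survival, X)
    for penalizer in (0.01, 0.1, 1.0):
        try:
            cph = CoxPHFitter(penalizer=penalizer)
            cph.fit(df, duration_col="pfs_days", event_col="event")
            return cph.params_.to_numpy()
        except Exception:
            continue
    logger.warning("fold fit failed at all penalties; scoring as null")
    return np.zeros(X.shape[1])


def robust_risk_scores(
    survival: pd.DataFrame, predictors: pd.DataFrame
) -> pd.Series:
    """Per-sample risk scores from the full-data Cox fit, falling back to
    a lightly penalized fit when the unpenalized likelihood fails
    (monotone likelihood on sparse categorical levels)."""
    try:
        _, lp = fit_cox(survival, predictors)
        return lp
    except RuntimeError:
        logger.warning("unpenalized Cox fit failed; using penalized fit "
                       "for risk scores")
        coef = _fit_fold(survival, predictors)
        return pd.Series(
            predictors.to_numpy(float) @ coef,
            index=predictors.index,
            name="risk_score",
        )


def cv_concordance(
    survival: pd.DataFrame,
    predictors: pd.DataFrame,
    folds: int = 5,
    iterations: int = 200,
    seed: int = 0,
) -> CoxCVResult:
    """Repeated k-fold cross-validated Cox concordance.

    Per iteration: shuffle, split into folds, fit on the training folds,
    score held-out samples, pool the out-of-fold risk scores, and compute
    one Harrell concordance; summarized as the mean and the percentile
    95% interval over iterations.
    """
    n = len(predictors)
    rng = np.random.default_rng(seed)
    times = survival["pfs_days"].to_numpy(float)
    events = survival["event"].to_numpy(int)
    cvals = np.empty(iterations)
    for it in range(iterations):
        for attempt in range(10):
            order = rng.permutation(n)
            fold_of = np.empty(n, dtype=int)
            fold_of[order] = np.arange(n) % folds
            ok = all(events[fold_of != f].sum() >= 2 for f in range(folds))
            if ok:
                break
            logger.info("resampling folds (a fold lacked events)")
        else:
            raise RuntimeError("could not build folds with enough events")
        risk = np.empty(n)
        for f in range(folds):
            tr = fold_of != f
            X_tr = predictors.iloc[tr]
            # columns constant within the training fold carry no
            # information and break the partial likelihood
            keep = X_tr.columns[X_tr.std(axis=0) > 0]
            coef = _fit_fold(survival.iloc[tr], X_tr[keep])
            risk[~tr] = predictors.iloc[~tr][keep].to_numpy(float) @ coef
        cvals[it] = concordance_index(times, -risk, events)
    lo, hi = np.percentile(cvals, [2.5, 97.5])
    return CoxCVResult(
        concordances=cvals,
        mean=float(cvals.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        folds=folds,
        iterations=iterations,
        seed=seed,
    )


def median_split_km(
    risk_scores: pd.Series, survival: pd.DataFrame
) -> KMResult:
    """Kaplan-Meier curves for samples at or below vs above the median
    risk score, compared by the log-rank test (1 df)."""
    if len(risk_scores) < 4:
        raise ValueError("need at least 4 samples")
    scores = risk_scores.astype(float)
    med = float(scores.median())
    low = scores <= med
    if low.all():
        # ties at the median swallowed the cohort (e.g. a binary score
        # with a majority level): split strictly below instead
        low = scores < med
    if low.all() or not low.any():
        raise ValueError("all risk scores identical; cannot split at median")
    groups = {"low_risk": low, "high_risk": ~low}
    curves = {}
    for name, sel in groups.items():
        km = KaplanMeierFitter()
        km.fit(
            survival.loc[sel.values, "pfs_days"],
            survival.loc[sel.values, "event"],
            label=name,
        )
        curves[name] = km.survival_function_
    lr = logrank_test(
        survival.loc[low.values, "pfs_days"],
        survival.loc[(~low).values, "pfs_days"],
        survival.loc[low.values, "event"],
        survival.loc[(~low).values, "event"],
    )
    return KMResult(
        curves=curves,
        logrank_statistic=float(lr.test_statistic),
        pvalue=float(lr.p_value),
        group_sizes={k: int(v.sum()) for k, v in groups.items()},
        threshold=med,
    )


def stratified_by_therapy(
    survival: pd.DataFrame,
    predictors: pd.DataFrame,
    therapy: pd.Series,
    folds: int = 5,
    iterations: int = 200,
    seed: int = 0,
    min_stratum: int = 20,
) -> dict[str, tuple[CoxCVResult, KMResult]]:
    """Run the CV-concordance + median-split KM pipeline within each
    therapy stratum; undersized strata are skipped with a warning."""
    out: dict[str, tuple[CoxCVResult, KMResult]] = {}
    for level in pd.unique(therapy):
        sel = (therapy == level).values
        if sel.sum() < min_stratum:
            logger.warning("stratum '%s' has %d samples (< %d); skipped",
                           level, sel.sum(), min_stratum)
            continue
        surv_s = survival.loc[sel]
        pred_s = predictors.loc[sel]
        cv = cv_concordance(surv_s, pred_s, folds, iterations, seed)
        lp = robust_risk_scores(surv_s, pred_s)
        km = median_split_km(lp, surv_s)
        out[str(level)] = (cv, km)
    return out


def chi_square_assoc(
    phenotypes: pd.Series, covariate: pd.Series
) -> tuple[float, float]:
    """Pearson chi-square test of independence between phenotype labels
    and a categorical covariate (no continuity correction)."""
    table = pd.crosstab(phenotypes, covariate)
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    if (expected == 0).any():
        raise ValueError(
            "contingency table has an expected count of 0; merge sparse "
            "categories before testing"
        )
    return float(chi2), float(p)


def phenotype_predicts_pdl1(
    phenotypes: pd.Series,
    pdl1: pd.Series,
    high_threshold: float = 50.0,
    test_size: float = 0.3,
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Random-forest prediction of high PD-L1 expression from the
    phenotype label alone; returns (cross-validated AUC on the training
    split, holdout AUC)."""
    X = pd.get_dummies(phenotypes.astype("category"), prefix="ph").to_numpy(float)
    y = (pdl1.astype(float) >= high_threshold).astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("PD-L1 outcome has a single class")
    for attempt in range(10):
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=test_size, random_state=seed + attempt, stratify=y
        )
        if len(np.unique(ytr)) == 2 and len(np.unique(yte)) == 2:
            break
        logger.info("re-drawing train/test split (single-class side)")
    clf = RandomForestClassifier(n_estimators=200, random_state=seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(Xtr, ytr):
        clf.fit(Xtr[tr], ytr[tr])
        prob = clf.predict_proba(Xtr[te])[:, 1]
        if len(np.unique(ytr[te])) == 2:
            aucs.append(roc_auc_score(ytr[te], prob))
    clf.fit(Xtr, ytr)
    holdout = roc_auc_score(yte, clf.predict_proba(Xte)[:, 1])
    return float(np.mean(aucs)), float(holdout)
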