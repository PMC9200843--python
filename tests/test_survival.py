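import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radiophen.survival import (
    MODEL_MENU,
    build_design,
    chi_square_assoc,
    cv_concordance,
    encode_clinical,
    fit_cox,
    median_split_km,
    phenotype_predicts_pdl1,
    stratified_by_therapy,
)
from radiophen.synthetic import SurvivalDef, simulate_survival
from lifelines.utils import concordance_index

from oracles import two_point_auc


def _binary_cohort(n=1000, log_hr=1.0, rate=0.005, censor=800.0, seed=0):
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < 0.5).astype(float)
    sdef = SurvivalDef(baseline_rate=rate, cluster_log_hr=(0.0,),
                       censoring_window=censor)
    surv = simulate_survival(x * log_hr, sdef, seed=seed + 1)
    return pd.DataFrame({"x": x}), surv


class TestFitCox:
    def test_null_predictor_coefficient_near_zero(self):
        pred, surv = _binary_cohort(n=500, log_hr=0.0, seed=1)
        coef, _ = fit_cox(surv, pred)
        se = 2.0 / np.sqrt(surv["event"].sum())  # conservative SE bound
        assert abs(coef["x"]) < 3 * se

    def test_planted_log_hazard_recovered(self):
        pred, surv = _binary_cohort(n=1000, log_hr=1.0, seed=2)
        coef, _ = fit_cox(surv, pred)
        assert coef["x"] == pytest.approx(1.0, abs=0.15)

    def test_sample_duplication_leaves_coefficient_unchanged(self):
        pred, surv = _binary_cohort(n=300, log_hr=0.8, seed=3)
        coef1, _ = fit_cox(surv, pred)
        pred2 = pd.concat([pred, pred], ignore_index=True)
        surv2 = pd.concat([surv, surv], ignore_index=True)
        coef2, _ = fit_cox(surv2, pred2)
        assert coef2["x"] == pytest.approx(coef1["x"], abs=0.02)

    def test_too_few_events_rejected(self):
        pred, surv = _binary_cohort(n=20, seed=4)
        surv = surv.assign(event=0)
        with pytest.raises(ValueError, match="events"):
            fit_cox(surv, pred)


class TestCVConcordance:
    def test_noise_predictor_is_chance(self):
        rng = np.random.default_rng(5)
        pred = pd.DataFrame({"z": rng.standard_normal(300)})
        surv = simulate_survival(
            np.zeros(300), SurvivalDef(0.005, (0.0,), 800.0), seed=5
        )
        cv = cv_concordance(surv, pred, iterations=50, seed=5)
        assert 0.45 <= cv.mean <= 0.55

    def test_planted_effect_matches_simulation_oracle(self):
        # oracle: population concordance of the true predictor, from a
        # large independent draw of the same generative model
        pred_big, surv_big = _binary_cohort(n=20000, log_hr=1.5, seed=6)
        oracle = concordance_index(
            surv_big["pfs_days"], -pred_big["x"], surv_big["event"]
        )
        pred, surv = _binary_cohort(n=1000, log_hr=1.5, seed=7)
        cv = cv_concordance(surv, pred, iterations=50, seed=7)
        assert cv.mean == pytest.approx(oracle, abs=0.03)

    def test_deterministic_for_fixed_seed(self):
        pred, surv = _binary_cohort(n=200, seed=8)
        cv1 = cv_concordance(surv, pred, iterations=5, seed=8)
        cv2 = cv_concordance(surv, pred, iterations=5, seed=8)
        np.testing.assert_array_equal(cv1.concordances, cv2.concordances)

    def test_ci_percentiles_bracket_mean(self):
        pred, surv = _binary_cohort(n=300, seed=9)
        cv = cv_concordance(surv, pred, iterations=20, seed=9)
        assert cv.ci_low <= cv.mean <= cv.ci_high
        assert ((cv.concordances >= 0) & (cv.concordances <= 1)).all()

    def test_concordance_invariant_to_monotone_transform(self):
        pred, surv = _binary_cohort(n=400, log_hr=1.0, seed=10)
        _, lp = fit_cox(surv, pred)
        c1 = concordance_index(surv["pfs_days"], -lp, surv["event"])
        c2 = concordance_index(
            surv["pfs_days"], -(np.exp(2 * lp) + 5), surv["event"]
        )
        assert c1 == pytest.approx(c2)


class TestMedianSplitKM:
    def test_distinct_scores_split_evenly(self):
        rng = np.random.default_rng(11)
        scores = pd.Series(rng.permutation(100).astype(float))
        surv = simulate_survival(
            np.zeros(100), SurvivalDef(0.005, (0.0,), None), seed=11
        )
        km = median_split_km(scores, surv)
        assert km.group_sizes["low_risk"] == km.group_sizes["high_risk"] == 50

    def test_curves_start_at_one_and_decrease(self):
        pred, surv = _binary_cohort(n=200, seed=12)
        _, lp = fit_cox(surv, pred)
        km = median_split_km(lp, surv)
        for curve in km.curves.values():
            vals = curve.iloc[:, 0].to_numpy()
            assert vals[0] == pytest.approx(1.0)
            assert (np.diff(vals) <= 1e-12).all()
            assert vals[-1] >= 0

    def test_identical_scores_rejected(self):
        surv = simulate_survival(
            np.zeros(10), SurvivalDef(0.005, (0.0,), None), seed=13
        )
        with pytest.raises(ValueError, match="identical"):
            median_split_km(pd.Series(np.ones(10)), surv)

    def test_planted_hazard_ratio_detected_with_power(self):
        hits = 0
        for rep in range(40):
            rng = np.random.default_rng(100 + rep)
            x = np.repeat([0.0, 1.0], 100)
            surv = simulate_survival(
                x * np.log(3.0), SurvivalDef(0.004, (0.0,), None),
                seed=200 + rep,
            )
            km = median_split_km(pd.Series(x + rng.normal(0, 1e-9, 200)), surv)
            hits += km.pvalue < 0.05
        assert hits >= 38  # >= 95% power

    def test_invariant_to_affine_score_rescaling(self):
        pred, surv = _binary_cohort(n=200, log_hr=1.0, seed=14)
        _, lp = fit_cox(surv, pred)
        km1 = median_split_km(lp, surv)
        km2 = median_split_km(3.0 * lp + 7.0, surv)
        assert km1.pvalue == pytest.approx(km2.pvalue)


class TestStratified:
    def test_strata_partition_cohort(self):
        pred, surv = _binary_cohort(n=300, seed=15)
        therapy = pd.Series(
            np.where(np.arange(300) % 3 == 0, "mono", "combo"),
            index=pred.index,
        )
        out = stratified_by_therapy(surv, pred, therapy, iterations=3, seed=15)
        sizes = {
            lv: (therapy == lv).sum() for lv in ("mono", "combo")
        }
        assert sum(sizes.values()) == 300
        assert set(out) == {"mono", "combo"}

    def test_single_stratum_reduces_to_unstratified(self):
        pred, surv = _binary_cohort(n=200, seed=16)
        therapy = pd.Series(["combo"] * 200, index=pred.index)
        out = stratified_by_therapy(surv, pred, therapy, iterations=5, seed=16)
        direct = cv_concordance(surv, pred, iterations=5, seed=16)
        np.testing.assert_array_equal(
            out["combo"][0].concordances, direct.concordances
        )

    def test_undersized_stratum_skipped(self):
        pred, surv = _binary_cohort(n=100, seed=17)
        therapy = pd.Series(["big"] * 95 + ["tiny"] * 5, index=pred.index)
        out = stratified_by_therapy(surv, pred, therapy, iterations=3, seed=17)
        assert "tiny" not in out


class TestChiSquare:
    def test_perfect_independence(self):
        ph = pd.Series([1] * 20 + [2] * 20)
        cov = pd.Series((["a"] * 10 + ["b"] * 10) * 2)
        chi2, p = chi_square_assoc(ph, cov)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_association(self):
        ph = pd.Series([1] * 25 + [2] * 25)
        cov = pd.Series(["a"] * 20 + ["b"] * 5 + ["a"] * 5 + ["b"] * 20)
        chi2, p = chi_square_assoc(ph, cov)
        assert chi2 == 18.0
        assert p < 0.001

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(18)
        ps = []
        for _ in range(300):
            ph = pd.Series(rng.choice([1, 2], 80))
            cov = pd.Series(rng.choice(["a", "b"], 80))
            ps.append(chi_square_assoc(ph, cov)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPDL1Prediction:
    def test_perfect_predictor(self):
        ph = pd.Series([1] * 50 + [2] * 50)
        pdl1 = pd.Series([80.0] * 50 + [5.0] * 50)
        cv_auc, holdout = phenotype_predicts_pdl1(ph, pdl1, seed=0)
        assert cv_auc == pytest.approx(1.0)
        assert holdout == pytest.approx(1.0)

    def test_independent_phenotype_near_chance(self):
        rng = np.random.default_rng(19)
        ph = pd.Series(rng.choice([1, 2], 400))
        pdl1 = pd.Series(rng.uniform(0, 100, 400))
        cv_auc, holdout = phenotype_predicts_pdl1(ph, pdl1, seed=19)
        assert 0.4 <= holdout <= 0.6

    def test_planted_mixture_matches_closed_form_roc(self):
        # 70/30 vs 30/70 class mix, balanced phenotypes, exact proportions
        ph = pd.Series([1] * 1000 + [2] * 1000)
        pdl1 = pd.Series(
            [80.0] * 700 + [5.0] * 300 + [80.0] * 300 + [5.0] * 700
        )
        expected = two_point_auc(0.7, 0.3)
        assert expected == pytest.approx(0.70)
        cv_auc, holdout = phenotype_predicts_pdl1(ph, pdl1, seed=20)
        assert holdout == pytest.approx(expected, abs=0.05)


class TestDesigns:
    def test_model_menu_designs_build(self):
        rng = np.random.default_rng(21)
        n = 60
        clinical = pd.DataFrame(
            {
                "pdl1_pct": rng.uniform(0, 100, n),
                "bmi": rng.normal(27, 4, n),
                "smoking": rng.choice(["former", "current", "never"], n),
                "ecog": rng.choice(["0", "1", "2"], n).astype(str),
            }
        )
        ph = pd.Series(rng.choice([1, 2], n))
        vol = pd.Series(rng.lognormal(3, 1, n))
        for model in MODEL_MENU:
            design = build_design(model, clinical, ph, vol)
            assert len(design) == n
            assert design.notnull().all().all()

    def test_reference_levels_are_dropped(self):
        clinical = pd.DataFrame(
            {"smoking": ["former", "current", "never", "former"]}
        )
        enc = encode_clinical(clinical)
        assert "smoking_former" not in enc.columns
        assert {"smoking_current", "smoking_never"} <= set(enc.columns)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            build_design("volume+phenotype", pd.DataFrame(), None, None)
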