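import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radiophen.synthetic import (
    BatchDef,
    ClusterDef,
    SurvivalDef,
    SyntheticSpec,
    default_cohort_spec,
    simulate_feature_cohort,
    simulate_survival,
    simulate_tumor_volume,
    write_cohort,
)

from conftest import single_batch_spec


class TestFeatureCohort:
    def test_null_model_calibrated_batch_tests(self):
        # no planted effects: two-sample t-tests across batches should
        # reject at roughly the nominal rate
        spec = single_batch_spec(n=200, n_features=200, gamma=0.0, delta=1.0,
                                 prop=(0.5, 0.5), seed=4)
        coh = simulate_feature_cohort(spec)
        a = coh.batches["batch"] == "A"
        rej = 0
        for col in coh.features:
            _, p = stats.ttest_ind(coh.features.loc[a.values, col],
                                   coh.features.loc[~a.values, col])
            rej += p < 0.05
        # binomial(200, 0.05) 99.9% band
        assert 1 <= rej <= 23

    def test_planted_location_shift_recovered_by_sample_means(self):
        coh = simulate_feature_cohort(single_batch_spec(seed=5))
        b = (coh.batches["batch"] == "B").values
        n_a, n_b = (~b).sum(), b.sum()
        for col in coh.features.columns[:20]:
            sd = coh.feature_sd[col]
            diff = (coh.features.loc[b, col].mean()
                    - coh.features.loc[~b, col].mean()) / sd
            se = np.sqrt(1.0 / n_a + 4.0 / n_b)  # delta = 2 in level B
            assert abs(diff - 1.5) < 3 * se

    def test_deterministic_for_fixed_seed(self):
        c1 = simulate_feature_cohort(default_cohort_spec(seed=9))
        c2 = simulate_feature_cohort(default_cohort_spec(seed=9))
        pd.testing.assert_frame_equal(c1.features, c2.features)
        pd.testing.assert_frame_equal(c1.clinical, c2.clinical)
        pd.testing.assert_frame_equal(c1.batches, c2.batches)

    def test_tables_share_sample_ordering(self):
        coh = simulate_feature_cohort(default_cohort_spec(n_samples=50, seed=2))
        for table in (coh.batches, coh.covariates, coh.survival):
            assert list(table.index) == list(coh.features.index)
        assert set(coh.survival["event"].unique()) <= {0, 1}
        assert (coh.survival["pfs_days"] > 0).all()

    def test_starved_batch_level_rejected_by_name(self):
        spec = SyntheticSpec(
            n_samples=20, n_features=5,
            batch_defs=[BatchDef("kernel", ("soft", "lung"), (0.999, 0.001),
                                 (0.0, 1.0), (1.0, 1.0))],
            cluster_def=ClusterDef(1, (1.0,), 0.0),
            survival_def=SurvivalDef(cluster_log_hr=(0.0,)),
            seed=0,
        )
        with pytest.raises(ValueError, match="lung"):
            simulate_feature_cohort(spec)

    def test_invalid_proportions_rejected(self):
        spec = default_cohort_spec()
        spec.cluster_def = ClusterDef(2, (0.7, 0.7), 6.0)
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_feature_cohort(spec)

    def test_confounding_knob_links_cluster_and_batch(self):
        spec = default_cohort_spec(n_samples=300, seed=3)
        spec.cluster_batch_confounding = 0.9
        coh = simulate_feature_cohort(spec)
        tab = pd.crosstab(coh.cluster_truth, coh.batches["contrast"])
        _, p, *_ = stats.chi2_contingency(tab)
        assert p < 0.01


class TestSimulateSurvival:
    def test_exponential_mean_matches_rate(self):
        sdef = SurvivalDef(baseline_rate=0.01, cluster_log_hr=(0.0,),
                           censoring_window=None)
        out = simulate_survival(np.zeros(2000), sdef, seed=1)
        se = 100.0 / np.sqrt(2000)
        assert abs(out["pfs_days"].mean() - 100.0) < 3 * se

    def test_no_censoring_means_all_events(self):
        sdef = SurvivalDef(baseline_rate=0.01, cluster_log_hr=(0.0,),
                           censoring_window=None)
        out = simulate_survival(np.zeros(100), sdef, seed=2)
        assert (out["event"] == 1).all()

    def test_cox_recovers_planted_log_hazard(self):
        from radiophen.survival import fit_cox

        rng = np.random.default_rng(3)
        x = (rng.random(1000) < 0.5).astype(float)
        sdef = SurvivalDef(baseline_rate=0.005, cluster_log_hr=(0.0,),
                           censoring_window=800)
        surv = simulate_survival(x * 1.0, sdef, seed=3)
        coef, _ = fit_cox(surv, pd.DataFrame({"x": x}))
        assert coef["x"] == pytest.approx(1.0, abs=0.15)

    def test_nonfinite_predictor_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            simulate_survival(np.array([0.0, np.inf]), SurvivalDef(), seed=0)


class TestSimulateTumorVolume:
    def test_mask_volume_close_to_continuous_ellipsoid(self):
        _, msk = simulate_tumor_volume(radii=(5, 5, 5), grid_shape=(13, 13, 13))
        expected = 4.0 / 3.0 * np.pi * 125
        assert abs(msk.n_voxels - expected) / expected < 0.10

    def test_constant_texture_uniform_inside(self):
        img, msk = simulate_tumor_volume(texture="constant",
                                         grid_shape=(20, 20, 20),
                                         radii=(6, 5, 4))
        inside = img.intensities[msk.labels > 0]
        assert np.ptp(inside) == 0.0

    def test_radii_exceeding_grid_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            simulate_tumor_volume(radii=(20, 5, 5), grid_shape=(16, 16, 16))

    def test_tiny_radii_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            simulate_tumor_volume(radii=(1, 5, 5))

    def test_deterministic(self):
        a, _ = simulate_tumor_volume(seed=11)
        b, _ = simulate_tumor_volume(seed=11)
        np.testing.assert_array_equal(a.intensities, b.intensities)


class TestWriteCohort:
    def test_csv_trio_round_trips(self, tmp_path):
        coh = simulate_feature_cohort(default_cohort_spec(n_samples=30, seed=6))
        paths = write_cohort(coh, tmp_path)
        feats = pd.read_csv(paths["features"], index_col=0)
        pd.testing.assert_frame_equal(feats, coh.features)
        clin = pd.read_csv(paths["clinical"], index_col=0)
        assert {"pfs_days", "event", "pdl1_pct"} <= set(clin.columns)
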