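import numpy as np
import pandas as pd
import pytest

from radiophen.harmonization import (
    ad_significant_count,
    combat,
    drop_nonrobust,
    encode_covariates,
    nested_combat,
)
from radiophen.synthetic import simulate_feature_cohort

from conftest import single_batch_spec, two_batch_spec


def _recovered_gamma(est, cohort, level_hi="B", level_lo="A"):
    """Between-level contrast of gamma*, rescaled to true-SD units."""
    hi = est.levels.index(level_hi)
    lo = est.levels.index(level_lo)
    return (
        (est.gamma_star[hi] - est.gamma_star[lo])
        * est.sigma
        / cohort.feature_sd.values
    )


class TestCombat:
    def test_no_batch_effect_is_near_identity(self):
        spec = single_batch_spec(n=500, gamma=0.0, delta=1.0, seed=10)
        coh = simulate_feature_cohort(spec)
        adj, _ = combat(coh.features, coh.batches["batch"])
        change = (adj - coh.features).abs().mean(axis=0) / coh.feature_sd
        assert change.mean() <= 0.05

    def test_planted_parameters_recovered(self, recovery_cohort):
        coh = recovery_cohort
        adj, est = combat(coh.features, coh.batches["batch"])
        rec = _recovered_gamma(est, coh)
        assert np.abs(rec - 1.5).mean() <= 0.1
        # residual batch effect in means and variances
        b = (coh.batches["batch"] == "B").values
        mean_diff = (
            (adj[b].mean() - adj[~b].mean()).abs() / coh.feature_sd
        )
        assert mean_diff.mean() <= 0.1
        var_ratio = adj[b].var() / adj[~b].var()
        assert 0.9 <= var_ratio.mean() <= 1.1

    def test_protected_covariate_effect_preserved(self):
        spec = single_batch_spec(n=500, seed=12, feature_effect=0.8)
        coh = simulate_feature_cohort(spec)
        cov = encode_covariates(coh.covariates[["biomarker"]])
        adj, _ = combat(coh.features, coh.batches["batch"], cov)
        x = cov["biomarker"].to_numpy()
        x = (x - x.mean())
        slopes = adj.apply(lambda col: np.dot(x, col - col.mean()) / np.dot(x, x))
        planted = 0.8 * coh.feature_sd * coh.covariates["biomarker"].std(ddof=0)
        rel_err = np.abs(slopes.values / planted.values - 1.0)
        assert rel_err.mean() <= 0.10

    def test_zero_variance_feature_rejected_by_name(self, recovery_cohort):
        feats = recovery_cohort.features.copy()
        feats["feature_0001"] = 3.14
        with pytest.raises(ValueError, match="feature_0001"):
            combat(feats, recovery_cohort.batches["batch"])

    def test_eb_shrinkage_contracts_toward_prior_mean(self, recovery_cohort):
        coh = recovery_cohort
        _, est = combat(coh.features, coh.batches["batch"])
        for i in range(len(est.levels)):
            assert np.all(
                np.abs(est.gamma_star[i] - est.gamma_bar[i])
                <= np.abs(est.gamma_hat[i] - est.gamma_bar[i]) + 1e-12
            )

    def test_near_idempotent_at_large_n(self, recovery_cohort):
        coh = recovery_cohort
        once, _ = combat(coh.features, coh.batches["batch"])
        twice, _ = combat(once, coh.batches["batch"])
        change = (twice - once).abs().mean(axis=0) / coh.feature_sd
        assert change.mean() <= 0.02

    def test_sample_order_equivariance(self, recovery_cohort):
        coh = recovery_cohort
        adj, _ = combat(coh.features, coh.batches["batch"])
        perm = np.random.default_rng(0).permutation(len(coh.features))
        feats_p = coh.features.iloc[perm]
        adj_p, _ = combat(feats_p, coh.batches["batch"].iloc[perm])
        pd.testing.assert_frame_equal(adj_p, adj.iloc[perm])


class TestADCount:
    def test_null_labels_calibrated(self):
        rng = np.random.default_rng(1)
        feats = pd.DataFrame(rng.standard_normal((200, 100)))
        batch = pd.Series(rng.choice(["a", "b"], 200), index=feats.index)
        count, p = ad_significant_count(feats, batch, 0.05)
        assert 0 <= count <= 13  # binomial(100, .05) 99% band
        assert len(p) == 100

    def test_full_power_under_large_shift(self):
        rng = np.random.default_rng(2)
        feats = pd.DataFrame(rng.standard_normal((200, 100)))
        batch = pd.Series(["a"] * 100 + ["b"] * 100, index=feats.index)
        feats.iloc[100:] += 2.0
        count, _ = ad_significant_count(feats, batch, 0.05)
        assert count == 100

    def test_identical_groups_never_flagged(self):
        rng = np.random.default_rng(3)
        block = pd.DataFrame(rng.standard_normal((50, 10)))
        feats = pd.concat([block, block], ignore_index=True)
        batch = pd.Series(["a"] * 50 + ["b"] * 50, index=feats.index)
        count, p = ad_significant_count(feats, batch, 0.05)
        assert count == 0
        assert (p > 0.2).all()

    def test_small_level_falls_back_to_permutation(self):
        rng = np.random.default_rng(4)
        feats = pd.DataFrame(rng.standard_normal((24, 3)))
        batch = pd.Series(["a"] * 20 + ["b"] * 4, index=feats.index)
        with pytest.warns(UserWarning, match="permutation"):
            count, p = ad_significant_count(feats, batch, 0.05)
        assert ((p >= 0) & (p <= 1)).all()


class TestNestedCombat:
    def test_two_variables_give_two_permutations(self, two_batch_cohort):
        coh = two_batch_cohort
        _, report = nested_combat(coh.features, coh.batches)
        assert len(report.permutations) == 2
        assert set(report.permutations) == {
            ("contrast", "kernel"), ("kernel", "contrast")
        }

    def test_double_harmonization_beats_single(self, two_batch_cohort):
        coh = two_batch_cohort
        _, report = nested_combat(coh.features, coh.batches)

        def score(table):
            return sum(
                ad_significant_count(table, coh.batches[v])[0]
                for v in coh.batches.columns
            )

        singles = []
        for var in coh.batches.columns:
            adj, _ = combat(coh.features, coh.batches[var])
            singles.append(score(adj))
        assert report.selected_total <= min(singles)

    def test_single_variable_reduces_to_plain_combat(self, recovery_cohort):
        coh = recovery_cohort
        plain, _ = combat(coh.features, coh.batches["batch"])
        nested, report = nested_combat(coh.features, coh.batches[["batch"]])
        pd.testing.assert_frame_equal(nested, plain)
        assert report.permutations == [("batch",)]

    def test_pre_and_post_significant_fractions(self, two_batch_cohort):
        coh = two_batch_cohort
        d = coh.features.shape[1]
        pre = sum(
            ad_significant_count(coh.features, coh.batches[v])[0]
            for v in coh.batches.columns
        ) / (2 * d)
        harmonized, report = nested_combat(coh.features, coh.batches)
        post = report.selected_total / (2 * d)
        assert pre >= 0.9
        assert post <= 0.10


class TestDropNonrobust:
    def test_null_drop_rate_calibrated(self):
        rng = np.random.default_rng(5)
        feats = pd.DataFrame(rng.standard_normal((200, 100)))
        batches = pd.DataFrame(
            {"b": rng.choice(["x", "y"], 200)}, index=feats.index
        )
        kept, dropped = drop_nonrobust(feats, batches, 0.05)
        assert len(dropped) <= 13
        assert kept.shape[1] + len(dropped) == 100

    def test_alpha_zero_drops_nothing(self, two_batch_cohort):
        coh = two_batch_cohort
        harmonized, _ = nested_combat(coh.features, coh.batches)
        kept, dropped = drop_nonrobust(harmonized, coh.batches, alpha=0.0)
        assert dropped == []
        assert kept.shape == harmonized.shape

    def test_level_specific_bimodality_survives_combat_and_is_dropped(self):
        # a batch interaction ComBat cannot remove: level B is a +/-2
        # mixture with the same mean/variance structure ComBat matches
        rng = np.random.default_rng(6)
        n = 300
        batch = pd.Series(["A"] * 150 + ["B"] * 150)
        feats = pd.DataFrame(rng.standard_normal((n, 20)) * 0.5)
        sign = rng.choice([-2.0, 2.0], 150)
        feats.loc[150:, 0] = sign + 0.1 * rng.standard_normal(150)
        feats.columns = [f"f{i}" for i in range(20)]
        batches = pd.DataFrame({"b": batch.values}, index=feats.index)
        harmonized, _ = nested_combat(feats, batches)
        _, dropped = drop_nonrobust(harmonized, batches, 0.05)
        assert "f0" in dropped
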