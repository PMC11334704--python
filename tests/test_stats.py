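"""Rank tests, correlation, contingency, and clustered linear models."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from octavd.stats import (StatsError, chi_squared_2xk, clustered_linear_fit,
                          clustered_wilcoxon_signed_rank, mann_whitney_u,
                          multivariable_fit, outlier_sensitivity, pearson_r,
                          univariable_screen)


class TestMannWhitney:
    def test_exact_enumeration_small_example(self):
        # x entirely below y: U = 0; of the 6 assignments of 4 values
        # into groups of 2, two are at least as extreme two-sidedly.
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0
        assert res.p == pytest.approx(2 / 6)

    def test_identical_samples_give_p_one(self):
        assert mann_whitney_u([5, 6, 7], [5, 6, 7]).p == 1.0

    def test_constant_pooled_sample_degenerate(self):
        res = mann_whitney_u([4, 4], [4, 4, 4])
        assert res.p == 1.0 and "identical" in res.notes

    def test_exact_and_normal_agree_at_6_plus_6(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            x = rng.normal(0, 1, 6).round(1)  # rounding induces ties
            y = rng.normal(0.5, 1, 6).round(1)
            p_exact = mann_whitney_u(x, y, exact_n_max=12).p
            p_norm = mann_whitney_u(x, y, exact_n_max=0).p
            assert abs(p_exact - p_norm) < 0.05

    def test_large_sample_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.4, 1, 60)
        ours = mann_whitney_u(x, y).p
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic").pvalue
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(StatsError):
            mann_whitney_u([], [1.0])


class TestClusteredWilcoxon:
    def test_singleton_clusters_reduce_to_standard_wilcoxon(self):
        rng = np.random.default_rng(2)
        d = rng.normal(0.3, 1.0, 25)
        ours = clustered_wilcoxon_signed_rank(d, np.arange(25))
        ref = sps.wilcoxon(d, correction=False, method="approx",
                           zero_method="wilcox")
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_duplicated_eyes_do_not_add_evidence(self):
        # perfect within-cluster copies: the cluster-adjusted p should
        # match the single-eye-per-cluster analysis closely
        rng = np.random.default_rng(3)
        d = rng.normal(0.5, 1.0, 10)
        single = clustered_wilcoxon_signed_rank(d, np.arange(10))
        doubled = clustered_wilcoxon_signed_rank(
            np.repeat(d, 2), np.repeat(np.arange(10), 2))
        assert doubled.p == pytest.approx(single.p, abs=0.05)

    def test_matches_cluster_sign_flip_permutation_oracle(self):
        # independent oracle: enumerate all 2^G joint sign flips of
        # whole clusters and compare the tail probability of |T|
        rng = np.random.default_rng(4)
        clusters = np.repeat(np.arange(8), 2)
        d = rng.normal(0.6, 1.0, 16)
        res = clustered_wilcoxon_signed_rank(d, clusters)
        ranks = sps.rankdata(np.abs(d))
        signed = np.sign(d) * ranks
        t_obs = abs(signed.sum())
        count = 0
        for flips in itertools.product([1, -1], repeat=8):
            t = sum(flips[c] * s for c, s in zip(clusters, signed))
            if abs(t) >= t_obs - 1e-9:
                count += 1
        p_perm = count / 2 ** 8
        assert res.p == pytest.approx(p_perm, abs=0.05)

    def test_all_zero_deltas_give_p_one(self):
        res = clustered_wilcoxon_signed_rank(np.zeros(10), np.arange(10))
        assert res.p == 1.0

    def test_too_few_clusters_rejected(self):
        with pytest.raises(StatsError):
            clustered_wilcoxon_signed_rank([1.0, -2.0, 3.0],
                                           ["a", "a", "b"])


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = pearson_r(x, 2 * x + 1)
        assert res.statistic == pytest.approx(1.0)

    def test_independent_data_near_zero(self):
        rng = np.random.default_rng(5)
        res = pearson_r(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(res.statistic) < 0.1

    def test_estimator_unbiased_at_study_sample_size(self):
        # generating correlation -0.5, n = 53: mean estimate over
        # replicates within 0.05 of truth
        rng = np.random.default_rng(6)
        cov = np.array([[1.0, -0.5], [-0.5, 1.0]])
        est = [sps.pearsonr(*rng.multivariate_normal([0, 0], cov, 53).T)[0]
               for _ in range(500)]
        assert np.mean(est) == pytest.approx(-0.5, abs=0.05)

    def test_cluster_bootstrap_p_is_valid_and_deterministic(self):
        rng = np.random.default_rng(7)
        cl = np.repeat(np.arange(30), 2)
        x = rng.normal(size=60) + 0.3 * cl
        y = 0.8 * x + rng.normal(size=60)
        r1 = pearson_r(x, y, cluster_ids=cl, seed=11)
        r2 = pearson_r(x, y, cluster_ids=cl, seed=11)
        assert r1.p == r2.p and r1.p < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestChiSquared:
    def test_homogeneous_table_gives_zero_statistic(self):
        res = chi_squared_2xk(np.array([[10, 10], [10, 10]]))
        assert res.statistic == 0.0 and res.p == 1.0

    def test_perfect_separation(self):
        res = chi_squared_2xk(np.array([[20, 0], [0, 20]]))
        assert res.statistic == pytest.approx(40.0)
        assert "df=1" in res.notes

    def test_hand_computed_example(self):
        res = chi_squared_2xk(np.array([[5, 15], [15, 5]]))
        assert res.statistic == pytest.approx(10.0)
        assert res.p == pytest.approx(0.001565, abs=2e-5)

    def test_zero_margin_rejected(self):
        with pytest.raises(StatsError):
            chi_squared_2xk(np.array([[0, 10], [0, 20]]))


def _bcr_like_frame(rng, n_pat=28, n_eyes=53, beta_age=0.0, sd=6.0, rho=0.5):
    n_two = n_eyes - n_pat
    pat = np.concatenate([np.repeat(np.arange(n_two), 2),
                          np.arange(n_two, n_pat)])
    age = rng.uniform(30, 80, n_pat)[pat]
    b = rng.standard_normal(n_pat)[pat]
    e = rng.standard_normal(n_eyes)
    y = 30 + beta_age * (age - 55) + sd * (np.sqrt(rho) * b
                                           + np.sqrt(1 - rho) * e)
    return pd.DataFrame({"patient_id": pat, "age": age, "y": y,
                         "cst_um": rng.normal(260, 30, n_eyes),
                         "noise": rng.normal(size=n_eyes)})


class TestClusteredLinearFit:
    def test_singleton_clusters_equal_ols_with_robust_se(self):
        rng = np.random.default_rng(8)
        n = 80
        df = pd.DataFrame({"patient_id": np.arange(n),
                           "x1": rng.normal(size=n),
                           "x2": rng.normal(size=n)})
        df["y"] = 1 + 2 * df.x1 - 0.5 * df.x2 + rng.normal(size=n)
        fit = clustered_linear_fit(df, "y", ["x1", "x2"])
        X = sm.add_constant(df[["x1", "x2"]])
        # With one observation per cluster the bias-reduced (Mancl-DeRouen)
        # sandwich reduces exactly to the HC3 heteroskedasticity correction.
        ols = sm.OLS(df["y"], X).fit(cov_type="HC3")
        np.testing.assert_allclose(fit.table["estimate"],
                                   ols.params[["x1", "x2"]], atol=1e-8)
        np.testing.assert_allclose(fit.table["se"],
                                   ols.bse[["x1", "x2"]], atol=1e-8)

    def test_noiseless_linear_outcome_recovered_exactly(self):
        rng = np.random.default_rng(9)
        df = _bcr_like_frame(rng)
        df["y"] = 5.0 - 0.25 * df["age"] + 0.01 * df["cst_um"]
        fit = clustered_linear_fit(df, "y", ["age", "cst_um"])
        assert fit.table.loc["age", "estimate"] == pytest.approx(-0.25,
                                                                 abs=1e-10)
        assert fit.table.loc["cst_um", "estimate"] == pytest.approx(0.01,
                                                                    abs=1e-10)

    def test_rank_deficiency_names_collinear_covariates(self):
        rng = np.random.default_rng(10)
        df = _bcr_like_frame(rng)
        df["age_copy"] = df["age"]
        with pytest.raises(StatsError, match="age"):
            clustered_linear_fit(df, "y", ["age", "age_copy"])

    def test_reports_cluster_counts(self):
        rng = np.random.default_rng(11)
        fit = clustered_linear_fit(_bcr_like_frame(rng), "y", ["age"])
        assert fit.n_eyes == 53 and fit.n_patients == 28


class TestScreenAndMultivariable:
    def test_strong_effect_always_retained(self):
        rng = np.random.default_rng(12)
        retained_count = 0
        for _ in range(20):
            df = _bcr_like_frame(rng, beta_age=-0.5, sd=3.0)
            retained, _ = univariable_screen(df, "y", ["age", "noise"])
            retained_count += "age" in retained
        assert retained_count == 20

    def test_pure_noise_covariate_retained_near_alpha_rate(self):
        rng = np.random.default_rng(13)
        kept = 0
        n_rep = 300
        for _ in range(n_rep):
            df = _bcr_like_frame(rng)
            retained, _ = univariable_screen(df, "y", ["noise"], alpha=0.10)
            kept += "noise" in retained
        assert 0.05 < kept / n_rep < 0.16

    def test_single_retained_covariate_reduces_to_univariable(self):
        rng = np.random.default_rng(14)
        df = _bcr_like_frame(rng, beta_age=-0.4)
        multi = multivariable_fit(df, "y", ["age"])
        uni = clustered_linear_fit(df, "y", ["age"])
        assert multi.table.loc["age", "estimate"] == pytest.approx(
            uni.table.loc["age", "estimate"], abs=1e-12)
        assert multi.table.loc["age", "p"] == pytest.approx(
            uni.table.loc["age", "p"], abs=1e-12)

    def test_empty_retained_list_rejected_with_note(self):
        rng = np.random.default_rng(15)
        with pytest.raises(StatsError, match="not applicable"):
            multivariable_fit(_bcr_like_frame(rng), "y", [])

    def test_screen_records_model_failures_per_candidate(self):
        rng = np.random.default_rng(16)
        df = _bcr_like_frame(rng)
        df["flat"] = 1.0
        retained, table = univariable_screen(df, "y", ["age", "flat"])
        row = table[table.covariate == "flat"].iloc[0]
        assert row["error"] != "" and not row["retained"]


class TestOutlierSensitivity:
    def test_clean_data_rarely_flagged_and_results_stable(self):
        # |studentized residual| > 3 is rare under the model (<~0.5% per
        # point), so clean data should yield almost no flags, and whenever
        # none occur the trimmed result must be the full result.
        rng = np.random.default_rng(17)
        n_flags = n_points = 0
        for _ in range(50):
            x = rng.normal(size=50)
            y = 0.6 * x + rng.normal(scale=0.5, size=50)
            full, trimmed, flags = outlier_sensitivity(x, y)
            n_flags += int(flags.sum())
            n_points += flags.size
            if not flags.any():
                assert full.statistic == trimmed.statistic
            else:  # a chance flag must not move the correlation much
                assert abs(full.statistic - trimmed.statistic) < 0.1
        assert n_flags / n_points < 0.02

    def test_gross_outlier_flagged_and_correlation_restored(self):
        rng = np.random.default_rng(18)
        x = rng.normal(size=50)
        y = 0.9 * x + rng.normal(scale=0.3, size=50)
        y[7] += 15.0  # gross contamination
        full, trimmed, flags = outlier_sensitivity(x, y)
        assert flags[7]
        assert abs(trimmed.statistic - 0.9) < abs(full.statistic - 0.9)

    def test_collinear_data_has_no_flags(self):
        x = np.arange(10.0)
        full, trimmed, flags = outlier_sensitivity(x, 3 * x - 2)
        assert full.statistic == pytest.approx(1.0)
        assert trimmed.statistic == pytest.approx(1.0)
        assert not flags.any()
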