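"""Two-sample MR estimators and the per-variant association scan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from refluxmr import (
    TwoSampleMR,
    egger,
    gwas_scan,
    ivw,
    make_summary_stats,
    wald_ratio,
    weighted_median,
)


class TestWaldRatio:
    def test_direct_division(self):
        est, se = wald_ratio(0.1, 0.02, 0.01)
        assert est == pytest.approx(0.2)
        assert se == pytest.approx(0.1)

    def test_zero_outcome_beta(self):
        est, _ = wald_ratio(0.1, 0.0, 0.01)
        assert est == 0.0

    def test_delta_method_se(self):
        # first-order delta: se = se_y / |beta_x|, independent of beta_y
        _, se = wald_ratio(-0.25, 0.07, 0.02)
        assert se == pytest.approx(0.02 / 0.25)

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.1, 0.01)


class TestIVW:
    def test_perfect_homogeneity_recovers_ratio_with_zero_q(self):
        bx = np.array([0.05, 0.1, 0.2, 0.4])
        st_ = pd.DataFrame({"beta_x": bx, "beta_y": 0.3 * bx,
                            "se_y": [0.01, 0.03, 0.02, 0.05]})
        res = ivw(st_)
        assert res.estimate == pytest.approx(0.3)
        assert res.q_statistic == pytest.approx(0.0, abs=1e-20)
        assert res.effects == "fixed"

    def test_single_variant_reduces_to_wald_ratio(self):
        st_ = pd.DataFrame({"beta_x": [0.1], "beta_y": [0.02],
                            "se_y": [0.01]})
        res = ivw(st_)
        w_est, w_se = wald_ratio(0.1, 0.02, 0.01)
        assert res.estimate == pytest.approx(w_est)
        assert res.se == pytest.approx(w_se)
        assert "single variant" in res.note

    def test_matches_direct_summation_oracle(self, summary_fixture):
        res = ivw(summary_fixture, effects="fixed")
        w = summary_fixture["beta_x"] ** 2 / summary_fixture["se_y"] ** 2
        ratios = summary_fixture["beta_y"] / summary_fixture["beta_x"]
        oracle_est = float((w * ratios).sum() / w.sum())
        oracle_se = float(1 / np.sqrt(w.sum()))
        oracle_q = float((w * (ratios - oracle_est) ** 2).sum())
        assert res.estimate == pytest.approx(oracle_est, rel=1e-10)
        assert res.se == pytest.approx(oracle_se, rel=1e-10)
        assert res.q_statistic == pytest.approx(oracle_q, rel=1e-10)

    def test_random_effects_inflates_se_only_under_heterogeneity(self):
        bx = np.array([0.1, 0.1, 0.1, 0.1])
        st_ = pd.DataFrame({"beta_x": bx,
                            "beta_y": [0.01, 0.2, -0.15, 0.05],
                            "se_y": [0.01] * 4})
        fixed = ivw(st_, effects="fixed")
        random = ivw(st_, effects="random")
        assert random.se > fixed.se
        assert random.se == pytest.approx(
            fixed.se * np.sqrt(fixed.q_statistic / 3))
        # homogeneous data: scale factor clamps at 1
        st_h = pd.DataFrame({"beta_x": bx, "beta_y": 0.2 * bx,
                             "se_y": [0.01] * 4})
        assert ivw(st_h, effects="random").se == pytest.approx(
            ivw(st_h, effects="fixed").se)

    def test_all_zero_beta_x_rejected(self):
        st_ = pd.DataFrame({"beta_x": [0.0, 0.0], "beta_y": [0.1, 0.2],
                            "se_y": [0.1, 0.1]})
        with pytest.raises(ValueError):
            ivw(st_)


class TestEgger:
    def test_exact_line_through_origin(self, summary_fixture):
        stats = summary_fixture.copy()
        stats["beta_y"] = 0.25 * stats["beta_x"]
        res = egger(stats)
        assert res.estimate == pytest.approx(0.25, abs=1e-10)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)

    def test_constant_offset_recovered_in_intercept(self, summary_fixture):
        stats = summary_fixture.copy()
        stats["beta_y"] = 0.25 * stats["beta_x"] + 0.04
        res = egger(stats)
        assert res.intercept == pytest.approx(0.04, abs=1e-10)
        assert res.estimate == pytest.approx(0.25, abs=1e-10)

    def test_orientation_flip_invariance(self, summary_fixture):
        stats = summary_fixture.copy()
        flipped = stats.copy()
        flipped.loc[0, ["beta_x", "beta_y"]] *= -1
        a, b = egger(stats), egger(flipped)
        assert a.estimate == pytest.approx(b.estimate)
        assert a.intercept == pytest.approx(b.intercept)

    def test_fewer_than_three_variants_rejected(self):
        st_ = pd.DataFrame({"beta_x": [0.1, 0.2], "beta_y": [0.01, 0.02],
                            "se_y": [0.01, 0.01]})
        with pytest.raises(ValueError):
            egger(st_)


class TestWeightedMedian:
    def test_identical_ratios_returned_regardless_of_weights(self):
        st_ = pd.DataFrame({"beta_x": [0.1, 0.2, 0.4],
                            "beta_y": [0.03, 0.06, 0.12],
                            "se_y": [0.01, 0.05, 0.02]})
        res = weighted_median(st_, bootstrap_B=50, seed=0)
        assert res.estimate == pytest.approx(0.3)

    def test_equal_weights_odd_k_equals_simple_median(self):
        st_ = pd.DataFrame({"beta_x": [1.0, 1.0, 1.0, 1.0, 1.0],
                            "beta_y": [0.5, 0.1, 0.3, 0.9, 0.2],
                            "se_y": [1.0] * 5})
        res = weighted_median(st_, bootstrap_B=50, seed=0)
        assert res.estimate == pytest.approx(np.median(st_["beta_y"]))

    def test_bootstrap_seeded_reproducible(self, summary_fixture):
        a = weighted_median(summary_fixture, bootstrap_B=200, seed=5)
        b = weighted_median(summary_fixture, bootstrap_B=200, seed=5)
        assert a.se == b.se

    def test_resists_minority_pleiotropy_better_than_ivw(self):
        """40% of variants given a large directional outcome offset:
        weighted-median bias stays well below IVW bias (mean over
        replicates)."""
        rng = np.random.default_rng(14)
        truth = 0.2
        biases_ivw, biases_wm = [], []
        for _ in range(200):
            k = 15
            bx = rng.uniform(0.05, 0.3, k)
            sey = rng.uniform(0.005, 0.02, k)
            by = truth * bx + rng.normal(0, sey)
            bad = rng.choice(k, 6, replace=False)   # 40% invalid
            by[bad] += 0.3
            st_ = pd.DataFrame({"beta_x": bx, "se_x": np.full(k, 1e-4),
                                "beta_y": by, "se_y": sey})
            biases_ivw.append(ivw(st_).estimate - truth)
            biases_wm.append(
                weighted_median(st_, bootstrap_B=20, seed=1).estimate - truth)
        ratio = abs(np.mean(biases_wm)) / abs(np.mean(biases_ivw))
        assert ratio < 0.5


class TestSignFlipInvariance:
    @given(st.integers(0, 4))
    @settings(max_examples=5, deadline=None)
    def test_simultaneous_sign_flip_leaves_all_estimators(self, idx):
        rng = np.random.default_rng(15)
        k = 5
        stats = pd.DataFrame({
            "variant_id": [f"v{i}" for i in range(k)],
            "beta_x": rng.uniform(0.05, 0.3, k),
            "se_x": np.full(k, 0.01),
            "beta_y": rng.normal(0.05, 0.02, k),
            "se_y": rng.uniform(0.005, 0.02, k)})
        flipped = stats.copy()
        flipped.loc[idx, ["beta_x", "beta_y"]] *= -1
        assert ivw(stats).estimate == pytest.approx(ivw(flipped).estimate)
        assert egger(stats).estimate == pytest.approx(egger(flipped).estimate)
        assert weighted_median(stats, 50, 3).estimate == pytest.approx(
            weighted_median(flipped, 50, 3).estimate)


class TestModelClass:
    def test_fit_all_and_summary(self, summary_fixture):
        model = TwoSampleMR(summary_fixture, design="one-cohort")
        fits = model.fit_all(seed=2)
        assert set(fits) == {"ivw", "egger", "weighted_median"}
        text = model.summary(seed=2)
        assert "IVW" in text and "design" not in text
        assert all("one-cohort" in f.note for f in fits.values())

    def test_invalid_design_rejected(self, summary_fixture):
        with pytest.raises(ValueError):
            TwoSampleMR(summary_fixture, design="overlapping")


class TestGwasScan:
    def test_vectorised_logistic_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(16)
        n = 3000
        g = rng.binomial(2, 0.3, size=(n, 3)).astype(float)
        eta = -2 + 0.3 * g[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        scan = gwas_scan(g, y, trait_type="binary")
        for j in range(3):
            fit = sm.Logit(y, sm.add_constant(g[:, j])).fit(disp=0)
            assert scan.loc[j, "beta"] == pytest.approx(fit.params[1], abs=1e-6)
            assert scan.loc[j, "se"] == pytest.approx(fit.bse[1], abs=1e-6)

    def test_linear_scan_recovers_generative_slope(self):
        rng = np.random.default_rng(17)
        n = 5000
        g = rng.binomial(2, 0.4, size=(n, 1)).astype(float)
        y = 0.2 * g[:, 0] + rng.standard_normal(n)
        scan = gwas_scan(g, y, trait_type="continuous")
        assert abs(scan.loc[0, "beta"] - 0.2) < 3 * scan.loc[0, "se"]

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(18)
        g = rng.binomial(2, 0.3, size=(800, 500)).astype(float)
        y = rng.standard_normal(800)
        scan = gwas_scan(g, y, trait_type="continuous")
        assert kstest(scan["p"], "uniform").pvalue > 0.01

    def test_monomorphic_variant_dropped(self):
        rng = np.random.default_rng(19)
        g = np.column_stack([np.zeros(200), rng.binomial(2, 0.3, 200)])
        y = rng.standard_normal(200)
        scan = gwas_scan(g, y, variant_ids=["mono", "ok"])
        assert scan["variant_id"].tolist() == ["ok"]

    def test_covariate_path_agrees_with_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(20)
        n = 1500
        g = rng.binomial(2, 0.3, size=(n, 2)).astype(float)
        cov = rng.normal(size=(n, 1))
        y = 0.1 * g[:, 0] + 0.5 * cov[:, 0] + rng.standard_normal(n)
        scan = gwas_scan(g, y, covariates=cov, trait_type="continuous")
        fit = sm.OLS(y, sm.add_constant(np.column_stack([g[:, 0], cov]))).fit()
        assert scan.loc[0, "beta"] == pytest.approx(fit.params[1], rel=1e-9)

    def test_scan_deterministic(self):
        rng = np.random.default_rng(21)
        g = rng.binomial(2, 0.3, size=(400, 5)).astype(float)
        y = (rng.random(400) < 0.2).astype(float)
        a = gwas_scan(g, y, trait_type="binary")
        b = gwas_scan(g, y, trait_type="binary")
        pd.testing.assert_frame_equal(a, b)

    def test_make_summary_stats_merges_on_variant(self):
        sx = pd.DataFrame({"variant_id": ["a", "b"], "beta_x": [0.1, 0.2],
                           "se_x": [0.01, 0.01], "p_x": [0.1, 0.2]})
        sy = pd.DataFrame({"variant_id": ["b", "a"], "beta_y": [0.02, 0.01],
                           "se_y": [0.01, 0.01], "p_y": [0.3, 0.4]})
        merged = make_summary_stats(sx, sy)
        assert merged.loc[merged["variant_id"] == "b", "beta_y"].item() == 0.02
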