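"""One-sample MR: two-stage IV, per-unit rescaling, power formula."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refluxmr import (
    TwoStageIV,
    logistic_assoc,
    mr_power,
    rescale_per_unit,
    two_stage_iv,
)


def simulate_iv_data(n=8000, beta=0.3, seed=0):
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, 0.3, size=n).astype(float) \
        + rng.binomial(2, 0.4, size=n)
    u = rng.standard_normal(n)
    x = 0.15 * g + 0.4 * u + rng.standard_normal(n)
    eta = -2.4 + beta * (x - x.mean()) / x.std() + 0.4 * u
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return g, x, y


class TestTwoStageIV:
    def test_ratio_equivalence_covariate_free(self):
        """Two-stage estimate equals (score->outcome logit coef) /
        (score->exposure linear coef) without covariates."""
        g, x, y = simulate_iv_data(seed=1)
        res = two_stage_iv(g, x, y)
        import statsmodels.api as sm
        from refluxmr import inverse_normal

        num = logistic_assoc(y, g).estimate
        den = float(sm.OLS(inverse_normal(x), sm.add_constant(g)).fit().params[1])
        assert res.estimate == pytest.approx(num / den, abs=1e-4)

    def test_affine_rescaling_of_score_leaves_estimate(self):
        g, x, y = simulate_iv_data(seed=2)
        base = two_stage_iv(g, x, y)
        shifted = two_stage_iv(7.5 * g - 3.0, x, y)
        assert shifted.estimate == pytest.approx(base.estimate, rel=1e-6)
        assert shifted.se == pytest.approx(base.se, rel=1e-6)

    def test_null_outcome_ci_covers_zero(self):
        rng = np.random.default_rng(1003)  # independent of the IV stream
        g, x, _ = simulate_iv_data(seed=3)
        y = (rng.random(len(g)) < 0.1).astype(float)
        res = two_stage_iv(g, x, y)
        lo, hi = res.ci95
        assert lo < 0 < hi

    def test_covariates_enter_both_stages(self):
        g, x, y = simulate_iv_data(seed=4)
        cov = np.random.default_rng(4).normal(size=(len(g), 2))
        res = TwoStageIV(y, x, g, cov).fit()
        assert np.isfinite(res.estimate)
        assert res.stage1["F"] > 10

    def test_from_dataframe_constructor(self):
        g, x, y = simulate_iv_data(n=2000, seed=5)
        df = pd.DataFrame({"grs": g, "exp": x, "gord": y,
                           "age": np.random.default_rng(5).uniform(40, 70, 2000)})
        res = TwoStageIV.from_dataframe(
            df, outcome="gord", exposure="exp", score="grs",
            covariates=["age"]).fit()
        assert np.isfinite(res.estimate)
        assert "two-stage" in res.summary()

    def test_bootstrap_se_close_to_analytic(self):
        g, x, y = simulate_iv_data(n=4000, seed=6)
        res = TwoStageIV(y, x, g).fit(bootstrap_B=60, seed=1)
        assert res.bootstrap_se is not None
        assert 0.5 * res.se < res.bootstrap_se < 2.0 * res.se

    def test_constant_instrument_rejected(self):
        _, x, y = simulate_iv_data(n=500, seed=7)
        with pytest.raises(ValueError):
            TwoStageIV(y, x, np.ones(500))

    def test_non_binary_outcome_rejected(self):
        g, x, _ = simulate_iv_data(n=500, seed=8)
        with pytest.raises(ValueError):
            TwoStageIV(x, x, g)

    def test_weak_instrument_warning(self):
        rng = np.random.default_rng(9)
        n = 1000
        g = rng.binomial(2, 0.3, n).astype(float)
        x = rng.standard_normal(n)  # score explains nothing
        y = (rng.random(n) < 0.2).astype(float)
        with pytest.warns(UserWarning, match="weak"):
            TwoStageIV(y, x, g).fit()


class TestRescalePerUnit:
    def test_waist_circumference_conversion(self):
        assert round(rescale_per_unit(1.19, 4.2, 5.0), 2) == 1.23

    def test_identity_and_unit_or(self):
        assert rescale_per_unit(1.19, 4.2, 4.2) == pytest.approx(1.19)
        assert rescale_per_unit(1.0, 3.0, 17.0) == pytest.approx(1.0)

    @given(st.floats(0.5, 2.0), st.floats(0.5, 10.0), st.floats(0.5, 10.0),
           st.floats(0.5, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_rescaling_composes(self, orx, s, u, v):
        via_u = rescale_per_unit(rescale_per_unit(orx, s, u), u, v)
        direct = rescale_per_unit(orx, s, v)
        assert via_u == pytest.approx(direct, rel=1e-9)

    def test_nonpositive_inputs_rejected(self):
        for args in [(0.0, 4.2, 5.0), (1.2, 0.0, 5.0), (1.2, 4.2, -1.0)]:
            with pytest.raises(ValueError):
                rescale_per_unit(*args)


class TestMrPower:
    def test_null_or_gives_alpha(self):
        assert mr_power(50_000, 0.02, 1.0, 0.09) == pytest.approx(0.05)
        assert mr_power(50_000, 0.0, 1.3, 0.09) == pytest.approx(0.05)

    def test_power_tends_to_one(self):
        assert mr_power(1e9, 0.02, 1.2, 0.09) > 0.999

    def test_monotone_in_n_r2_effect_and_balance(self):
        base = mr_power(10_000, 0.02, 1.3, 0.09)
        assert mr_power(20_000, 0.02, 1.3, 0.09) >= base
        assert mr_power(10_000, 0.04, 1.3, 0.09) >= base
        assert mr_power(10_000, 0.02, 1.5, 0.09) >= base
        assert mr_power(10_000, 0.02, 1.3, 0.5) >= base
        # protective effects mirror risk effects
        assert mr_power(10_000, 0.02, 1 / 1.3, 0.09) == pytest.approx(base)

    def test_invalid_arguments_rejected(self):
        for args in [(0, 0.02, 1.3, 0.09), (1e4, -0.1, 1.3, 0.09),
                     (1e4, 0.02, -1.0, 0.09), (1e4, 0.02, 1.3, 1.5)]:
            with pytest.raises(ValueError):
                mr_power(*args)
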