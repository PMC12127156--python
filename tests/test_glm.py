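"""Weighted GLM: closed-form oracles, reductions to classical fits,
robust-variance cross-checks and frequentist calibration."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from dietscore.glm import (
    ModelSpec,
    SeparationError,
    SurveyGLM,
    build_design_matrix,
    fit_model,
    tertile_contrasts,
)
from dietscore.survey import SurveyDesign


def _toy_2x2():
    """Exposed: 30/100 events; unexposed: 15/100.  OR = (30*85)/(70*15)."""
    y = np.r_[np.ones(30), np.zeros(70), np.ones(15), np.zeros(85)]
    x = np.r_[np.ones(100), np.zeros(100)]
    return y, x


class TestLogistic:
    def test_2x2_closed_form_or(self):
        y, x = _toy_2x2()
        X = np.column_stack([np.ones(200), x])
        res = SurveyGLM(y, X, SurveyDesign(np.ones(200)), family="binomial").fit()
        assert np.exp(res.params.iloc[1]) == pytest.approx((30 * 85) / (70 * 15), rel=1e-8)
        assert np.exp(res.params.iloc[1]) == pytest.approx(2.4286, abs=1e-4)

    def test_equal_weights_match_statsmodels(self, rng):
        n = 300
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-X @ [0.2, 0.7, -0.4]))).astype(float)
        mine = SurveyGLM(y, X, SurveyDesign(np.ones(n)), family="binomial").fit()
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(mine.params.to_numpy(), ref.params, atol=1e-8)

    def test_weight_scale_invariance(self, rng):
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = (rng.uniform(size=n) < 0.3).astype(float)
        w = rng.gamma(4, 0.25, n)
        r1 = SurveyGLM(y, X, SurveyDesign(w), family="binomial").fit()
        r2 = SurveyGLM(y, X, SurveyDesign(3.0 * w), family="binomial").fit()
        np.testing.assert_allclose(r1.params, r2.params, atol=1e-10)
        np.testing.assert_allclose(r1.bse, r2.bse, atol=1e-10)

    def test_separation_detected(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        X = np.column_stack([np.ones(40), x])
        with pytest.raises((SeparationError, Exception)):
            SurveyGLM(y, X, SurveyDesign(np.ones(40)), family="binomial").fit()

    def test_nonbinary_outcome_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            SurveyGLM(
                np.array([0.0, 0.5, 1.0]),
                np.ones((3, 1)),
                SurveyDesign(np.ones(3)),
                family="binomial",
            )


class TestLinear:
    def test_equal_weights_are_ols(self, rng):
        n = 150
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = X @ [1.0, 2.0, -0.5] + rng.normal(size=n)
        mine = SurveyGLM(y, X, SurveyDesign(np.ones(n)), family="gaussian").fit()
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(mine.params.to_numpy(), ref.params, atol=1e-8)

    def test_slope_recovery(self, rng):
        n = 20000
        x = rng.normal(size=n)
        y = 2.0 * x + rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        res = SurveyGLM(y, X, SurveyDesign(rng.gamma(4, 0.25, n)), family="gaussian").fit()
        assert res.params.iloc[1] == pytest.approx(2.0, abs=0.05)

    def test_frequency_weight_point_estimates(self, rng):
        # one obs with weight 2 == the same obs twice with weight 1
        x = rng.normal(size=20)
        y = 1.0 + 0.5 * x + rng.normal(size=20)
        X = np.column_stack([np.ones(20), x])
        w = np.ones(20)
        w[0] = 2.0
        dup = SurveyGLM(
            np.r_[y, y[0]],
            np.vstack([X, X[:1]]),
            SurveyDesign(np.ones(21)),
            family="gaussian",
        ).fit()
        wtd = SurveyGLM(y, X, SurveyDesign(w), family="gaussian").fit()
        np.testing.assert_allclose(wtd.params, dup.params, atol=1e-10)

    def test_robust_cov_matches_wls_sandwiches(self, rng):
        """The survey sandwich coincides with the WLS heteroscedasticity-
        robust covariances: HC3 for the default leverage-adjusted form,
        HC0 for the plain form."""
        n = 250
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = X @ [1.0, 2.0, -1.0] + rng.normal(size=n) * (1 + 0.5 * np.abs(X[:, 1]))
        w = rng.gamma(4, 0.25, n)
        model = SurveyGLM(y, X, SurveyDesign(w), family="gaussian")
        ref = sm.WLS(y, X, weights=w).fit()
        np.testing.assert_allclose(
            model.fit().cov_params.to_numpy(), ref.cov_HC3, atol=1e-10
        )
        np.testing.assert_allclose(
            model.fit(cov_type="robust_hc1").cov_params.to_numpy() * (n - 3) / n,
            ref.cov_HC0,
            atol=1e-10,
        )

    def test_rank_deficiency_raises(self, rng):
        n = 50
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2.0 * x])
        with pytest.raises(Exception):
            SurveyGLM(x, X, SurveyDesign(np.ones(n)), family="gaussian").fit()


class TestCoverage:
    def test_ci_coverage_both_families(self, rng):
        """Nominal 95% Wald CIs cover the truth 93-97% of the time."""
        n, reps = 300, 1000
        beta = 0.5
        cover = {"gaussian": 0, "binomial": 0}
        for _ in range(reps):
            x = rng.normal(size=n)
            w = rng.gamma(4, 0.25, n)
            X = np.column_stack([np.ones(n), x])
            yg = 1.0 + beta * x + rng.normal(size=n)
            res = SurveyGLM(yg, X, SurveyDesign(w), family="gaussian").fit()
            lo, hi = res.conf_int().iloc[1]
            cover["gaussian"] += lo <= beta <= hi
            p = 1 / (1 + np.exp(-(-0.5 + beta * x)))
            yb = (rng.uniform(size=n) < p).astype(float)
            res = SurveyGLM(yb, X, SurveyDesign(w), family="binomial").fit()
            lo, hi = res.conf_int().iloc[1]
            cover["binomial"] += lo <= beta <= hi
        for fam, c in cover.items():
            assert 0.93 <= c / reps <= 0.97, (fam, c / reps)


class TestModelSpecAndContrasts:
    def test_design_matrix_dummy_coding(self):
        df = pd.DataFrame(
            {"x": [1.0, 2.0], "g": pd.Categorical(["a", "b"], categories=["a", "b"])}
        )
        X = build_design_matrix(df, ["x", "g"])
        assert list(X.columns) == ["Intercept", "x", "g[b]"]

    def test_empty_exposure_level_rejected(self, rng):
        n = 60
        df = pd.DataFrame(
            {
                "y": rng.integers(0, 2, n).astype(float),
                "g": pd.Categorical(["T1"] * 30 + ["T2"] * 30, categories=["T1", "T2", "T3"]),
            }
        )
        with pytest.raises(ValueError, match="empty exposure"):
            fit_model(
                ModelSpec("y", "binomial", "g", None), df, SurveyDesign(np.ones(n))
            )

    def test_tertile_contrasts_recover_planted_log_or(self, rng):
        n = 6000
        tert = pd.Categorical(
            rng.choice(["T1", "T2", "T3"], n), categories=["T1", "T2", "T3"]
        )
        logit = -1.5 + 0.62 * (tert == "T3") + 0.2 * (tert == "T2")
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(float)
        df = pd.DataFrame({"y": y, "tert": tert})
        res = fit_model(
            ModelSpec("y", "binomial", "tert", None), df, SurveyDesign(np.ones(n))
        )
        tab = tertile_contrasts(res, "tert")
        assert tab.loc[0, "estimate"] == 1.0  # reference
        t3 = tab.set_index("level").loc["T3"]
        assert t3["ci_low"] <= np.exp(0.62) <= t3["ci_high"]

    def test_covariate_sets_resolve(self):
        assert "homa_ir" in ModelSpec("y", "binomial", "x", "extended").covariates()
        assert ModelSpec("y", "binomial", "x", None).covariates() == ()
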