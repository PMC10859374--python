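import dataclasses
from types import SimpleNamespace

import numpy as np
import pytest
from scipy import special

from pollenlag import (
    LagSurfaceSpec,
    ModelSpec,
    PoissonDLNM,
    SimulationConfig,
    compare_aic,
    generate,
    pacf,
    select_time_df,
)
from pollenlag.model import _irls

from conftest import make_series
from oracles import pacf_ols_oracle, poisson_mle_oracle


class TestIRLS:
    def test_intercept_only_matches_poisson_mle_mean(self):
        y = np.array([1, 2, 3])
        X = np.ones((3, 1))
        beta, cov, mu, dev, llf, resid, converged, clipped, _ = _irls(X, y)
        assert converged and not clipped
        assert np.allclose(beta, np.log(2.0), atol=1e-10)
        assert np.allclose(mu, 2.0, atol=1e-9)
        # AIC by definition: -2 sum[y log 2 - 2 - log y!] + 2
        aic = -2 * llf + 2
        expected = -2 * np.sum(y * np.log(2.0) - 2.0 - special.gammaln(y + 1)) + 2
        assert np.isclose(aic, expected, atol=1e-10)

    def test_matches_generic_likelihood_oracle_small_fixture(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-1, 1, 12)
        y = rng.poisson(np.exp(1.0 + 0.5 * x))
        X = np.column_stack([np.ones(12), x])
        beta, *_ = _irls(X, y)
        oracle = poisson_mle_oracle(X, y)
        assert np.allclose(beta, oracle, atol=1e-8)

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        X = np.column_stack([np.ones(60), rng.normal(size=60), rng.uniform(size=60)])
        y = rng.poisson(np.exp(0.8 + 0.3 * X[:, 1] - 0.5 * X[:, 2]))
        beta, cov, *_ = _irls(X, y)
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert np.allclose(beta, glm.params, atol=1e-8)
        # statsmodels stops at a looser deviance tolerance, so its Fisher
        # information is evaluated at a slightly different beta
        assert np.allclose(cov, glm.cov_params(), rtol=1e-4)

    def test_full_model_reproduces_oracle(self):
        cfg = SimulationConfig(n_days=80, seed=21, truth_surface=LagSurfaceSpec(max_lag=5))
        series, _ = generate(cfg)
        spec = ModelSpec(df_exposure=2, df_lag=2, max_lag=5, time_df=3,
                         covariate_names=("temperature",), include_dow=False,
                         include_holiday=False)
        res = PoissonDLNM(series, spec).fit()
        assert len(res.params) <= 20
        from pollenlag.model import _Design

        design = _Design(series, spec, 3)
        oracle = poisson_mle_oracle(design.X, design.y, beta0=res.params)
        assert np.allclose(res.params, oracle, atol=1e-8)

    def test_fitted_totals_conserved_with_intercept(self, fitted):
        assert np.isclose(fitted.fittedvalues.sum(), fitted.response.sum(), rtol=1e-8)

    def test_covariance_psd_and_ses_positive(self, fitted):
        eig = np.linalg.eigvalsh(fitted.cov_params)
        assert eig.min() > -1e-8 * max(1.0, eig.max())
        assert (fitted.bse > 0).all()

    def test_score_equations_hold_at_convergence(self, fitted):
        from pollenlag.model import _Design

        design = _Design(fitted.model.series, fitted.model.spec, fitted.time_df)
        grad = design.X.T @ (design.y - fitted.fittedvalues)
        assert np.max(np.abs(grad)) < 1e-6

    def test_rank_deficiency_reports_columns(self, default_sim):
        series, _ = default_sim
        frame = series.frame.copy()
        frame["dew"] = frame["temperature"]  # duplicated block
        with pytest.raises(ValueError, match="rank deficient.*offending"):
            PoissonDLNM.from_dataframe(frame, ModelSpec(time_df=4)).fit()


class TestPACF:
    def test_white_noise_stays_in_band(self):
        rng = np.random.default_rng(123)
        x = rng.normal(size=2000)
        p = pacf(x, 30)
        assert np.sum(np.abs(p) < 2 / np.sqrt(2000)) >= 27

    def test_ar1_truncation(self):
        rng = np.random.default_rng(5)
        n = 5000
        x = np.zeros(n)
        eps = rng.normal(size=n)
        for t in range(1, n):
            x[t] = 0.5 * x[t - 1] + eps[t]
        p = pacf(x, 10)
        assert abs(p[0] - 0.5) < 0.05
        assert np.all(np.abs(p[1:]) < 0.05)

    def test_matches_successive_regression_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=12)
        assert np.allclose(pacf(x, 5), pacf_ols_oracle(x, 5), atol=1e-10)

    def test_errors(self):
        with pytest.raises(ValueError, match="constant"):
            pacf(np.full(100, 3.0), 10)
        with pytest.raises(ValueError, match="max_lag"):
            pacf(np.arange(20.0), 10)


class TestSelectTimeDF:
    def test_returned_df_minimizes_score_table(self, default_sim):
        series, _ = default_sim
        chosen, table = select_time_df(series, ModelSpec(), [3, 5, 7, 9])
        s_chosen = table.loc[table["time_df"] == chosen, "pacf_abs_sum"].iloc[0]
        assert (s_chosen <= table["pacf_abs_sum"] + 1e-12).all()
        assert set(table["time_df"]) == {3, 5, 7, 9}

    def test_tie_breaks_toward_smaller_df(self, default_sim, monkeypatch):
        series, _ = default_sim
        import pollenlag.model as model_mod

        monkeypatch.setattr(model_mod, "pacf", lambda r, m: np.full(m, 0.01))
        chosen, table = select_time_df(series, ModelSpec(), [6, 4, 8])
        assert chosen == 4
        assert np.allclose(table["pacf_abs_sum"], table["pacf_abs_sum"].iloc[0])

    def test_rule_tracks_trend_roughness(self):
        """A 3-cycle sinusoidal trend needs more than a near-linear smooth:
        the PACF rule should pick df >= 4 in >= 90 of 100 seeds."""
        wins = 0
        for s in range(100):
            cfg = SimulationConfig(seed=7000 + s, truth_surface=LagSurfaceSpec(kind="null"),
                                   trend_amplitude=0.6, trend_cycles=3.0)
            series, _ = generate(cfg)
            chosen, _ = select_time_df(series, ModelSpec(), [3, 4, 6, 8, 10, 12])
            wins += chosen >= 4
        assert wins >= 90

    def test_empty_candidates_error(self, default_sim):
        series, _ = default_sim
        with pytest.raises(ValueError, match="candidate"):
            select_time_df(series, ModelSpec(), [])


class TestCompareAIC:
    @staticmethod
    def _fit(y, X, name):
        beta, cov, mu, dev, llf, *_ = _irls(X, y)
        return SimpleNamespace(response=y, params=beta, aic=-2 * llf + 2 * len(beta), name=name)

    def test_duplicate_fits_tie_with_stable_order(self):
        y = np.array([4, 5, 6, 7, 8])
        f = self._fit(y, np.ones((5, 1)), "a")
        g = self._fit(y, np.ones((5, 1)), "b")
        table = compare_aic([f, g])
        assert np.allclose(table["delta_aic"], 0.0)
        assert list(table["model"]) == ["a", "b"]

    def test_single_fit(self):
        y = np.array([1, 2, 3])
        table = compare_aic([self._fit(y, np.ones((3, 1)), "only")])
        assert len(table) == 1 and table["delta_aic"].iloc[0] == 0.0

    def test_mixed_response_detected(self):
        f = self._fit(np.array([1, 2, 3]), np.ones((3, 1)), "a")
        g = self._fit(np.array([1, 2, 4]), np.ones((3, 1)), "b")
        with pytest.raises(ValueError, match="identical response"):
            compare_aic([f, g])

    def test_noise_column_penalized_in_majority_of_seeds(self):
        wins = 0
        for s in range(100):
            rng = np.random.default_rng(200 + s)
            y = rng.poisson(5.0, size=400)
            X0 = np.ones((400, 1))
            X1 = np.column_stack([X0, rng.normal(size=400)])
            table = compare_aic([self._fit(y, X0, "small"), self._fit(y, X1, "noisy")])
            wins += table["model"].iloc[0] == "small"
        assert wins > 50
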