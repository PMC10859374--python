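import numpy as np
import pytest
from hypothesis import given, strategies as st

from pollenlag import (
    EffectCurve,
    LagSurfaceSpec,
    ModelSpec,
    PoissonDLNM,
    SimulationConfig,
    generate,
    implied_point_estimate,
    rr_from_beta,
    summarize_curve,
)
from pollenlag.basis import build_cross_basis
from pollenlag.effects import predict_surface


@pytest.fixture(scope="module")
def recovery_fit():
    """Large-sample fit of a known linear x exp-decay truth surface."""
    series, truth = generate(SimulationConfig(n_days=2000, seed=42))
    res = PoissonDLNM(series, ModelSpec(time_df=10)).fit()
    return series, truth, res


class TestRRFromBeta:
    def test_zero_slope_gives_unit_rr_symmetric_ci(self):
        est = rr_from_beta(0.0, 0.07, 10.0)
        assert est.rr == 1.0
        assert np.isclose(np.log(est.ci_high), -np.log(est.ci_low))

    def test_direct_formula_evaluation(self):
        est = rr_from_beta(0.01, 0.004, 10.0)
        assert np.isclose(est.rr, np.exp(0.1))
        assert np.isclose(est.rr, 1.10517, atol=1e-5)
        assert np.isclose(est.ci_low, np.exp(0.0216), atol=1e-9)
        assert np.isclose(est.ci_high, np.exp(0.1784), atol=1e-9)
        assert np.isclose(est.ci_low, 1.02184, atol=1e-5)
        assert np.isclose(est.ci_high, 1.19530, atol=1e-5)

    def test_published_interval_readback(self):
        # a published high-percentile RR of 1.444 with CI (1.087, 1.917)
        # is internally consistent with the geometric-mean identity
        point = implied_point_estimate(1.087, 1.917)
        assert np.isclose(point, 1.4435, atol=5e-4)
        assert round(point, 3) == 1.444

    def test_input_validation(self):
        with pytest.raises(ValueError):
            rr_from_beta(np.nan, 0.1, 1.0)
        with pytest.raises(ValueError):
            rr_from_beta(0.1, -0.1, 1.0)
        with pytest.raises(ValueError):
            implied_point_estimate(-1.0, 2.0)

    @given(beta=st.floats(-0.5, 0.5), se=st.floats(0.0, 0.5), dc=st.floats(0.0, 50.0))
    def test_geometric_mean_identity(self, beta, se, dc):
        est = rr_from_beta(beta, se, dc)
        assert np.isclose(est.rr, np.sqrt(est.ci_low * est.ci_high), rtol=1e-12)


class TestPredictSurface:
    def test_reference_exposure_has_unit_rr_everywhere(self, fitted):
        surf = fitted.predict_surface(np.array([0.0, 100.0]), reference=0.0)
        curve = surf.lag_specific_curve(0.0)
        assert np.array_equal(curve.rr, np.ones(31))
        assert np.array_equal(curve.se, np.zeros(31))
        assert np.array_equal(curve.ci_low, np.ones(31))
        assert np.array_equal(curve.ci_high, np.ones(31))
        cum = surf.cumulative_curve(0.0)
        assert np.array_equal(cum.rr, np.ones(31))

    def test_cumulative_se_follows_quadratic_form_rule(self):
        # two-lag cross-basis arranged so the per-lag log-RR variances are
        # 0.01 with covariance 0.005: cumulative SE at lag 1 = sqrt(0.03)
        cb = build_cross_basis(np.arange(1.0, 40.0), 1, 2, 1,
                               exposure_kind="linear", lag_kind="linear")
        A = cb.contrast(1.0, 0.0)  # (2 lags, 2 columns)
        target = np.array([[0.01, 0.005], [0.005, 0.01]])
        Ainv = np.linalg.inv(A)
        V = Ainv @ target @ Ainv.T
        beta = np.array([0.1, 0.02])
        surf = predict_surface(beta, V, cb, np.array([1.0]), reference=0.0)
        assert np.allclose(surf.se[0], 0.1, atol=1e-12)
        assert np.isclose(surf.cumulative_se[0, 1], np.sqrt(0.03), atol=1e-12)
        assert np.isclose(surf.cumulative_se[0, 1], 0.17321, atol=5e-6)

    def test_cumulative_is_running_sum_of_lag_specific(self, fitted):
        surf = fitted.predict_surface(grid_size=20)
        assert np.allclose(np.cumsum(surf.log_rr, axis=1), surf.cumulative_log_rr, atol=1e-12)
        assert np.allclose(surf.cumulative_log_rr[:, 0], surf.log_rr[:, 0], atol=1e-15)

    def test_reference_shift_invariance_linear_exposure_basis(self):
        series, _ = generate(SimulationConfig(seed=31))
        spec = ModelSpec(df_exposure=1, exposure_kind="linear", time_df=4, max_lag=10, df_lag=3)
        res = PoissonDLNM(series, spec).fit()
        shift = 25.0
        frame2 = series.frame.copy()
        frame2["pollen"] = frame2["pollen"] + shift
        res2 = PoissonDLNM.from_dataframe(frame2, spec).fit()
        x = 120.0
        s1 = res.predict_surface(np.array([x]), reference=0.0)
        s2 = res2.predict_surface(np.array([x + shift]), reference=shift)
        assert np.allclose(s1.log_rr[0], s2.log_rr[0], atol=1e-6)
        assert np.allclose(s1.se[0], s2.se[0], atol=1e-6)

    def test_reference_outside_boundary_rejected(self, fitted):
        with pytest.raises(ValueError, match="reference"):
            fitted.predict_surface(np.array([10.0]), reference=-50.0)

    def test_large_sample_recovery_of_true_surface(self, recovery_fit):
        _, truth, res = recovery_fit
        surf = res.predict_surface()
        true_grid = truth.log_rr(surf.exposures[:, None], surf.lags[None, :].astype(float))
        mae = np.abs(surf.log_rr - true_grid).mean()
        assert mae < 0.05


class TestPercentileEffects:
    def test_quantile_rule_linear_interpolation(self, fitted):
        series = fitted.model.series
        q = fitted.percentile_exposures((25,))[25]
        assert np.isclose(q, np.percentile(series.exposure, 25))
        # the documented rule on 1..100: P25 = 25.75
        assert np.isclose(np.percentile(np.arange(1.0, 101.0), 25), 25.75)

    def test_curves_match_surface_at_percentile_exposure(self, fitted):
        pe = fitted.percentile_effects((50,))
        x50 = pe[50]["exposure"]
        surf = fitted.predict_surface(np.array([x50]))
        assert np.allclose(pe[50]["specific"].log_rr, surf.lag_specific_curve(x50).log_rr)
        assert np.allclose(pe[50]["cumulative"].log_rr, surf.cumulative_curve(x50).log_rr)

    def test_peak_rr_monotone_across_percentiles_for_monotone_truth(self, recovery_fit):
        _, _, res = recovery_fit
        pe = res.percentile_effects()
        peaks = [summarize_curve(pe[p]["specific"]).peak.rr for p in (5, 25, 50, 75, 95)]
        assert all(a <= b + 1e-12 for a, b in zip(peaks, peaks[1:]))


class TestSummarizeCurve:
    @staticmethod
    def curve(log_rr, se):
        log_rr = np.asarray(log_rr, float)
        se = np.asarray(se, float)
        return EffectCurve(10.0, np.arange(log_rr.size), log_rr, se)

    def test_peak_day0_effect_gone_day4(self):
        # significant at lags 0-3, CI containing 1 from lag 4 onward
        log_rr = np.array([0.30, 0.20, 0.12, 0.06, 0.02, 0.00])
        se = np.array([0.02, 0.02, 0.02, 0.02, 0.05, 0.05])
        s = summarize_curve(self.curve(log_rr, se))
        assert s.peak_lag == 0
        assert s.lag_time == 4

    def test_degenerate_null_curve(self):
        s = summarize_curve(self.curve(np.zeros(31), np.zeros(31)))
        assert s.peak_lag == 0
        assert s.lag_time == 0

    def test_always_significant_curve_censored(self):
        s = summarize_curve(self.curve(np.linspace(0.5, 0.1, 31), np.full(31, 0.01)))
        assert s.lag_time == 31

    def test_peak_tie_takes_smallest_lag(self):
        log_rr = np.array([0.1, 0.2, 0.2, 0.05])
        s = summarize_curve(self.curve(log_rr, np.full(4, 0.01)))
        assert s.peak_lag == 1

    def test_lag_time_never_before_peak(self):
        # early CI containing 1 must not end the effect before its peak
        log_rr = np.array([0.0, 0.3, 0.2, 0.0])
        se = np.array([0.5, 0.01, 0.01, 0.5])
        s = summarize_curve(self.curve(log_rr, se))
        assert s.peak_lag == 1
        assert s.lag_time == 3
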