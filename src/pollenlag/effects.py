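"""Lag-specific and cumulative relative-risk estimates from a fitted DLNM.

All effects are linear contrasts of the cross-basis coefficient block: for an
exposure x against a reference exposure (pollen = 0 by convention), the
contrast vector at lag l is a(x, l) = [b(x) - b(ref)] (x) c(l).  The
lag-specific log RR is a . beta_hat, its variance the quadratic form
a' V a in the coefficient covariance, and the running-cumulative effect over
lags 0..l uses the summed contrast.  Confidence intervals follow
RR = exp(beta * dc), CI = exp[(beta +/- z * SE) * dc] with z = 1.96 at the
default 95% level, so every point estimate equals the geometric mean of its
interval bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Z_95",
    "EffectEstimate",
    "EffectCurve",
    "EffectSummary",
    "LagEffectSurface",
    "rr_from_beta",
    "implied_point_estimate",
    "predict_surface",
    "summarize_curve",
]

#: standard-normal quantile for two-sided 95% intervals
Z_95 = 1.96


@dataclass(frozen=True)
class EffectEstimate:
    """One relative risk with its 95% interval; rr = sqrt(ci_low * ci_high)."""

    log_rr: float
    se: float
    zcrit: float = Z_95

    @property
    def rr(self) -> float:
        return float(np.exp(self.log_rr))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.log_rr - self.zcrit * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.log_rr + self.zcrit * self.se))


def implied_point_estimate(ci_low: float, ci_high: float) -> float:
    """Point RR implied by a symmetric-on-log-scale interval: sqrt(low*high).

    Because CI = exp[(beta +/- z SE) dc], the point estimate exp(beta dc) is
    exactly the geometric mean of the bounds; reading a published interval
    back through this identity recovers (and checks) the published RR.
    """
    if ci_low <= 0 or ci_high <= 0 or ci_low > ci_high:
        raise ValueError("need 0 < ci_low <= ci_high")
    return float(np.sqrt(ci_low * ci_high))


def rr_from_beta(beta: float, se: float, delta_c: float, zcrit: float = Z_95) -> EffectEstimate:
    """Relative risk for an exposure increment delta_c given a slope beta.

    Implements RR = exp(beta * dc) with CI exp[(beta +/- z SE) * dc]; the
    interval collapses around RR when either SE or dc is 0 and is symmetric
    about RR on the log scale.
    """
    if not np.isfinite([beta, se, delta_c]).all():
        raise ValueError("non-finite inputs to rr_from_beta")
    if se < 0:
        raise ValueError("se must be >= 0")
    return EffectEstimate(log_rr=beta * delta_c, se=se * abs(delta_c), zcrit=zcrit)


@dataclass(frozen=True)
class EffectCurve:
    """Per-lag effect estimates at a single exposure value."""

    exposure: float
    lags: np.ndarray
    log_rr: np.ndarray
    se: np.ndarray
    zcrit: float = Z_95

    @property
    def rr(self) -> np.ndarray:
        return np.exp(self.log_rr)

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.log_rr - self.zcrit * self.se)

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.log_rr + self.zcrit * self.se)

    def __len__(self) -> int:
        return len(self.lags)

    def estimate(self, lag: int) -> EffectEstimate:
        i = int(np.flatnonzero(self.lags == lag)[0])
        return EffectEstimate(float(self.log_rr[i]), float(self.se[i]), self.zcrit)


@dataclass(frozen=True)
class EffectSummary:
    """Peak and persistence of a lag-response curve.

    ``lag_time`` is the smallest lag at or after the RR peak whose 95% CI
    contains 1 (the lag at which the effect "disappears"); curves significant
    through the last lag L are censored at L + 1.
    """

    peak_lag: int
    peak: EffectEstimate
    lag_time: int


def summarize_curve(curve: EffectCurve) -> EffectSummary:
    if len(curve) == 0:
        raise ValueError("empty curve")
    rr = curve.rr
    peak_idx = int(np.argmax(rr))  # argmax takes the smallest index on ties
    lo, hi = curve.ci_low, curve.ci_high
    contains_one = (lo <= 1.0) & (1.0 <= hi)
    after_peak = np.flatnonzero(contains_one[peak_idx:])
    if after_peak.size:
        lag_time = int(curve.lags[peak_idx + after_peak[0]])
    else:
        lag_time = int(curve.lags[-1]) + 1
    return EffectSummary(
        peak_lag=int(curve.lags[peak_idx]),
        peak=curve.estimate(int(curve.lags[peak_idx])),
        lag_time=lag_time,
    )


@dataclass(frozen=True)
class LagEffectSurface:
    """Grid of lag-specific and running-cumulative log-RR estimates.

    ``log_rr`` and ``se`` have shape (n_exposures, n_lags); the cumulative
    arrays hold the effect summed over lags 0..l, with standard errors from
    the summed-contrast quadratic form (so lag-to-lag covariances are kept).
    """

    exposures: np.ndarray
    lags: np.ndarray
    reference: float
    log_rr: np.ndarray
    se: np.ndarray
    cumulative_log_rr: np.ndarray
    cumulative_se: np.ndarray
    zcrit: float = Z_95

    @property
    def rr(self) -> np.ndarray:
        return np.exp(self.log_rr)

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.log_rr - self.zcrit * self.se)

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.log_rr + self.zcrit * self.se)

    @property
    def cumulative_rr(self) -> np.ndarray:
        return np.exp(self.cumulative_log_rr)

    def _row(self, exposure: float) -> int:
        i = np.flatnonzero(np.isclose(self.exposures, exposure))
        if i.size == 0:
            raise KeyError(f"exposure {exposure} not on the surface grid")
        return int(i[0])

    def lag_specific_curve(self, exposure: float) -> EffectCurve:
        i = self._row(exposure)
        return EffectCurve(float(self.exposures[i]), self.lags, self.log_rr[i], self.se[i], self.zcrit)

    def cumulative_curve(self, exposure: float) -> EffectCurve:
        i = self._row(exposure)
        return EffectCurve(
            float(self.exposures[i]), self.lags, self.cumulative_log_rr[i], self.cumulative_se[i], self.zcrit
        )


def _quad_form_se(A: np.ndarray, V: np.ndarray) -> np.ndarray:
    var = np.einsum("lp,pq,lq->l", A, V, A)
    if np.any(var < -1e-8):
        raise ValueError("covariance sub-block is not positive semi-definite")
    return np.sqrt(np.clip(var, 0.0, None))


def predict_surface(
    beta_cb: np.ndarray,
    cov_cb: np.ndarray,
    crossbasis,
    exposures: np.ndarray,
    reference: float = 0.0,
    zcrit: float = Z_95,
) -> LagEffectSurface:
    """Evaluate the exposure-lag effect surface implied by fitted coefficients.

    Parameters are the cross-basis coefficient block, its covariance
    sub-block, the fitted CrossBasis (which carries both marginal bases), the
    exposure grid, and the reference exposure.
    """
    eb = crossbasis.exposure_basis
    if eb.kind == "natural-cubic":
        lo, hi = eb.boundary
        if not (lo <= reference <= hi):
            raise ValueError(f"reference {reference} outside basis boundary ({lo}, {hi})")
    exposures = np.atleast_1d(np.asarray(exposures, float))
    L = crossbasis.max_lag
    lags = np.arange(L + 1)
    n_exp = exposures.size
    log_rr = np.empty((n_exp, L + 1))
    se = np.empty_like(log_rr)
    clog_rr = np.empty_like(log_rr)
    cse = np.empty_like(log_rr)
    for i, x in enumerate(exposures):
        A = crossbasis.contrast(float(x), reference)  # (L+1, p_cb)
        log_rr[i] = A @ beta_cb
        se[i] = _quad_form_se(A, cov_cb)
        Acum = np.cumsum(A, axis=0)
        clog_rr[i] = Acum @ beta_cb
        cse[i] = _quad_form_se(Acum, cov_cb)
    return LagEffectSurface(
        exposures=exposures,
        lags=lags,
        reference=float(reference),
        log_rr=log_rr,
        se=se,
        cumulative_log_rr=clog_rr,
        cumulative_se=cse,
        zcrit=zcrit,
    )
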