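"""Poisson GAM with a distributed-lag cross-basis, statsmodels-style.

The model for daily counts Y_t is

    Y_t ~ Poisson(mu_t)
    log mu_t = b0 + cb(X_t) . beta + s(t, df_t) + sum_j s(Z_jt, 3)
               + DOW contrasts + holiday indicator

where cb(X_t) is the exposure x lag cross-basis of the pollen series, s(.)
are fixed-df natural cubic splines (time smoother df chosen by the PACF rule
or fixed), and day-of-week / holiday enter as categorical contrasts.  The
fit maximizes the Poisson log-likelihood by iteratively reweighted least
squares; the coefficient covariance is the inverse Fisher information at the
optimum.

Typical use::

    model = PoissonDLNM(series)           # or PoissonDLNM.from_dataframe(df)
    res = model.fit()
    surf = res.predict_surface()          # lag-specific + cumulative RR grids
    res.percentile_effects()              # P5..P95 curves, paper-style
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, special, stats

from .basis import CrossBasis, SplineBasis, build_cross_basis, natural_cubic_basis
from .data import DailySeries
from .diagnostics import pacf
from .effects import Z_95, LagEffectSurface, predict_surface

__all__ = ["ModelSpec", "PoissonDLNM", "PoissonDLNMResults", "select_time_df"]

_ETA_CLIP = 30.0


@dataclass(frozen=True)
class ModelSpec:
    """Model structure: cross-basis dimensions, smoother dfs, categorical terms."""

    df_exposure: int = 3
    df_lag: int = 4
    max_lag: int = 30
    exposure_kind: str = "natural-cubic"
    lag_kind: str = "natural-cubic"
    time_df: int | str = "auto"
    time_df_candidates: tuple[int, ...] = tuple(range(3, 16))
    covariate_names: tuple[str, ...] | None = None
    covariate_df: int = 3
    include_dow: bool = True
    include_holiday: bool = True
    incomplete: str = "pad"
    pacf_max_lag: int = 30

    def __post_init__(self):
        if isinstance(self.time_df, str):
            if self.time_df != "auto":
                raise ValueError("time_df must be an integer >= 2 or 'auto'")
            if not self.time_df_candidates:
                raise ValueError("time_df_candidates must be non-empty")
        elif self.time_df < 2:
            raise ValueError("fixed time_df must be >= 2")
        if self.covariate_df < 1:
            raise ValueError("covariate_df must be >= 1")


class _Design:
    """Assembled fixed-df design matrix with named column blocks."""

    def __init__(self, series: DailySeries, spec: ModelSpec, time_df: int, include_crossbasis: bool = True):
        cb = build_cross_basis(
            series.exposure,
            df_exposure=spec.df_exposure,
            df_lag=spec.df_lag,
            max_lag=spec.max_lag,
            exposure_kind=spec.exposure_kind,
            lag_kind=spec.lag_kind,
            incomplete=spec.incomplete,
        )
        off = cb.offset
        n = len(series) - off
        blocks: list[np.ndarray] = [np.ones((n, 1))]
        names: list[str] = ["intercept"]

        if include_crossbasis:
            blocks.append(cb.design)
            names += [f"cb[{j},{k}]" for j in range(cb.df_exposure) for k in range(cb.df_lag)]
            self.cb_slice = slice(1, 1 + cb.design.shape[1])
        else:
            self.cb_slice = slice(1, 1)

        t = np.arange(len(series), dtype=float)[off:]
        blocks.append(natural_cubic_basis(t, df=time_df))
        names += [f"s(t)[{i}]" for i in range(time_df)]

        cov_names = spec.covariate_names
        if cov_names is None:
            cov_names = tuple(series.covariate_names)
        for name in cov_names:
            z = series.covariate(name)[off:]
            df_z = min(spec.covariate_df, max(1, np.unique(z).size - 1))
            basis = SplineBasis.natural_cubic(df=df_z, boundary=(float(z.min()), float(z.max())), values=z)
            blocks.append(basis.evaluate(z))
            names += [f"s({name})[{i}]" for i in range(basis.df)]

        if spec.include_dow:
            dow = series.dow[off:]
            for level in range(2, 8):  # Monday is the reference
                blocks.append((dow == level).astype(float)[:, None])
                names.append(f"dow[{level}]")
        if spec.include_holiday and series.holiday[off:].any():
            blocks.append(series.holiday[off:].astype(float)[:, None])
            names.append("holiday")

        self.X = np.column_stack(blocks)
        self.names = names
        self.y = series.counts[off:]
        self.crossbasis = cb
        self.time_df = time_df

        r_diag = np.abs(np.diag(linalg.qr(self.X, mode="r", pivoting=True)[0]))
        piv = linalg.qr(self.X, mode="r", pivoting=True)[1]
        tol = r_diag.max() * max(self.X.shape) * np.finfo(float).eps
        deficient = r_diag < tol
        if deficient.any():
            bad = [names[piv[i]] for i in np.flatnonzero(deficient)]
            raise ValueError(f"design matrix is rank deficient; offending columns: {bad}")


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    return float(2.0 * np.sum(special.xlogy(y, y / mu) - (y - mu)))


def _irls(X: np.ndarray, y: np.ndarray, tol: float = 1e-10, maxiter: int = 100):
    """Newton scoring (IRLS) for the Poisson log-link likelihood."""
    n, p = X.shape
    mu = (y + y.mean() + 0.1) / 2.0
    eta = np.log(mu)
    dev = _poisson_deviance(y, mu)
    converged = False
    clipped = False
    it = 0
    for it in range(1, maxiter + 1):
        w = mu
        z = eta + (y - mu) / mu
        wx = X * np.sqrt(w)[:, None]
        wz = z * np.sqrt(w)
        try:
            c, low = linalg.cho_factor(wx.T @ wx)
            beta = linalg.cho_solve((c, low), wx.T @ wz)
        except linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(wx, wz, rcond=None)
        eta_new = X @ beta
        if np.any(np.abs(eta_new) > _ETA_CLIP):
            clipped = True
            warnings.warn("linear predictor clipped at +/-30; possible separation/overflow")
            eta_new = np.clip(eta_new, -_ETA_CLIP, _ETA_CLIP)
        eta = eta_new
        mu = np.exp(eta)
        dev_new = _poisson_deviance(y, mu)
        dev_done = abs(dev - dev_new) < tol * (abs(dev_new) + 0.1)
        dev = dev_new
        # require a flat score as well: the deviance can stall one Newton
        # step before the gradient does
        if dev_done and np.max(np.abs(X.T @ (y - mu))) < 1e-6:
            converged = True
            break
    grad = X.T @ (y - mu)
    converged = converged and (not clipped) and np.max(np.abs(grad)) < 1e-6
    fisher = (X * mu[:, None]).T @ X
    try:
        c, low = linalg.cho_factor(fisher)
        cov = linalg.cho_solve((c, low), np.eye(p))
    except linalg.LinAlgError:
        cov = np.linalg.pinv(fisher)
    cov = (cov + cov.T) / 2.0
    llf = float(np.sum(y * eta - mu - special.gammaln(y + 1.0)))
    resid_dev = np.sign(y - mu) * np.sqrt(np.clip(2.0 * (special.xlogy(y, y / mu) - (y - mu)), 0.0, None))
    return beta, cov, mu, dev, llf, resid_dev, converged, clipped, it


class PoissonDLNM:
    """Distributed-lag non-linear Poisson GAM for a daily count series."""

    def __init__(self, series: DailySeries, spec: ModelSpec | None = None):
        if not isinstance(series, DailySeries):
            raise TypeError("series must be a DailySeries; see PoissonDLNM.from_dataframe")
        self.series = series
        self.spec = spec or ModelSpec()
        if len(series) <= self.spec.max_lag:
            raise ValueError("series shorter than max_lag")

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, spec: ModelSpec | None = None, holidays=None):
        return cls(DailySeries.from_frame(frame, holidays=holidays), spec)

    @classmethod
    def from_csv(cls, path, spec: ModelSpec | None = None, holidays=None):
        return cls.from_dataframe(pd.read_csv(path), spec, holidays=holidays)

    # -- fitting -----------------------------------------------------------

    def _fit_fixed(self, time_df: int, df_score_table: pd.DataFrame | None = None, include_crossbasis: bool = True):
        design = _Design(self.series, self.spec, time_df, include_crossbasis=include_crossbasis)
        beta, cov, mu, dev, llf, resid, converged, clipped, n_iter = _irls(design.X, design.y)
        if not converged:
            warnings.warn(f"IRLS did not converge after {n_iter} iterations")
        ybar = design.y.mean()
        null_dev = _poisson_deviance(design.y, np.full_like(mu, ybar))
        return PoissonDLNMResults(
            model=self,
            params=beta,
            cov_params=cov,
            names=list(design.names),
            cb_slice=design.cb_slice,
            crossbasis=design.crossbasis,
            fittedvalues=mu,
            response=design.y,
            deviance=dev,
            null_deviance=null_dev,
            llf=llf,
            aic=-2.0 * llf + 2.0 * len(beta),
            resid_deviance=resid,
            converged=converged,
            clipped=clipped,
            n_iter=n_iter,
            time_df=time_df,
            df_score_table=df_score_table,
        )

    def fit(self) -> "PoissonDLNMResults":
        """Fit by IRLS; resolves time_df="auto" with the PACF-sum rule first."""
        if self.spec.time_df == "auto":
            chosen, table = select_time_df(self.series, self.spec, list(self.spec.time_df_candidates))
            return self._fit_fixed(chosen, df_score_table=table)
        return self._fit_fixed(int(self.spec.time_df))


def select_time_df(series: DailySeries, spec: ModelSpec, candidates: list[int]):
    """Choose the time-smoother df minimizing the summed |PACF| of residuals.

    For each candidate df the base model (time smoother, covariates and
    calendar terms, without the cross-basis — the exposure block is
    introduced only after the trend df is settled) is fitted and
    S(df) = sum_{k=1..30} |PACF_k(deviance residuals)| computed; the df with
    the smallest S wins, ties (within 1e-12) broken toward the smaller df.
    Returns (chosen df, score table with one row per candidate).
    """
    if not candidates:
        raise ValueError("no candidate df values")
    model = PoissonDLNM(series, replace(spec, time_df=candidates[0]))
    max_lag = min(spec.pacf_max_lag, (len(series) - spec.max_lag * (spec.incomplete == "drop")) // 2 - 1)
    rows = []
    failures = []
    for df in sorted(candidates):
        try:
            res = model._fit_fixed(int(df), include_crossbasis=False)
            s = float(np.abs(pacf(res.resid_deviance, max_lag)).sum())
            rows.append({"time_df": int(df), "pacf_abs_sum": s, "aic": res.aic, "converged": res.converged})
        except Exception as exc:  # noqa: BLE001 - candidate failure is data, not fatal
            failures.append((df, exc))
    if not rows:
        raise RuntimeError(f"all candidate fits failed: {failures}")
    table = pd.DataFrame(rows)
    best = table["pacf_abs_sum"].min()
    chosen = int(table.loc[table["pacf_abs_sum"] <= best + 1e-12, "time_df"].min())
    return chosen, table


@dataclass
class PoissonDLNMResults:
    """Fitted coefficients, covariance, diagnostics, and effect predictions."""

    model: PoissonDLNM
    params: np.ndarray
    cov_params: np.ndarray
    names: list[str]
    cb_slice: slice
    crossbasis: CrossBasis
    fittedvalues: np.ndarray
    response: np.ndarray
    deviance: float
    null_deviance: float
    llf: float
    aic: float
    resid_deviance: np.ndarray
    converged: bool
    clipped: bool
    n_iter: int
    time_df: int
    df_score_table: pd.DataFrame | None = None
    name: str = field(default="", repr=False)

    def __post_init__(self):
        if not self.name:
            self.name = f"dlnm(df_t={self.time_df})"

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def pseudo_r2(self) -> float:
        """Explained deviance, 1 - D/D_null (a deviance pseudo R^2)."""
        return 1.0 - self.deviance / self.null_deviance

    @property
    def cb_params(self) -> np.ndarray:
        return self.params[self.cb_slice]

    @property
    def cb_cov(self) -> np.ndarray:
        return self.cov_params[self.cb_slice, self.cb_slice]

    # -- effect predictions ------------------------------------------------

    def predict_surface(
        self,
        exposures: np.ndarray | None = None,
        reference: float = 0.0,
        grid_size: int = 50,
        zcrit: float = Z_95,
    ) -> LagEffectSurface:
        """Lag-specific and cumulative RR over an exposure grid vs. reference.

        The default grid is ``grid_size`` evenly spaced concentrations from 0
        to the observed maximum.
        """
        if exposures is None:
            exposures = np.linspace(0.0, float(self.model.series.exposure.max()), grid_size)
        return predict_surface(self.cb_params, self.cb_cov, self.crossbasis, exposures, reference, zcrit)

    def percentile_exposures(self, probs=(5, 25, 50, 75, 95)) -> dict[int, float]:
        """Empirical exposure quantiles (linear interpolation rule)."""
        x = self.model.series.exposure
        return {int(p): float(np.percentile(x, p)) for p in probs}

    def percentile_effects(self, probs=(5, 25, 50, 75, 95), reference: float = 0.0, zcrit: float = Z_95):
        """Lag-specific and cumulative RR curves at exposure percentiles.

        Returns {percentile: {"exposure", "specific", "cumulative"}} with
        EffectCurve values, mirroring the P5..P95 RR-matrix outputs.
        """
        pexp = self.percentile_exposures(probs)
        surf = self.predict_surface(np.array(list(pexp.values())), reference, zcrit=zcrit)
        out = {}
        for p, x in pexp.items():
            out[p] = {
                "exposure": x,
                "specific": surf.lag_specific_curve(x),
                "cumulative": surf.cumulative_curve(x),
            }
        return out

    # -- reporting ---------------------------------------------------------

    def coefficient_table(self) -> pd.DataFrame:
        se = self.bse
        z = np.divide(self.params, se, out=np.zeros_like(self.params), where=se > 0)
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame({"term": self.names, "coef": self.params, "se": se, "z": z, "p": p})

    def summary(self) -> str:
        head = [
            "Poisson DLNM (log link, fixed-df natural splines)",
            f"n obs: {len(self.response)}   cross-basis: "
            f"{self.crossbasis.df_exposure} x {self.crossbasis.df_lag}, max lag {self.crossbasis.max_lag}",
            f"time smoother df: {self.time_df}   converged: {self.converged} ({self.n_iter} iter)",
            f"deviance: {self.deviance:.3f}   null deviance: {self.null_deviance:.3f}   "
            f"pseudo R2: {self.pseudo_r2:.3f}",
            f"log-likelihood: {self.llf:.3f}   AIC: {self.aic:.3f}",
        ]
        tab = self.coefficient_table()
        body = tab.to_string(index=False, float_format=lambda v: f"{v: .5f}")
        return "\n".join(head) + "\n" + "-" * 72 + "\n" + body

    def to_json_dict(self) -> dict:
        return {
            "terms": self.names,
            "coefficients": self.params.tolist(),
            "standard_errors": self.bse.tolist(),
            "aic": self.aic,
            "deviance": self.deviance,
            "null_deviance": self.null_deviance,
            "pseudo_r2": self.pseudo_r2,
            "log_likelihood": self.llf,
            "converged": bool(self.converged),
            "time_df": self.time_df,
            "crossbasis": self.crossbasis.to_dict(),
        }
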