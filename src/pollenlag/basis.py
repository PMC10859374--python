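"""Natural cubic spline bases and the exposure x lag cross-basis.

The cross-basis is the design-matrix block of a distributed lag non-linear
model (DLNM): a tensor product of a spline basis over the exposure dimension
and a spline basis over the lag dimension, summed over the lagged exposure
history of each day.  It enters a Poisson log-link regression as an ordinary
block of columns, and lag-response relative risks are linear contrasts of its
coefficients.

Natural cubic splines are cubic between knots with zero second derivative at
(and linear extension beyond) the boundary knots.  Each basis column is built
as the cardinal natural interpolant of an indicator vector on the knot set, so
any function in the span is fully determined by its values at the knots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "SplineBasis",
    "CrossBasis",
    "natural_cubic_basis",
    "build_cross_basis",
]


def _quantile_knots(values: np.ndarray, n_interior: int) -> np.ndarray:
    """Interior knots at equally spaced quantiles of the observed values."""
    if n_interior <= 0:
        return np.empty(0)
    probs = np.arange(1, n_interior + 1) / (n_interior + 1)
    return np.quantile(values, probs)


@dataclass(frozen=True)
class SplineBasis:
    """A fixed one-dimensional basis with a deterministic evaluation contract.

    Parameters
    ----------
    kind : {"natural-cubic", "linear", "indicator0"}
        "natural-cubic" gives cardinal natural-spline columns; "linear" is the
        identity map (a single column equal to the input, through the origin);
        "indicator0" is a single 0/1 column marking the value 0 (used as a
        lag-0 indicator basis in degenerate cross-bases).
    knots : interior knot positions (strictly inside the boundary, sorted).
    boundary : (lower, upper) boundary knots.
    df : number of basis columns.
    include_intercept : whether the constant function is in the span.  For a
        natural-cubic basis without intercept df = interior knots + 1; with
        intercept df = interior knots + 2.  Lag bases include the intercept so
        a constant-over-lags effect is representable.
    """

    kind: str
    knots: tuple[float, ...] = ()
    boundary: tuple[float, float] = (0.0, 1.0)
    df: int = 1
    include_intercept: bool = False
    _spline: CubicSpline | None = field(default=None, repr=False, compare=False)

    # -- construction -----------------------------------------------------

    @staticmethod
    def natural_cubic(
        df: int,
        boundary: tuple[float, float],
        knots: Sequence[float] | None = None,
        values: np.ndarray | None = None,
        include_intercept: bool = False,
    ) -> "SplineBasis":
        lo, hi = float(boundary[0]), float(boundary[1])
        if not np.isfinite([lo, hi]).all() or lo >= hi:
            raise ValueError(f"boundary must satisfy lower < upper, got ({lo}, {hi})")
        if df < 1:
            raise ValueError(f"df must be >= 1, got {df}")
        n_interior = df - 2 if include_intercept else df - 1
        if n_interior < 0:
            raise ValueError(f"df={df} too small for include_intercept={include_intercept}")
        if knots is None:
            if n_interior > 0 and values is None:
                raise ValueError("interior knots required: pass knots or values")
            knots_arr = _quantile_knots(np.asarray(values, float), n_interior) if n_interior else np.empty(0)
            # ties in the quantiles (heavily discrete data, e.g. mostly-zero
            # rainfall) collapse knots; reduce the df rather than fail
            knots_arr = np.unique(knots_arr)
            knots_arr = knots_arr[(knots_arr > lo) & (knots_arr < hi)]
            if knots_arr.size < n_interior:
                df = knots_arr.size + (2 if include_intercept else 1)
                n_interior = knots_arr.size
        else:
            knots_arr = np.asarray(knots, float)
        if knots_arr.size != n_interior:
            raise ValueError(
                f"natural-cubic basis with df={df} (intercept={include_intercept}) "
                f"needs {n_interior} interior knots, got {knots_arr.size}"
            )
        if knots_arr.size:
            if not np.all(np.diff(knots_arr) > 0):
                raise ValueError("interior knots must be strictly increasing")
            if knots_arr[0] <= lo or knots_arr[-1] >= hi:
                raise ValueError("interior knots must lie strictly inside the boundary")
        all_knots = np.concatenate([[lo], knots_arr, [hi]])
        spline = CubicSpline(all_knots, np.eye(all_knots.size), bc_type="natural", axis=0)
        return SplineBasis(
            kind="natural-cubic",
            knots=tuple(knots_arr),
            boundary=(lo, hi),
            df=df,
            include_intercept=include_intercept,
            _spline=spline,
        )

    @staticmethod
    def linear() -> "SplineBasis":
        return SplineBasis(kind="linear", df=1)

    @staticmethod
    def indicator0() -> "SplineBasis":
        return SplineBasis(kind="indicator0", df=1)

    # -- evaluation --------------------------------------------------------

    @property
    def all_knots(self) -> np.ndarray:
        """Boundary and interior knots, ascending."""
        lo, hi = self.boundary
        return np.concatenate([[lo], np.asarray(self.knots), [hi]])

    def evaluate(self, values: np.ndarray) -> np.ndarray:
        """Basis matrix with one row per value and ``df`` columns.

        Natural-cubic columns are C2 inside the boundary and continue
        linearly (zero curvature) outside it.
        """
        x = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("basis evaluation requires finite inputs")
        flat = x.ravel()
        if self.kind == "linear":
            out = flat[:, None].copy()
        elif self.kind == "indicator0":
            out = (flat == 0).astype(float)[:, None]
        elif self.kind == "natural-cubic":
            lo, hi = self.boundary
            clipped = np.clip(flat, lo, hi)
            full = self._spline(clipped)
            deriv = self._spline.derivative()
            below = flat < lo
            above = flat > hi
            if below.any():
                full[below] += (flat[below] - lo)[:, None] * deriv(lo)
            if above.any():
                full[above] += (flat[above] - hi)[:, None] * deriv(hi)
            # the K cardinal columns sum to 1 everywhere; dropping the first
            # removes the constant from the span while keeping dimension df
            out = full if self.include_intercept else full[:, 1:]
        else:  # pragma: no cover - guarded at construction
            raise ValueError(f"unknown basis kind {self.kind!r}")
        return out.reshape(x.shape + (self.df,)) if x.ndim > 1 else out

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "knots": list(self.knots),
            "boundary": list(self.boundary),
            "df": self.df,
            "include_intercept": self.include_intercept,
        }

    @staticmethod
    def from_dict(d: dict) -> "SplineBasis":
        if d["kind"] == "natural-cubic":
            return SplineBasis.natural_cubic(
                df=d["df"],
                boundary=tuple(d["boundary"]),
                knots=d["knots"],
                include_intercept=d["include_intercept"],
            )
        return SplineBasis(kind=d["kind"], df=1)


def natural_cubic_basis(
    values: np.ndarray,
    df: int,
    boundary: tuple[float, float] | None = None,
    knots: Sequence[float] | None = None,
) -> np.ndarray:
    """Natural cubic spline basis matrix (intercept excluded).

    ``df = 1`` is the no-interior-knot case: a single column affine in the
    input.  When ``knots`` is omitted, interior knots sit at equally spaced
    quantiles of ``values``; the boundary defaults to the observed range.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in spline input")
    if df > np.unique(x).size:
        raise ValueError(f"df={df} exceeds the number of distinct values ({np.unique(x).size})")
    if boundary is None:
        boundary = (float(x.min()), float(x.max()))
    basis = SplineBasis.natural_cubic(df=df, boundary=boundary, knots=knots, values=x)
    return basis.evaluate(x)


def _default_lag_knots(max_lag: int, n_interior: int) -> np.ndarray:
    """Interior lag knots equally spaced on the log(1+lag) scale.

    Concentrates resolution at short lags, where acute exposure effects live.
    """
    if n_interior <= 0:
        return np.empty(0)
    log_grid = np.linspace(0.0, np.log1p(max_lag), n_interior + 2)[1:-1]
    return np.expm1(log_grid)


@dataclass(frozen=True)
class CrossBasis:
    """Exposure x lag tensor-product design block for a DLNM.

    Row t of ``design`` is sum over lags l = 0..L of  b(X_{t-l}) (x) c(l),
    where b is the exposure basis and c the lag basis; exposure history
    before the first observed day is padded with the day-0 exposure (or the
    first L rows are dropped when ``incomplete="drop"``).  Columns are ordered
    exposure-major: column j*df_lag + k pairs exposure column j with lag
    column k.
    """

    exposure_basis: SplineBasis
    lag_basis: SplineBasis
    max_lag: int
    design: np.ndarray
    offset: int = 0  # rows of the source series dropped from the front

    @property
    def df_exposure(self) -> int:
        return self.exposure_basis.df

    @property
    def df_lag(self) -> int:
        return self.lag_basis.df

    def lag_matrix(self) -> np.ndarray:
        """Lag-basis matrix c(l), shape (max_lag+1, df_lag)."""
        return self.lag_basis.evaluate(np.arange(self.max_lag + 1.0))

    def contrast(self, exposure: float, reference: float) -> np.ndarray:
        """Per-lag contrast rows [b(x) - b(ref)] (x) c(l), shape (L+1, df_x*df_l)."""
        b = self.exposure_basis.evaluate(np.array([exposure, reference], float))
        db = b[0] - b[1]
        c = self.lag_matrix()
        return np.einsum("j,lk->ljk", db, c).reshape(self.max_lag + 1, -1)

    def to_dict(self) -> dict:
        return {
            "exposure_basis": self.exposure_basis.to_dict(),
            "lag_basis": self.lag_basis.to_dict(),
            "max_lag": self.max_lag,
            "offset": self.offset,
        }


def build_cross_basis(
    exposure,
    df_exposure: int = 3,
    df_lag: int = 4,
    max_lag: int = 30,
    exposure_kind: str = "natural-cubic",
    lag_kind: str = "natural-cubic",
    exposure_knots: Sequence[float] | None = None,
    exposure_boundary: tuple[float, float] | None = None,
    lag_knots: Sequence[float] | None = None,
    incomplete: str = "pad",
) -> CrossBasis:
    """Build the DLNM cross-basis from an exposure series.

    Parameters
    ----------
    exposure : array-like or DailySeries
        Daily exposure values in time order.
    df_exposure, df_lag : basis dimensions of the exposure and lag splines.
        The exposure basis excludes the intercept (identified separately by
        the model intercept); the lag basis includes it.
    max_lag : longest lag, in days, carried by the exposure history.
    exposure_kind, lag_kind : "natural-cubic", "linear", or (lag only)
        "indicator0".
    exposure_boundary : defaults to (min(0, observed min), observed max) so
        the zero-exposure reference used for relative risks stays inside the
        boundary.
    incomplete : {"pad", "drop"}
        "pad" fills pre-series history with the day-0 exposure; "drop"
        discards the first ``max_lag`` design rows instead.
    """
    x = np.asarray(getattr(exposure, "exposure", exposure), dtype=float)
    if x.ndim != 1:
        raise ValueError("exposure must be one-dimensional")
    n = x.size
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    if n <= max_lag:
        raise ValueError(f"series length {n} must exceed max_lag {max_lag}")
    if incomplete not in ("pad", "drop"):
        raise ValueError("incomplete must be 'pad' or 'drop'")

    if exposure_kind == "linear":
        if df_exposure != 1:
            raise ValueError("linear exposure basis has df_exposure = 1")
        exp_basis = SplineBasis.linear()
    elif exposure_kind == "natural-cubic":
        if exposure_boundary is None:
            exposure_boundary = (min(0.0, float(x.min())), float(x.max()))
        exp_basis = SplineBasis.natural_cubic(
            df=df_exposure,
            boundary=exposure_boundary,
            knots=exposure_knots,
            values=x,
        )
    else:
        raise ValueError(f"unsupported exposure basis kind {exposure_kind!r}")

    if lag_kind == "indicator0":
        if df_lag != 1:
            raise ValueError("indicator0 lag basis has df_lag = 1")
        lag_basis = SplineBasis.indicator0()
    elif lag_kind == "linear":
        # intercept + slope over lags
        if df_lag != 2:
            raise ValueError("linear lag basis has df_lag = 2 (intercept + slope)")
        lag_basis = SplineBasis.natural_cubic(
            df=2, boundary=(0.0, float(max(max_lag, 1))), include_intercept=True
        )
    elif lag_kind == "natural-cubic":
        if max_lag == 0:
            raise ValueError("natural-cubic lag basis needs max_lag >= 1; use indicator0")
        if lag_knots is None:
            lag_knots = _default_lag_knots(max_lag, df_lag - 2)
        lag_basis = SplineBasis.natural_cubic(
            df=df_lag,
            boundary=(0.0, float(max_lag)),
            knots=lag_knots,
            include_intercept=True,
        )
    else:
        raise ValueError(f"unsupported lag basis kind {lag_kind!r}")

    # lagged exposure matrix Q[t, l] = X_{t-l}, padded with X_0 before day 0
    idx = np.arange(n)[:, None] - np.arange(max_lag + 1)[None, :]
    q = x[np.clip(idx, 0, None)]
    b = exp_basis.evaluate(q.ravel()).reshape(n, max_lag + 1, exp_basis.df)
    c = lag_basis.evaluate(np.arange(max_lag + 1.0))
    design = np.einsum("tlj,lk->tjk", b, c).reshape(n, exp_basis.df * lag_basis.df)

    offset = 0
    if incomplete == "drop":
        design = design[max_lag:]
        offset = max_lag
    return CrossBasis(
        exposure_basis=exp_basis,
        lag_basis=lag_basis,
        max_lag=max_lag,
        design=design,
        offset=offset,
    )
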