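"""Residual diagnostics used for smoothing-df selection and model comparison."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["pacf", "compare_aic"]


def pacf(residuals: np.ndarray, max_lag: int = 30) -> np.ndarray:
    """Partial autocorrelations at lags 1..max_lag by successive regressions.

    Entry k is the coefficient of the lag-k regressor when the series is
    regressed (with intercept, ordinary least squares) on its lags 1..k —
    the regression definition of the PACF.
    """
    x = np.asarray(residuals, float)
    n = x.size
    if max_lag >= n / 2:
        raise ValueError(f"max_lag {max_lag} must be < length/2 = {n / 2:g}")
    if np.ptp(x) == 0:
        raise ValueError("PACF undefined for a constant series")
    out = np.empty(max_lag)
    for k in range(1, max_lag + 1):
        y = x[k:]
        lagmat = np.column_stack([np.ones(n - k)] + [x[k - j : n - j] for j in range(1, k + 1)])
        coef, *_ = np.linalg.lstsq(lagmat, y, rcond=None)
        out[k - 1] = coef[-1]
    return out


def compare_aic(fits) -> pd.DataFrame:
    """Rank fitted models by AIC (ascending), with a delta-AIC column.

    All fits must be on the same response series; mismatches are detected by
    comparing response checksums.  Ties keep the input order (stable sort).
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    checksums = {np.asarray(f.response, float).tobytes() for f in fits}
    if len(checksums) > 1:
        raise ValueError("fits are not on identical response data; AIC not comparable")
    table = pd.DataFrame(
        {
            "model": [getattr(f, "name", f"model{i}") for i, f in enumerate(fits)],
            "aic": [f.aic for f in fits],
            "n_params": [len(f.params) for f in fits],
        }
    )
    table = table.sort_values("aic", kind="stable").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return table
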