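"""Summary statistics and the Spearman correlation matrix with significance stars."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import DailySeries

__all__ = ["summarize", "spearman_matrix", "CorrelationMatrix"]

_UNITS = {
    "temperature": "degC",
    "dew": "degC",
    "humidity": "%",
    "wind": "m/s",
    "pressure": "",
    "precipitation": "mm",
    "pollen": "grains/1000 mm^2",
    "count": "visits/day",
}


def _variables(series: DailySeries) -> dict[str, np.ndarray]:
    out = {name: series.covariate(name) for name in series.covariate_names}
    out["pollen"] = series.exposure
    out["count"] = series.counts.astype(float)
    return out


def summarize(series: DailySeries) -> pd.DataFrame:
    """One descriptive row per variable: mean, median, SD (n-1), range, quartiles."""
    if len(series) == 0:
        raise ValueError("empty series")
    rows = []
    for name, v in _variables(series).items():
        rows.append(
            {
                "variable": name,
                "unit": _UNITS.get(name, ""),
                "mean": float(np.mean(v)),
                "median": float(np.median(v)),
                "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
                "min": float(np.min(v)),
                "max": float(np.max(v)),
                "p25": float(np.percentile(v, 25)),
                "p75": float(np.percentile(v, 75)),
            }
        )
    return pd.DataFrame(rows)


class CorrelationMatrix:
    """Spearman rho / p matrices with the conventional star coding."""

    def __init__(self, names: list[str], rho: np.ndarray, p: np.ndarray):
        self.names = names
        self.rho = rho
        self.p = p

    def stars(self) -> pd.DataFrame:
        """rho rendered with * (p<0.05) / ** (p<0.01) marks, upper triangle."""
        n = len(self.names)
        cells = np.full((n, n), "", dtype=object)
        for i in range(n):
            for j in range(i, n):
                mark = "**" if self.p[i, j] < 0.01 else "*" if self.p[i, j] < 0.05 else ""
                cells[i, j] = f"{self.rho[i, j]:.3f}{mark if i != j else ''}"
        return pd.DataFrame(cells, index=self.names, columns=self.names)

    def rho_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.names, columns=self.names)

    def p_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p, index=self.names, columns=self.names)


def spearman_matrix(series: DailySeries) -> CorrelationMatrix:
    """Pairwise Spearman correlations (mid-rank ties) with two-sided t-approx p.

    rho is the Pearson correlation of average ranks; p comes from
    t = rho sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom — the standard
    large-sample approximation.  Zero-variance variables make rho undefined;
    those entries are returned as NaN.
    """
    data = _variables(series)
    names = list(data)
    n_obs = len(series)
    if n_obs < 4:
        raise ValueError("need at least 4 observations per variable")
    mat = np.column_stack(list(data.values()))
    k = mat.shape[1]
    rho = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if np.ptp(mat[:, i]) == 0 or np.ptp(mat[:, j]) == 0:
                rho[i, j] = rho[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            r, pv = stats.spearmanr(mat[:, i], mat[:, j])
            rho[i, j] = rho[j, i] = r
            p[i, j] = p[j, i] = pv
    return CorrelationMatrix(names, rho, p)
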