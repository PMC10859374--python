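"""The daily observation table: event counts, exposure, and covariates."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: meteorological covariates carried by a full daily series
MET_COVARIATES = ("temperature", "dew", "humidity", "wind", "pressure", "precipitation")

REQUIRED_COLUMNS = ("date", "count", "pollen")


@dataclass
class DailySeries:
    """One row per calendar day: count, pollen exposure, covariates, calendar flags.

    ``frame`` is indexed 0..n-1 (the day index t) and holds columns ``date``
    (datetime), ``count`` (non-negative int), ``pollen`` (grains/1000 mm^2,
    >= 0), any subset of the meteorological covariates, ``holiday`` (bool)
    and ``dow`` (1=Monday .. 7=Sunday, derived from the date).
    """

    frame: pd.DataFrame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, holidays: set | None = None) -> "DailySeries":
        """Validate and normalize a raw daily table.

        Checks: required columns present, dates consecutive calendar days,
        counts non-negative integers, pollen non-negative, humidity within
        [0, 100]; derives ``dow`` and, if absent, ``holiday``.
        """
        df = frame.copy().reset_index(drop=True)
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        df["date"] = pd.to_datetime(df["date"])
        gaps = df["date"].diff().dt.days.iloc[1:]
        if (gaps != 1).any():
            bad = df["date"].iloc[int(np.argmax(gaps.to_numpy() != 1)) + 1]
            raise ValueError(f"calendar gap or disorder at {bad.date()}: days must be consecutive")
        counts = df["count"].to_numpy()
        if np.any(counts < 0) or np.any(counts != np.floor(counts)):
            row = int(np.argmax((counts < 0) | (counts != np.floor(counts))))
            raise ValueError(f"column 'count' must hold non-negative integers (row {row})")
        df["count"] = counts.astype(int)
        if (df["pollen"].to_numpy() < 0).any():
            raise ValueError("column 'pollen' must be non-negative")
        if "humidity" in df.columns:
            h = df["humidity"].to_numpy(float)
            if np.any((h < 0) | (h > 100)):
                raise ValueError("humidity must lie in [0, 100]")
        covs = [c for c in MET_COVARIATES if c in df.columns]
        if df[["count", "pollen", *covs]].isna().any().any():
            raise ValueError("missing values are not allowed")
        df["dow"] = df["date"].dt.dayofweek + 1
        if "holiday" not in df.columns:
            hol = holidays or set()
            df["holiday"] = df["date"].dt.date.map(lambda d: d in hol)
        df["holiday"] = df["holiday"].astype(bool)
        return cls(frame=df)

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def counts(self) -> np.ndarray:
        return self.frame["count"].to_numpy(int)

    @property
    def exposure(self) -> np.ndarray:
        """Pollen concentration, grains/1000 mm^2."""
        return self.frame["pollen"].to_numpy(float)

    @property
    def dow(self) -> np.ndarray:
        return self.frame["dow"].to_numpy(int)

    @property
    def holiday(self) -> np.ndarray:
        return self.frame["holiday"].to_numpy(bool)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in MET_COVARIATES if c in self.frame.columns]

    def covariate(self, name: str) -> np.ndarray:
        if name not in self.covariate_names:
            raise KeyError(f"unknown covariate {name!r}; have {self.covariate_names}")
        return self.frame[name].to_numpy(float)

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        cols = ["date", "count", "pollen", *self.covariate_names, "holiday"]
        out[cols].to_csv(path, index=False)
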