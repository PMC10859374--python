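import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pollenlag import DailySeries, ModelSpec, PoissonDLNM, SimulationConfig, generate

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_series(counts, pollen=None, start="2019-04-01", **covariates) -> DailySeries:
    """Minimal valid daily series for small fixtures."""
    counts = np.asarray(counts)
    n = counts.size
    frame = pd.DataFrame(
        {
            "date": pd.date_range(start, periods=n, freq="D"),
            "count": counts,
            "pollen": np.asarray(pollen) if pollen is not None else np.linspace(1, 50, n),
            **{k: np.asarray(v) for k, v in covariates.items()},
        }
    )
    return DailySeries.from_frame(frame)


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic series with its generating truth."""
    return generate(SimulationConfig())


@pytest.fixture(scope="session")
def fitted(default_sim):
    """Default model fitted (PACF-selected time df) to the default series."""
    series, _ = default_sim
    return PoissonDLNM(series).fit()


@pytest.fixture(scope="session")
def small_spec():
    """Cheap fixed-df spec for simulation loops."""
    return ModelSpec(time_df=4)
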