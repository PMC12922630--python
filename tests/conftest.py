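import numpy as np
import pandas as pd
import pytest

from hazardheat.synthetic import ClimateGenParams, generate_climate, mini_continental
from hazardheat.wbgt import WbgtTransformParams


@pytest.fixture(scope="session")
def default_params():
    return WbgtTransformParams()


@pytest.fixture(scope="session")
def small_climate():
    """A 3x3 grid, 2 years of daily climate, fixed seed."""
    params = ClimateGenParams(n_lat=3, n_lon=3, n_years=2, seed=11)
    grid, truth = generate_climate(params)
    return params, grid, truth


@pytest.fixture(scope="session")
def mini():
    """The documented mini-continental scenario (3 states, 60 facilities, 39 yr)."""
    return mini_continental(seed=7)


@pytest.fixture
def flat_year():
    """One non-leap year of dates."""
    return pd.date_range("2017-01-01", "2017-12-31", freq="D")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
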