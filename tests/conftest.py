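import numpy as np
import pandas as pd
import pytest

from thermofr.depletion import FRParams, MortalityParams
from thermofr.thermal import ArrheniusRate


@pytest.fixture
def type2_params():
    """A generic type II response: c0=1/day, b0=0.5 d, both athermal."""
    return FRParams("II", ArrheniusRate(1.0, 0.0), ArrheniusRate(0.5, 0.0))


@pytest.fixture
def small_trials():
    """Six predator arenas in two datasets at the reference temperature."""
    return pd.DataFrame({
        "dataset_id": ["a", "a", "a", "b", "b", "b"],
        "predator_present": [True] * 6,
        "temperature_C": [10.0] * 6,
        "n0": [10, 20, 30, 10, 20, 30],
        "n_survivors": [6, 13, 21, 7, 15, 22],
        "duration_days": [1.0] * 6,
    })


@pytest.fixture
def no_mortality():
    return {"a": MortalityParams(), "b": MortalityParams()}
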