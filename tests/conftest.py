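import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_phantom():
    """One rendered phantom at the default (healthy, EF 55%) parameters."""
    from hcsa.synth import PhantomParams, simulate_heart_series

    params = PhantomParams(noise_sd=0.05, seed=7)
    series, rois, truth = simulate_heart_series(params)
    return params, series, rois, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
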