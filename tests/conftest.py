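import numpy as np
import pytest

from hrvpipe.signal_prep import RRSeries
from hrvpipe.synthetic_cohort import RRGenParams, generate_rr_series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_recording():
    """A clean 32-min synthetic recording (no artifacts): both analysis
    windows pass the SQI gate without fallback."""
    return generate_rr_series(RRGenParams(duration=1920.0), seed=42)


@pytest.fixture
def constant_rr():
    """Metronomic 800-ms beats for 11 minutes."""
    n = 825
    rr = np.full(n, 800.0)
    times = np.cumsum(rr) / 1000.0
    return RRSeries(times, rr, subject="const", visit="first")


def gaussian_ar1(n, rho, seed):
    """Stationary unit-variance Gaussian AR(1) with lag-1 correlation rho."""
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    innov = rng.standard_normal(n) * np.sqrt(1.0 - rho ** 2)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + innov[i]
    return x
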