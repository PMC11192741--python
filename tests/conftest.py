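import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SAMPLING_DAYS = [0, 1, 2, 5, 8, 12]


@pytest.fixture
def sampling_days():
    """The incubation subsampling schedule (days)."""
    return list(SAMPLING_DAYS)


def ols_slope_oracle(t, y):
    """Brute-force least squares via the normal equations, written longhand
    so it shares nothing with scipy's implementation."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n = t.size
    sxx = np.sum(t * t) - np.sum(t) ** 2 / n
    sxy = np.sum(t * y) - np.sum(t) * np.sum(y) / n
    slope = sxy / sxx
    intercept = (np.sum(y) - slope * np.sum(t)) / n
    resid = y - intercept - slope * t
    sem = np.sqrt(np.sum(resid**2) / (n - 2) / sxx) if n > 2 else np.nan
    return slope, intercept, sem
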