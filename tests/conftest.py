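import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from glucodyn.series import GlucoseSeries

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_series():
    """Factory wrapping raw values into a GlucoseSeries at 5-min sampling."""

    def _make(values, interval_min=5.0, subject_id="test", group=None):
        return GlucoseSeries(
            subject_id=subject_id,
            values=np.asarray(values, dtype=float),
            interval_min=interval_min,
            group=group,
        )

    return _make


@pytest.fixture
def constant_series(make_series):
    return make_series(np.full(600, 5.0))


@pytest.fixture
def random_series(make_series, rng):
    """A positive, mildly autocorrelated 576-point series."""
    steps = rng.standard_normal(576)
    vals = 7.0 + np.convolve(steps, np.ones(4) / 4.0, mode="same")
    return make_series(np.clip(vals, 2.5, None))
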