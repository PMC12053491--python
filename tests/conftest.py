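import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from circascan import SyntheticConfig, UniformSeries, generate_series

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def cosine_series():
    """Pure 24 h cosine, 240 h at 2-min sampling, no trend or noise."""
    cfg = SyntheticConfig(
        duration_h=240.0, trend_coeffs=(0.0,), osc_amplitude=1.0,
        osc_period_h=24.0, noise_sigma=0.0, noise_alpha=0.0, seed=0,
    )
    return generate_series(cfg)


@pytest.fixture()
def wt_series():
    """Default wild-type-like synthetic series (trend + 24 h + red noise)."""
    return generate_series(SyntheticConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_series(values, dt_h=0.1, t0=0.0):
    return UniformSeries.from_values(values, dt_h=dt_h, t0=t0)
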