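import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_grating(angle_deg: float, size: int = 128, period_px: float = 16.0) -> np.ndarray:
    """Sinusoidal grating with stripes along ``angle_deg`` (axial convention)."""
    x = np.arange(size, dtype=float)
    X, Y = np.meshgrid(x, x)
    a = np.radians(angle_deg)
    phase = (-np.sin(a) * X + np.cos(a) * Y) / period_px
    return 0.5 + 0.4 * np.sin(2.0 * np.pi * phase)


@pytest.fixture(scope="session")
def grating():
    return make_grating


@pytest.fixture(scope="session")
def default_scheme():
    from histodti import phantom

    return phantom.make_scheme(n_directions=60, n_b0=6, b=3000.0, seed=0)


@pytest.fixture(scope="session")
def phantom_run():
    """One shared end-to-end phantom run at the default study conditions."""
    from histodti.pipeline import run_phantom_pipeline

    return run_phantom_pipeline(seed=1)
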