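import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tritone import TTSParams, generate_phantom, severity_preset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def severe_phantom():
    """Noise-free severe phantom: ground truth delta_FL=0.25, delta_PL=0.35."""
    spec = severity_preset("severe", noise_sd=0.0, seed=7)
    volume, boundaries = generate_phantom(spec)
    return spec, volume, boundaries


@pytest.fixture(scope="session")
def severe_params():
    return TTSParams(severity="severe")


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
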