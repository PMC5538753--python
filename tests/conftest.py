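import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stressim import REFERENCE_PARAMS, TREATMENT_PARAMS

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def reference_params():
    """Single-stress cycling benchmark: s=1, sigma=100, mu_M=1e-3, mu_R=1e-2, nu_R=1e-4."""
    return REFERENCE_PARAMS


@pytest.fixture
def treatment_params():
    """Multi-drug comparison set: s=0.5, sigma=100, mu_M=1e-3, mu_R=5e-3, nu_R=1e-4."""
    return TREATMENT_PARAMS


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
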