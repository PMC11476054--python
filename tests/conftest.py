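import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plastevo import ModelParams

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_params():
    """Smallest convenient model: 2 systems of 3 elements, 6 loci."""
    return ModelParams(N=8, n_g=5, L=6, A=2, P_e=6, C=3,
                       mu=0.05, p_e=0.5, t=2, seed=7)
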