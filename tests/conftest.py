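import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20140036)


@pytest.fixture(scope="session")
def model_a_ensemble():
    """Small shared model-A ensemble (mu=100) for engine-level statistics."""
    import md2bd
    return md2bd.run_model_A(mu=100, gamma=10, D=1, L=10, dt=1e-5,
                             t_end=0.5, n_realizations=200, seed=11,
                             save_every=250)
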