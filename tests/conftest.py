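import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def coupled_dyad():
    """Two-user community with a planted Single coupling 0 -> 1 (kappa 0.8)."""
    from emotrain.synthetic import SyntheticConfig, generate_community

    cfg = SyntheticConfig(n_users=2, n_steps=5000, coupling_edges=[(0, 1, 0.8)], seed=7)
    return generate_community(cfg)


@pytest.fixture
def small_community():
    """Six users, two planted Single dyads, short timeline."""
    from emotrain.synthetic import SyntheticConfig, generate_community

    cfg = SyntheticConfig(
        n_users=6, n_steps=400,
        coupling_edges=[(0, 1, 0.9), (2, 3, 0.9)],
        n_control_dyads=2, seed=11,
    )
    return generate_community(cfg)
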