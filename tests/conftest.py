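import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def rw_ensemble():
    """A 48-walker 2-D random-walk ensemble evolved a few cycles (no resampling)."""
    from revowe.randomwalk import RandomWalkDynamics, RWParams, make_initial_ensemble

    dynamics = RandomWalkDynamics(RWParams(n_dims=2))
    ens = make_initial_ensemble(48, 2)
    gen = np.random.default_rng(7)
    for _ in range(5):
        ens = dynamics(ens, gen)
    return ens
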