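import pytest
from hypothesis import settings

import duckreq as dq

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    return dq.ModelParameters()


@pytest.fixture(scope="session")
def clean_obs():
    """Small noise-free synthetic flock (winter scenario)."""
    cfg = dq.SimulationConfig(seed=7, n_ducks=10, obs_noise_sd=0.0)
    return cfg, dq.generate_observations(cfg)


@pytest.fixture(scope="session")
def noisy_obs():
    """Default-condition synthetic flock: 200 trajectories, 5 % noise."""
    cfg = dq.SimulationConfig(seed=11)
    return cfg, dq.generate_observations(cfg)
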