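import numpy as np
import pytest
from hypothesis import settings

from agbpot.forest import ForestParams
from agbpot.grid import GridSpec
from agbpot.synthetic import WorldConfig, generate_world

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")

SMALL_GRID = GridSpec(-12.0, -5.0, -68.0, -61.0, 0.25)  # 28 x 28


@pytest.fixture(scope="session")
def small_world():
    """A 28×28, 20-year world at the default study conditions."""
    return generate_world(WorldConfig(grid=SMALL_GRID, seed=7))


@pytest.fixture(scope="session")
def clean_world():
    """Noise-free, undisturbed world: observations equal the potential."""
    return generate_world(WorldConfig(
        grid=SMALL_GRID, seed=11, disturbance_intensity=0.0,
        obs_noise_sd=0.0, obs_spread=0.0, water_fraction=0.0))


@pytest.fixture(scope="session")
def fast_params():
    return ForestParams(n_trees=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
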