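import numpy as np
import pytest

from dualres import IntegratorConfig, ModelParams, QGrid, SystemState


@pytest.fixture(scope="session")
def grid():
    return QGrid.default()


@pytest.fixture
def base_params():
    """Endemic-only parameter core used by the single-pathogen experiments."""
    return ModelParams(b=1.5, mu=0.2, gamma=0.01, beta_e=1.0, theta=0.5)


@pytest.fixture
def config():
    return IntegratorConfig()


@pytest.fixture
def endemic_start(grid):
    """One susceptible host at q = 0 plus one endemic-infected host."""
    state = SystemState.zeros(grid)
    state.S[0] = 1.0
    state.I_e = 1.0
    return state


def random_state(grid, rng, infected=True):
    """Random strictly positive state used by property-style checks."""
    state = SystemState(
        rng.uniform(0.0, 5.0, grid.n),
        rng.uniform(0.0, 5.0, grid.n),
        rng.uniform(0.0, 10.0) if infected else 0.0,
        rng.uniform(0.0, 10.0) if infected else 0.0,
    )
    return state
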