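import numpy as np
import pytest

import discsim
from discsim import runner


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def relaxed_disc():
    """A small mechanically relaxed disc shared across read-only tests."""
    return discsim.init_disc(250, target_radius=20.0, seed=7)


@pytest.fixture(scope="session")
def short_wildtype_state():
    """A 150-step wild-type run on a small disc (read-only fixture)."""
    sc = runner.build_scenario(discsim.ScenarioConfig())
    state = runner.init_state(sc, n_cells=200, target_radius=18.0, seed=5)
    for _ in range(150):
        runner.step(state)
    return state
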