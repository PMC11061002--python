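import numpy as np
import pytest

from harvestgame.game import GameConfig
from harvestgame.mdp import SolverConfig, TransitionModel, build_transition_model, solve


@pytest.fixture(scope="session")
def default_game() -> GameConfig:
    return GameConfig()


@pytest.fixture(scope="session")
def default_model(default_game) -> TransitionModel:
    return build_transition_model(default_game)


@pytest.fixture(scope="session")
def optimal_table(default_model):
    """Average-reward solution of the default game, solved once per session."""
    return solve(default_model, SolverConfig())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
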