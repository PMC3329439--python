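import hypothesis
import numpy as np
import pytest

from stgames import Game, ImitationRule, enumerate_strategies, payoff_matrix

hypothesis.settings.register_profile("deterministic", derandomize=True)
hypothesis.settings.load_profile("deterministic")

PD_GAME = Game(S=-0.5, T=1.5)
HARMONY_GAME = Game(S=0.5, T=0.5)


@pytest.fixture(scope="session")
def pd_game():
    return PD_GAME


@pytest.fixture(scope="session")
def harmony_game():
    return HARMONY_GAME


@pytest.fixture(scope="session")
def strategies():
    return enumerate_strategies(0.01)


@pytest.fixture(scope="session")
def pd_payoffs(pd_game):
    return payoff_matrix(pd_game, 0.01)


@pytest.fixture(scope="session")
def pd_rule(pd_payoffs):
    return ImitationRule.from_payoff_matrix(pd_payoffs)


@pytest.fixture(scope="session")
def harmony_rule(harmony_game):
    return ImitationRule.from_payoff_matrix(payoff_matrix(HARMONY_GAME, 0.01))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
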