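import numpy as np
import pytest

from zdgames import donation_game, make_payoffs, named_strategy


@pytest.fixture(scope="session")
def conventional():
    """Conventional IPD payoffs (T + S > 2P)."""
    return make_payoffs(3, 0, 5, 1)


@pytest.fixture(scope="session")
def adversarial():
    """Adversarial payoffs with T + S < 2P, where extortion backfires."""
    return make_payoffs(1, -3, 2, 0)


@pytest.fixture(scope="session")
def donation():
    """Donation game b=4, c=1 used in the learning dynamics."""
    return donation_game(4, 1)


@pytest.fixture(scope="session")
def pso():
    return named_strategy("PSO_GAMBLER")


@pytest.fixture(scope="session")
def wsls():
    return named_strategy("WSLS")


@pytest.fixture(scope="session")
def tft():
    return named_strategy("TFT")


@pytest.fixture()
def rng():
    return np.random.default_rng(20230525)
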