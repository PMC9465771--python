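import numpy as np
import pytest

from stripforge import toy


@pytest.fixture(scope="session")
def toy_label_map():
    """A small 32^3 head phantom shared across tests."""
    return toy.toy_phantom(1)


@pytest.fixture(scope="session")
def toy_sdt_model():
    """SDT-regression model trained at toy scale (expensive; train once)."""
    return toy.train_toy_model("sdt", seed=7).net


@pytest.fixture(scope="session")
def toy_dice_model():
    """Soft-Dice model trained at toy scale (expensive; train once)."""
    return toy.train_toy_model("dice", seed=7).net


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
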