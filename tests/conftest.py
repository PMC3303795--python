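import numpy as np
import pytest

from rotlib import fixtures


@pytest.fixture(scope="session")
def toy1():
    return fixtures.load_topology("TOY1"), fixtures.params_for("TOY1")


@pytest.fixture(scope="session")
def toy2():
    return fixtures.load_topology("TOY2"), fixtures.params_for("TOY2")


@pytest.fixture(scope="session")
def val():
    return fixtures.load_topology("VAL"), fixtures.params_for("VAL")


@pytest.fixture(scope="session")
def leu():
    return fixtures.load_topology("LEU"), fixtures.params_for("LEU")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
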