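import numpy as np
import pytest

from twistgate import synthetic_data as sd


@pytest.fixture(scope="session")
def base_config():
    return sd.GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def chain5():
    """Five bonded atoms with angles, dihedrals and nonbonded terms."""
    return sd.make_toy_system(sd.GeneratorConfig(seed=7), preset="chain5")


@pytest.fixture(scope="session")
def channel():
    return sd.make_channel(sd.GeneratorConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
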