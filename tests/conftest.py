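import numpy as np
import pytest

from trackchem import chem, irt


@pytest.fixture(scope="session")
def network():
    return chem.default_network()


@pytest.fixture(scope="session")
def pure_water_system(network):
    """Compiled system for azide-free, air-saturated water."""
    return irt.compile_system(network, irt.make_scavenger_map(azide_M=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)
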