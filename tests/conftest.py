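import numpy as np
import pytest

from rsk import fixtures as fx
from rsk import motiflib as ml


@pytest.fixture(scope="session")
def toy_config():
    return fx.FixtureConfig(seed=0)


@pytest.fixture(scope="session")
def tetrad_array(toy_config):
    return fx.make_toy_catalytic_array("ra_tetrad", toy_config)


@pytest.fixture(scope="session")
def triad_array(toy_config):
    return fx.make_toy_catalytic_array("mbh_triad", toy_config)


@pytest.fixture(scope="session")
def rotamer_library(toy_config):
    return fx.make_toy_rotamer_library(toy_config)


@pytest.fixture(scope="session")
def helix7():
    return fx.make_ideal_helix(7)


@pytest.fixture(scope="session")
def tetrad_library(tetrad_array, rotamer_library, helix7):
    return ml.build_motif_library(
        tetrad_array, rotamer_library, [helix7],
        ml.MotifLibraryConfig(max_out=10))


@pytest.fixture(scope="session")
def tetrad_assembly(tetrad_library):
    assert tetrad_library.assemblies
    return tetrad_library.assemblies[0]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
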