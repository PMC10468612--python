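import numpy as np
import pytest

import hybridzone as hz
from hybridzone.cline import ClineModel
from hybridzone.synthetic_data import ZoneSimConfig, simulate_zone


@pytest.fixture(scope="session")
def table1():
    return hz.load_table1_fixture()


@pytest.fixture(scope="session")
def table1_transect(table1):
    """Signed-distance transect on the natural-range fixture (42 localities)."""
    return hz.build_transect(table1.natural_range())


@pytest.fixture(scope="session")
def small_zone():
    """A compact simulated hybrid zone: 9 localities, 12 individuals each,
    width 3 km, independent loci."""
    cfg = ZoneSimConfig(
        seed=42,
        positions_km=np.linspace(-20, 20, 9),
        n_per_locality=12,
        cline=ClineModel(c=0.0, w=3.0),
    )
    return simulate_zone(cfg)


@pytest.fixture
def tiny_panel():
    dosage = np.array([[0, 0, 0], [1, 0, 2], [2, 2, 2], [2, 2, hz.MISSING]], dtype=np.int8)
    return hz.GenotypePanel(
        ["a", "b", "c", "d"], ["west", "west", "east", "east"],
        ["m1", "m2", "m3"], dosage,
    )
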