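import numpy as np
import pytest

from opershape.phylo import TimeTree
from opershape.shapes import LandmarkConfiguration, LandmarkDataset
from opershape.synthetic_data import SimulationScenario, simulate_shape_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20231107)


@pytest.fixture
def balanced4_tree():
    return TimeTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def star4_tree():
    return TimeTree.from_newick("(A:1,B:1,C:1,D:1);")


@pytest.fixture
def small_dataset(rng):
    """Ten random 18-point configurations across five taxa."""
    base = rng.normal(size=(18, 2))
    configs = []
    for i in range(10):
        coords = base + 0.05 * rng.normal(size=(18, 2))
        configs.append(
            LandmarkConfiguration(
                specimen_id=f"sp{i}", taxon=f"tax{i % 5}", coords=coords
            )
        )
    return LandmarkDataset(configs)


@pytest.fixture(scope="session")
def bm16():
    """A 16-taxon Brownian-motion dataset with ground truth."""
    scenario = SimulationScenario(n_taxa=16, seed=42)
    return simulate_shape_dataset(scenario)
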