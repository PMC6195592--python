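import pytest

from coaldiscord.discordance import bovine_class_scheme
from coaldiscord.msc import simulate_topology_distribution
from coaldiscord.synth import bovini_preset
from coaldiscord.trees import bovine_taxa, enumerate_topologies

NUCLEAR_NEWICK = "((((bison,wisent),yak),(taurine,zebu)),buffalo);"
MT_NEWICK = "((((taurine,zebu),wisent),(bison,yak)),buffalo);"


@pytest.fixture(scope="session")
def taxa():
    return bovine_taxa()


@pytest.fixture(scope="session")
def scheme(taxa):
    return bovine_class_scheme(taxa)


@pytest.fixture(scope="session")
def topology_space(taxa):
    return enumerate_topologies(taxa)


@pytest.fixture(scope="session")
def preset():
    return bovini_preset()


@pytest.fixture(scope="session")
def preset_sample(preset):
    """A shared 20k-tree topology sample from the calibrated preset."""
    return simulate_topology_distribution(preset, 20_000, seed=20_240)
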