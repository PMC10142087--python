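import networkx as nx
import pytest

from netpharm.synth import GeneratorConfig, generate_study


@pytest.fixture(scope="session")
def study():
    """One default-configuration synthetic study reused across tests."""
    return generate_study(GeneratorConfig(seed=11))


@pytest.fixture()
def triangle():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("A", "C")])
    return g


@pytest.fixture()
def star5():
    """Star: center HUB with 4 leaves."""
    g = nx.Graph()
    g.add_edges_from([("HUB", leaf) for leaf in ("L1", "L2", "L3", "L4")])
    return g
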