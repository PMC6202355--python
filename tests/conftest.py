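import pytest

from lcpnet import UndirectedNetwork, worked_graph
from lcpnet.synthetic import erdos_renyi


@pytest.fixture
def g0() -> UndirectedNetwork:
    """The 6-node worked graph with every local-community link class."""
    return worked_graph()


@pytest.fixture
def triangle() -> UndirectedNetwork:
    return UndirectedNetwork([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def six_cycle() -> UndirectedNetwork:
    nodes = ["a", "b", "c", "d", "e", "f"]
    return UndirectedNetwork(
        [(nodes[i], nodes[(i + 1) % 6]) for i in range(6)]
    )


@pytest.fixture
def er_graphs() -> list[UndirectedNetwork]:
    """A small pool of random graphs for fuzz checks."""
    return [erdos_renyi(30, 0.12, seed=s) for s in range(8)]
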