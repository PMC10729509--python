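import networkx as nx
import pytest

from targetnet.network import Network


def make_network(edges, nodes=()) -> Network:
    """Build a Network directly from (a, b) pairs with score 1.0."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a, b in edges:
        g.add_edge(a, b, score=1.0)
    return Network(graph=g)


@pytest.fixture
def path_abc() -> Network:
    return make_network([("A", "B"), ("B", "C")])


@pytest.fixture
def star_k14() -> Network:
    return make_network([("c", leaf) for leaf in ("l1", "l2", "l3", "l4")])


@pytest.fixture
def k6_plus_path() -> Network:
    """A 6-clique bridged to a 10-node path (planted dense structure)."""
    clique = [f"K{i}" for i in range(6)]
    edges = [(a, b) for i, a in enumerate(clique) for b in clique[i + 1 :]]
    path = [f"P{i}" for i in range(10)]
    edges += [("K0", path[0])]
    edges += list(zip(path, path[1:]))
    return make_network(edges)


@pytest.fixture
def two_k5() -> Network:
    edges = []
    for prefix in ("A", "B"):
        clique = [f"{prefix}{i}" for i in range(5)]
        edges += [(a, b) for i, a in enumerate(clique) for b in clique[i + 1 :]]
    return make_network(edges)
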