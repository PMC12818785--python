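import networkx as nx
import pytest


def graph_from_edges(*edges, nodes=(), name="fixture"):
    """Build a simple undirected graph from ('a','b') pairs."""
    g = nx.Graph(name=name)
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    g.graph["name"] = name
    return g


def labelled(g, name):
    """Relabel an integer networkx graph to string ids v0..vN-1."""
    out = nx.relabel_nodes(g, {i: f"v{i:02d}" for i in g.nodes()})
    out.graph["name"] = name
    return out


@pytest.fixture
def single_edge():
    return graph_from_edges(("a", "b"), name="P2")


@pytest.fixture
def star6():
    return labelled(nx.star_graph(5), "star6")  # hub v00, 5 leaves


@pytest.fixture
def k6():
    return labelled(nx.complete_graph(6), "K6")


@pytest.fixture
def k10():
    return labelled(nx.complete_graph(10), "K10")


@pytest.fixture
def cycle6():
    return labelled(nx.cycle_graph(6), "C6")


@pytest.fixture
def path3():
    return graph_from_edges(("a", "b"), ("b", "c"), name="P3")
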