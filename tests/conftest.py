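"""Shared graph fixtures: small hand-traceable topologies."""

import networkx as nx
import pytest


def clique(prefix: str, n: int) -> nx.Graph:
    g = nx.Graph()
    nodes = [f"{prefix}{i}" for i in range(n)]
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            g.add_edge(u, v)
    return g


def union(*graphs: nx.Graph) -> nx.Graph:
    out = nx.Graph()
    for g in graphs:
        out.add_nodes_from(g.nodes())
        out.add_edges_from(g.edges())
    return out


@pytest.fixture
def k4() -> nx.Graph:
    return clique("a", 4)


@pytest.fixture
def k3() -> nx.Graph:
    return clique("a", 3)


@pytest.fixture
def two_k5_bridge() -> nx.Graph:
    """Two 5-cliques joined by a single bridge edge a0-b0."""
    g = union(clique("a", 5), clique("b", 5))
    g.add_edge("a0", "b0")
    return g


@pytest.fixture
def two_k4_bridge() -> nx.Graph:
    """Two 4-cliques joined by a single bridge edge a0-b0."""
    g = union(clique("a", 4), clique("b", 4))
    g.add_edge("a0", "b0")
    return g


def random_simple_graph(rng, n_max: int = 12) -> nx.Graph:
    """Small random graph with string node names, for oracle comparisons."""
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.1, 0.9))
    g = nx.Graph()
    names = [f"n{i:02d}" for i in range(n)]
    g.add_nodes_from(names)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(names[i], names[j])
    return g
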