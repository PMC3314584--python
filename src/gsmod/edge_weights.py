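"""Common-neighbour edge weighting and per-node highest edge weights.

The weight of an interaction (u, v) is

    w_uv = |N_uv| + alpha * |E_uv|

where N_uv is the set of common neighbours of u and v and E_uv the set of
network edges running between those common neighbours.  The interaction
factor ``alpha`` (default 1) sets how much the wiring *among* the common
neighbourhood counts on top of its size; with alpha = 0 the weight reduces
to the plain common-neighbour count.

``hw_n``, the highest edge weight of node n, is the maximum weight among
n's incident edges.  During iterative clustering, edges of already-emitted
modules are masked: weights are computed once on the full network and never
recomputed, but hw is kept up to date over the unmasked edges only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Collection, Iterable, Iterator, Set

import networkx as nx

from .model import EdgeKey, edge_key


def edge_weight(network: nx.Graph, u: str, v: str, alpha: float = 1) -> float:
    """Weight of the existing edge (u, v): ``|N_uv| + alpha * |E_uv|``.

    Raises ``ValueError`` if (u, v) is not an edge — the weight is defined
    on interactions only.
    """
    if not network.has_edge(u, v):
        raise ValueError(f"({u!r}, {v!r}) is not an edge of the network")
    common = set(network[u]) & set(network[v])
    if not common:
        return 0 * alpha
    # edges of the network with both endpoints among the common neighbours;
    # x < y avoids double counting
    e_uv = sum(1 for x in common for y in network[x] if y in common and x < y)
    return len(common) + alpha * e_uv


@dataclass
class WeightedNetwork:
    """A network with per-edge weights, an edge mask, and per-node hw.

    ``weight`` covers every edge of ``graph`` and is never recomputed after
    construction.  ``mask`` holds edges marked as clustered; ``hw`` maps
    each node with at least one unmasked incident edge to the pair
    ``(highest unmasked weight, partner node attaining it)``, the partner
    being the lexicographically smallest one among ties.
    """

    graph: nx.Graph
    alpha: float
    weight: dict[EdgeKey, float]
    mask: set[EdgeKey] = field(default_factory=set)
    hw: dict[str, tuple[float, str]] = field(default_factory=dict)

    def is_masked(self, u: str, v: str) -> bool:
        return edge_key(u, v) in self.mask

    def unmasked_edges(self) -> Iterator[EdgeKey]:
        for u, v in self.graph.edges():
            e = edge_key(u, v)
            if e not in self.mask:
                yield e

    def unmasked_neighbors(self, node: str) -> Iterator[str]:
        for nbr in self.graph[node]:
            if edge_key(node, nbr) not in self.mask:
                yield nbr


def _best_partner(wn: WeightedNetwork, node: str) -> tuple[float, str] | None:
    best_w: float | None = None
    best_p: str | None = None
    for nbr in wn.graph[node]:
        e = edge_key(node, nbr)
        if e in wn.mask:
            continue
        w = wn.weight[e]
        if best_w is None or w > best_w or (w == best_w and nbr < best_p):
            best_w, best_p = w, nbr
    if best_w is None:
        return None
    return best_w, best_p


def compute_weights(network: nx.Graph, alpha: float = 1) -> WeightedNetwork:
    """Weigh every edge of the network once and populate hw for all
    non-isolated nodes.  The mask starts empty."""
    weight = {
        edge_key(u, v): edge_weight(network, u, v, alpha)
        for u, v in network.edges()
    }
    wn = WeightedNetwork(graph=network, alpha=alpha, weight=weight)
    for node in network:
        rec = _best_partner(wn, node)
        if rec is not None:
            wn.hw[node] = rec
    return wn


def update_highest_weights(
    wn: WeightedNetwork, newly_masked: Iterable[tuple[str, str]]
) -> None:
    """Extend the mask and refresh hw for every node incident to a newly
    masked edge.  Nodes left with no unmasked incident edge drop out of hw.
    Weights themselves are untouched."""
    fresh = {edge_key(u, v) for u, v in newly_masked}
    for e in fresh:
        if not wn.graph.has_edge(*e):
            raise ValueError(f"cannot mask non-edge {e!r}")
    fresh -= wn.mask
    wn.mask |= fresh
    affected = {n for e in fresh for n in e}
    for node in affected:
        rec = _best_partner(wn, node)
        if rec is None:
            wn.hw.pop(node, None)
        else:
            wn.hw[node] = rec


def hw_partner_in(wn: WeightedNetwork, u: str, allowed: Set[str]) -> str | None:
    """Smallest-named node v in ``allowed`` whose unmasked edge (u, v)
    attains u's highest edge weight, or ``None``.

    The admission tests of core growth and attachment selection ask whether
    a highest-weight edge of u leads into the cluster; when several edges
    tie at hw_u, any of them qualifies, and the lexicographically smallest
    in-cluster partner is used for the subsequent closeness / overlap test.
    """
    rec = wn.hw.get(u)
    if rec is None:
        return None
    hw_u = rec[0]
    best: str | None = None
    for v in wn.graph[u]:
        if v not in allowed:
            continue
        e = edge_key(u, v)
        if e in wn.mask:
            continue
        if wn.weight[e] == hw_u and (best is None or v < best):
            best = v
    return best


def closeness(
    network: nx.Graph, cluster: Collection[str], n: str, k: str
) -> float:
    """Closeness of node n to cluster member k:
    ``|NC_n ∩ NC_k| / |NC_k|`` where NC_x is x's neighbour set restricted
    to the cluster.  Defined as 0 when k has no neighbours in the cluster.

    ``n`` may lie outside the cluster (it is evaluated for growth
    candidates before they join); ``k`` must be a member.
    """
    if n not in network or k not in network:
        raise ValueError("closeness arguments must be network nodes")
    cluster_set = cluster if isinstance(cluster, (set, frozenset)) else set(cluster)
    if k not in cluster_set:
        raise ValueError(f"{k!r} is not a member of the cluster")
    nc_k = set(network[k]) & cluster_set
    if not nc_k:
        return 0.0
    nc_n = set(network[n]) & cluster_set
    return len(nc_n & nc_k) / len(nc_k)
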