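"""Core-attachment greedy module detection (GSM-CA).

The algorithm repeats four phases until no usable seed remains:

1. *Seed selection* — the unmasked edge of globally maximal weight; the
   run terminates when that weight is not strictly above
   ``min_seed_weight`` (default 1, so lone triangles, whose edges all
   weigh 1, never seed a module).
2. *Core formation* — the core starts as the seed pair and grows one node
   per iteration: among unclustered neighbours u of the core whose
   highest-weight edge leads to a core member v and whose closeness
   cn_uv to the core is at least ``cn_in``, the one with the largest hw_u
   joins.
3. *Attachment selection* — a single sweep over the core's neighbours:
   u becomes an attachment when a highest-weight edge of u leads into the
   core at v and more than half of the common neighbours of u and v lie
   inside the core (strict inequality, so a 50/50 split is rejected).
4. *Output & update* — all edges incident to the module's members are
   masked and hw is refreshed on the remaining graph.

Ties are always broken towards the lexicographically smallest node or
edge, making a run a pure function of the input network and parameters.

Overlap mode re-opens the finished non-overlapping clustering: each module
may absorb further neighbours — including nodes owned by other modules —
under the attachment criterion, with hw recomputed on the original graph
minus the edges running between two clustered nodes.
"""

from __future__ import annotations

import math

import networkx as nx

from .edge_weights import (
    WeightedNetwork,
    closeness,
    compute_weights,
    hw_partner_in,
    update_highest_weights,
)
from .model import Clustering, EdgeKey, Module, edge_key


def select_seed(
    wn: WeightedNetwork, min_seed_weight: float = 1
) -> EdgeKey | None:
    """The unmasked edge of globally maximal weight, or ``None`` when that
    maximum is not strictly above ``min_seed_weight`` (termination)."""
    best_e: EdgeKey | None = None
    best_w = -math.inf
    for e in wn.unmasked_edges():
        w = wn.weight[e]
        if w > best_w or (w == best_w and e < best_e):
            best_e, best_w = e, w
    if best_e is None or best_w <= min_seed_weight:
        return None
    return best_e


def _core_neighbors(wn: WeightedNetwork, core: set[str]) -> set[str]:
    out: set[str] = set()
    for c in core:
        for nbr in wn.unmasked_neighbors(c):
            if nbr not in core:
                out.add(nbr)
    return out


def grow_core(
    wn: WeightedNetwork, seed: tuple[str, str], cn_in: float
) -> frozenset[str]:
    """Grow a core from ``seed``, admitting one neighbour per iteration.

    A neighbour u is eligible when some unmasked highest-weight edge of u
    ends at a core member v and ``cn_uv >= cn_in`` (closeness computed with
    u still outside the core).  Among eligible neighbours the one with the
    largest hw_u is added, smallest name first on ties.
    """
    seed = edge_key(*seed)
    if seed in wn.mask:
        raise ValueError(f"seed edge {seed!r} is masked")
    if not wn.graph.has_edge(*seed):
        raise ValueError(f"seed {seed!r} is not an edge")
    core: set[str] = set(seed)
    while True:
        best: tuple[float, str] | None = None
        for u in _core_neighbors(wn, core):
            v = hw_partner_in(wn, u, core)
            if v is None:
                continue
            if closeness(wn.graph, core, u, v) < cn_in:
                continue
            hw_u = wn.hw[u][0]
            if best is None or hw_u > best[0] or (hw_u == best[0] and u < best[1]):
                best = (hw_u, u)
        if best is None:
            return frozenset(core)
        core.add(best[1])


def select_attachments(
    wn: WeightedNetwork, core: frozenset[str] | set[str]
) -> frozenset[str]:
    """Single sweep over the core's unclustered neighbours.

    u is selected when a highest-weight edge of u leads into the core at v
    and ``|N_uv ∩ core| / |N_uv| > 0.5``, with N_uv the common neighbours
    of u and v in the *full* network.  Candidates with no common
    neighbours fail the test; additions do not cascade.
    """
    if not core:
        raise ValueError("core must be nonempty")
    core_set = set(core)
    attachments: set[str] = set()
    for u in _core_neighbors(wn, core_set):
        v = hw_partner_in(wn, u, core_set)
        if v is None:
            continue
        n_uv = set(wn.graph[u]) & set(wn.graph[v])
        if not n_uv:
            continue
        if len(n_uv & core_set) / len(n_uv) > 0.5:
            attachments.add(u)
    return frozenset(attachments)


def cluster_ca(
    network: nx.Graph,
    cn_in: float = 0.5,
    alpha: float = 1,
    min_size: int = 3,
    overlap: bool = False,
    min_seed_weight: float = 1,
) -> Clustering:
    """Run the full core-attachment clustering.

    Clusters of every size are formed and removed from the working graph
    (otherwise the same seed would repeat); only modules with at least
    ``min_size`` members appear in the returned clustering, the rest are
    counted in ``run_log``.  With ``overlap=True`` the non-overlapping
    result is post-extended via :func:`extend_overlapping`.
    """
    if not 0 <= cn_in <= 1:
        raise ValueError(f"cn_in must lie in [0, 1], got {cn_in}")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if nx.number_of_selfloops(network):
        raise ValueError("network must be simple (self-loops present)")

    wn = compute_weights(network, alpha)
    formed: list[tuple[frozenset[str], frozenset[str]]] = []
    seed_log: list[EdgeKey] = []
    while True:
        seed = select_seed(wn, min_seed_weight)
        if seed is None:
            break
        core = grow_core(wn, seed, cn_in)
        attachments = select_attachments(wn, core)
        members = core | attachments
        seed_log.append(seed)
        formed.append((core, attachments))
        incident = {
            edge_key(x, nbr) for x in members for nbr in wn.graph[x]
        }
        update_highest_weights(wn, incident)

    retained = [
        (core, att) for core, att in formed if len(core | att) >= min_size
    ]
    modules = [
        Module(module_id=i, core=core, attachments=att)
        for i, (core, att) in enumerate(retained, start=1)
    ]
    parameters = {
        "cn_in": cn_in,
        "alpha": alpha,
        "min_size": min_size,
        "min_seed_weight": min_seed_weight,
        "overlap": overlap,
    }
    clustering = Clustering(
        modules=modules,
        algorithm="gsm-ca",
        parameters=parameters,
        overlap=False,
        seed_log=seed_log,
        run_log={
            "clusters_formed": len(formed),
            "clusters_below_min_size": len(formed) - len(retained),
        },
    )
    if overlap:
        clustering = extend_overlapping(network, clustering, alpha)
    return clustering


def extend_overlapping(
    network: nx.Graph, clustering: Clustering, alpha: float = 1
) -> Clustering:
    """Extend a non-overlapping clustering into an overlapping one.

    Every module may absorb neighbours from the original graph — nodes
    already owned by other modules included — in one sweep per module,
    under the attachment criterion.  hw is recomputed on the original
    graph excluding edges whose *both* endpoints are clustered, so an
    unclustered candidate keeps its edges towards clustered nodes.
    Modules are never shrunk; admitted nodes are recorded as attachments.
    """
    if clustering.overlap:
        raise ValueError("clustering is already in overlap mode")
    clustered = clustering.covered_nodes()
    wn = compute_weights(network, alpha)
    between_clustered = {
        edge_key(u, v)
        for u, v in network.edges()
        if u in clustered and v in clustered
    }
    update_highest_weights(wn, between_clustered)

    extended: list[Module] = []
    for module in clustering.modules:
        members = module.members
        candidates = {
            nbr for x in members for nbr in network[x] if nbr not in members
        }
        added: set[str] = set()
        for u in sorted(candidates):
            v = hw_partner_in(wn, u, members)
            if v is None:
                continue
            n_uv = set(network[u]) & set(network[v])
            if not n_uv:
                continue
            if len(n_uv & members) / len(n_uv) > 0.5:
                added.add(u)
        extended.append(
            Module(
                module_id=module.module_id,
                core=module.core,
                attachments=module.attachments | added,
                unlabelled=module.unlabelled,
            )
        )
    return Clustering(
        modules=extended,
        algorithm=clustering.algorithm,
        parameters={**clustering.parameters, "overlap": True},
        overlap=True,
        seed_log=list(clustering.seed_log),
        run_log=dict(clustering.run_log),
    )
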