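"""Seeded generators for networks with known module structure.

Both detection algorithms exploit one structural premise: functional
modules appear as densely connected regions separated by sparse
inter-module wiring.  The generators here produce exactly that —
planted-partition graphs (Bernoulli edges at density ``p_in`` inside each
block and ``p_out`` between blocks) and a core-attachment variant in which
each planted module is a dense core plus peripheral attachment nodes wired
to a fraction of the core.  A matching annotation generator plants one
functional term per module (optionally with noise) so the enrichment and
f-measure statistics are testable without external annotation databases.

All generators are pure functions of their parameters and seed: the same
call reproduces the identical benchmark byte for byte.  Node names are
zero-padded (``P0001``) so lexicographic tie-breaking is stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .model import AnnotationSet, ComplexCatalog


@dataclass
class SyntheticBenchmark:
    """A generated network with its ground truth.

    ``roles`` records, for core-attachment benchmarks, each planted
    module's (core, attachment) node sets; it is ``None`` for plain
    planted-partition benchmarks.
    """

    network: nx.Graph
    truth: ComplexCatalog
    roles: dict[str, tuple[frozenset[str], frozenset[str]]] | None
    parameters: dict
    seed: int
    annotations: AnnotationSet | None = None


def _node_names(total: int) -> list[str]:
    width = max(4, len(str(total)))
    return [f"P{i:0{width}d}" for i in range(1, total + 1)]


def _complex_ids(n_modules: int) -> list[str]:
    width = max(2, len(str(n_modules)))
    return [f"M{i:0{width}d}" for i in range(1, n_modules + 1)]


def planted_partition_graph(
    n_modules: int,
    sizes: int | list[int],
    p_in: float,
    p_out: float,
    seed: int,
) -> SyntheticBenchmark:
    """Planted-partition benchmark: dense blocks, sparse background.

    Parameters
    ----------
    n_modules
        Number of planted blocks.
    sizes
        Per-block node counts (a single int applies to all blocks);
        every block needs at least 3 nodes.
    p_in, p_out
        Within-block and between-block edge probabilities,
        ``0 <= p_out < p_in <= 1``.
    seed
        Seed for the block-model sampler; fully determines the edge set.
    """
    if isinstance(sizes, int):
        sizes = [sizes] * n_modules
    if len(sizes) != n_modules:
        raise ValueError("sizes must have one entry per module")
    if any(s < 3 for s in sizes):
        raise ValueError("every planted module needs at least 3 nodes")
    if not (0 <= p_out < p_in <= 1):
        raise ValueError("need 0 <= p_out < p_in <= 1")

    probs = [
        [p_in if i == j else p_out for j in range(n_modules)]
        for i in range(n_modules)
    ]
    raw = nx.stochastic_block_model(sizes, probs, seed=seed)
    names = _node_names(sum(sizes))
    graph = nx.relabel_nodes(raw, dict(enumerate(names)), copy=True)
    graph.graph.clear()

    complexes: dict[str, frozenset[str]] = {}
    offset = 0
    for cid, size in zip(_complex_ids(n_modules), sizes):
        complexes[cid] = frozenset(names[offset : offset + size])
        offset += size
    return SyntheticBenchmark(
        network=graph,
        truth=ComplexCatalog(complexes),
        roles=None,
        parameters={
            "model": "planted-partition",
            "n_modules": n_modules,
            "sizes": list(sizes),
            "p_in": p_in,
            "p_out": p_out,
        },
        seed=seed,
    )


def core_attachment_graph(
    n_modules: int,
    core_size: int = 5,
    n_attach: int = 3,
    p_core: float = 1.0,
    attach_frac: float = 0.7,
    p_out: float = 0.01,
    seed: int = 0,
) -> SyntheticBenchmark:
    """Benchmark whose planted modules have a dense core plus attachments.

    Each module is a core of ``core_size`` nodes wired at density
    ``p_core`` plus ``n_attach`` attachment nodes, each adjacent to
    ``ceil(attach_frac * core_size)`` core nodes chosen at random.
    Attachments of the same module are not wired to each other; node pairs
    in different modules are connected at ``p_out``.  The defaults emulate
    the small, dense, reliable cores (here: cliques of 5) surrounded by a
    sparser periphery that the core-attachment model assumes.
    """
    if core_size < 2:
        raise ValueError("core_size must be >= 2")
    if n_attach < 0:
        raise ValueError("n_attach must be >= 0")
    if not 0 < attach_frac <= 1:
        raise ValueError("attach_frac must lie in (0, 1]")
    if not 0 < p_core <= 1:
        raise ValueError("p_core must lie in (0, 1]")
    if not 0 <= p_out < p_core:
        raise ValueError("need 0 <= p_out < p_core")
    if core_size + n_attach < 3:
        raise ValueError("every planted module needs at least 3 nodes")

    rng = np.random.default_rng(seed)
    names = _node_names(n_modules * (core_size + n_attach))
    graph = nx.Graph()
    graph.add_nodes_from(names)

    complexes: dict[str, frozenset[str]] = {}
    roles: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
    module_nodes: list[list[str]] = []
    n_core_links = math.ceil(attach_frac * core_size)
    offset = 0
    for cid in _complex_ids(n_modules):
        core = names[offset : offset + core_size]
        attach = names[offset + core_size : offset + core_size + n_attach]
        offset += core_size + n_attach
        for i, u in enumerate(core):
            for v in core[i + 1 :]:
                if rng.random() < p_core:
                    graph.add_edge(u, v)
        for a in attach:
            partners = rng.choice(core, size=n_core_links, replace=False)
            for v in partners:
                graph.add_edge(a, str(v))
        complexes[cid] = frozenset(core) | frozenset(attach)
        roles[cid] = (frozenset(core), frozenset(attach))
        module_nodes.append(core + attach)
    if p_out > 0:
        for i, block_i in enumerate(module_nodes):
            for block_j in module_nodes[i + 1 :]:
                for u in block_i:
                    for v in block_j:
                        if rng.random() < p_out:
                            graph.add_edge(u, v)
    return SyntheticBenchmark(
        network=graph,
        truth=ComplexCatalog(complexes),
        roles=roles,
        parameters={
            "model": "core-attachment",
            "n_modules": n_modules,
            "core_size": core_size,
            "n_attach": n_attach,
            "p_core": p_core,
            "attach_frac": attach_frac,
            "p_out": p_out,
        },
        seed=seed,
    )


def annotate_truth(
    benchmark: SyntheticBenchmark,
    background_terms: int = 0,
    noise_rate: float = 0.0,
    seed: int = 0,
) -> AnnotationSet:
    """Annotation set aligned with the planted modules.

    One term per planted module contains its members plus
    ``round(noise_rate * module size)`` random outside proteins;
    ``background_terms`` further terms draw 3-20 random proteins each.
    The background size is the number of network nodes.
    """
    if noise_rate < 0:
        raise ValueError("noise_rate must be >= 0")
    if background_terms < 0:
        raise ValueError("background_terms must be >= 0")
    rng = np.random.default_rng(seed)
    nodes = sorted(benchmark.network.nodes())
    terms: dict[str, frozenset[str]] = {}
    for cid in sorted(benchmark.truth.complexes):
        members = benchmark.truth.complexes[cid]
        n_extra = int(round(noise_rate * len(members)))
        pool = sorted(set(nodes) - members)
        extras: set[str] = set()
        if n_extra and pool:
            n_extra = min(n_extra, len(pool))
            extras = {str(x) for x in rng.choice(pool, size=n_extra, replace=False)}
        terms[f"T{cid}"] = frozenset(members | extras)
    width = max(3, len(str(background_terms)))
    for j in range(1, background_terms + 1):
        size = int(rng.integers(3, min(21, len(nodes) + 1)))
        proteins = {str(x) for x in rng.choice(nodes, size=size, replace=False)}
        terms[f"BG{j:0{width}d}"] = frozenset(proteins)
    return AnnotationSet(terms, background_size=len(nodes))
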