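"""Shared in-memory containers.

Protein identifiers are opaque, case-sensitive strings.  Interaction
networks are simple undirected graphs (:class:`networkx.Graph`); an edge is
addressed by its canonical unordered key — a lexicographically sorted
2-tuple — so that ``(u, v)`` and ``(v, u)`` name the same interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

EdgeKey = tuple[str, str]

#: deterministic ordering of node roles in module output
ROLE_ORDER = ("core", "attachment", "member")


def edge_key(u: str, v: str) -> EdgeKey:
    """Canonical unordered key for the interaction between ``u`` and ``v``."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class Module:
    """One detected cluster.

    Core-attachment detection partitions a module into a ``core`` (the
    dense heart grown from a seed edge, always at least two nodes) and its
    ``attachments`` (peripheral nodes admitted in a single sweep).  The
    single-pass fast-clustering algorithm produces no such split; its nodes
    are stored in ``unlabelled`` and reported with role ``member``.
    """

    module_id: int | str
    core: frozenset[str] = frozenset()
    attachments: frozenset[str] = frozenset()
    unlabelled: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if (
            self.core & self.attachments
            or self.core & self.unlabelled
            or self.attachments & self.unlabelled
        ):
            raise ValueError("module roles must be disjoint node sets")
        if self.core and len(self.core) < 2:
            raise ValueError("a core grows from a seed edge and has at least 2 nodes")
        if not (self.core or self.attachments or self.unlabelled):
            raise ValueError("empty module")

    @property
    def members(self) -> frozenset[str]:
        return self.core | self.attachments | self.unlabelled

    def __len__(self) -> int:
        return len(self.members)

    def roles(self) -> Iterator[tuple[str, str]]:
        """Yield ``(role, protein)`` rows in deterministic output order."""
        for protein in sorted(self.core):
            yield "core", protein
        for protein in sorted(self.attachments):
            yield "attachment", protein
        for protein in sorted(self.unlabelled):
            yield "member", protein


@dataclass
class Clustering:
    """Ordered collection of modules plus provenance of the producing run."""

    modules: list[Module]
    algorithm: str = ""
    parameters: dict = field(default_factory=dict)
    overlap: bool = False
    #: seed edges chosen, in discovery order (core-attachment runs only)
    seed_log: list[EdgeKey] = field(default_factory=list)
    #: free-form run statistics (clusters formed, filtered, edges visited...)
    run_log: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self) -> Iterator[Module]:
        return iter(self.modules)

    def member_sets(self) -> list[frozenset[str]]:
        return [m.members for m in self.modules]

    def covered_nodes(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.modules:
            out |= m.members
        return frozenset(out)


@dataclass
class ComplexCatalog:
    """Benchmark catalog: mapping from complex identifier to its protein set."""

    complexes: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for cid, members in self.complexes.items():
            if not members:
                raise ValueError(f"complex {cid!r} has no members")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.complexes)

    def items(self):
        return self.complexes.items()

    def filtered(self, min_size: int) -> "ComplexCatalog":
        """Catalog restricted to complexes with at least ``min_size`` members."""
        return ComplexCatalog(
            {cid: s for cid, s in self.complexes.items() if len(s) >= min_size}
        )


@dataclass
class AnnotationSet:
    """Flat functional annotation: term identifier -> annotated protein set.

    ``background_size`` is the number of annotatable proteins N used as the
    population size in enrichment tests; it defaults to the number of
    distinct proteins seen when read from file.
    """

    terms: dict[str, frozenset[str]]
    background_size: int

    def __post_init__(self) -> None:
        if self.background_size < 0:
            raise ValueError("background_size must be non-negative")
        for term, proteins in self.terms.items():
            if len(proteins) > self.background_size:
                raise ValueError(
                    f"background_size {self.background_size} smaller than "
                    f"term {term!r} ({len(proteins)} proteins)"
                )

    @property
    def annotated_proteins(self) -> frozenset[str]:
        out: set[str] = set()
        for proteins in self.terms.values():
            out |= proteins
        return frozenset(out)
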