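"""Plain-text readers and writers for every format the tool touches.

Formats
-------
Edge list
    Two or more whitespace/tab-delimited columns, ``#`` comments; the
    dialect used by DIP-style interaction-pair distributions.  Direction is
    ignored, self-interactions are dropped and duplicate pairs (in either
    orientation) are collapsed — the reader reports what it dropped in
    ``graph.graph["io_summary"]`` so users can reconcile interaction counts.
Complex catalog
    One complex per line: ``complex_id<TAB>member1 member2 ...``.
Annotation table
    One pair per line: ``term_id<TAB>protein_id``.
Clustering output
    TSV with columns ``module_id``, ``role`` (core | attachment | member)
    and ``protein``; deterministic row order (module order, then role, then
    protein name) so that write -> read -> write is byte-identical.
"""

from __future__ import annotations

import os
from typing import Iterable

import networkx as nx

from .model import AnnotationSet, Clustering, ComplexCatalog, Module, edge_key


class ParseError(ValueError):
    """Malformed line in an input file; carries the offending line number."""

    def __init__(self, path: os.PathLike | str, line_no: int, message: str):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{self.path}:{line_no}: {message}")


def _data_lines(path, comment_prefix: str):
    """Yield ``(line_no, stripped_line)`` skipping blanks and comments."""
    with open(path, "rt", encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(comment_prefix):
                continue
            yield line_no, line


def read_edge_list(
    path, comment_prefix: str = "#", delimiter: str | None = None
) -> nx.Graph:
    """Read an interaction network from a two-column protein-pair table.

    Parameters
    ----------
    path
        Text file; each non-comment line holds at least two fields naming
        the two interactors.  Extra columns are ignored.
    comment_prefix
        Lines starting with this prefix are skipped (default ``#``).
    delimiter
        Field separator; ``None`` (default) splits on any whitespace run.

    Returns
    -------
    networkx.Graph
        Simple undirected network.  ``graph.graph["io_summary"]`` records
        lines read, self-loops dropped and duplicate pairs collapsed.

    Raises
    ------
    ParseError
        If a non-comment line has fewer than two fields.
    """
    graph = nx.Graph()
    pairs_read = 0
    loops_dropped = 0
    duplicates_collapsed = 0
    for line_no, line in _data_lines(path, comment_prefix):
        fields = line.split(delimiter)
        if len(fields) < 2:
            raise ParseError(path, line_no, "expected at least 2 fields")
        u, v = fields[0], fields[1]
        pairs_read += 1
        if u == v:
            loops_dropped += 1
            graph.add_node(u)
            continue
        if graph.has_edge(u, v):
            duplicates_collapsed += 1
            continue
        graph.add_edge(u, v)
    graph.graph["io_summary"] = {
        "pairs_read": pairs_read,
        "self_loops_dropped": loops_dropped,
        "duplicates_collapsed": duplicates_collapsed,
        "nodes": graph.number_of_nodes(),
        "edges": graph.number_of_edges(),
    }
    return graph


def write_edge_list(network: nx.Graph, path) -> None:
    """Write a network as a sorted two-column edge list.

    Isolated nodes cannot be represented in an edge list and are omitted.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        for u, v in sorted(edge_key(u, v) for u, v in network.edges()):
            fh.write(f"{u}\t{v}\n")


def read_complex_catalog(
    path, min_size: int = 2, comment_prefix: str = "#"
) -> ComplexCatalog:
    """Read a benchmark complex catalog, dropping complexes below ``min_size``.

    The default ``min_size=2`` mirrors the usual benchmark preparation step
    of discarding single-protein complexes.
    """
    complexes: dict[str, frozenset[str]] = {}
    for line_no, line in _data_lines(path, comment_prefix):
        tokens = line.split()
        cid, members = tokens[0], tokens[1:]
        if not members:
            raise ParseError(path, line_no, f"complex {cid!r} has no members")
        if cid in complexes:
            raise ParseError(path, line_no, f"duplicate complex id {cid!r}")
        complexes[cid] = frozenset(members)
    return ComplexCatalog(
        {cid: s for cid, s in complexes.items() if len(s) >= min_size}
    )


def write_complex_catalog(catalog: ComplexCatalog, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for cid in sorted(catalog.complexes):
            fh.write(f"{cid}\t{' '.join(sorted(catalog.complexes[cid]))}\n")


def read_annotations(
    path, background_size: int | None = None, comment_prefix: str = "#"
) -> AnnotationSet:
    """Read a flat ``term<TAB>protein`` annotation table.

    ``background_size`` defaults to the number of distinct proteins seen;
    supplying a value smaller than some term's protein set is an error.
    """
    terms: dict[str, set[str]] = {}
    proteins: set[str] = set()
    for line_no, line in _data_lines(path, comment_prefix):
        tokens = line.split()
        if len(tokens) != 2:
            raise ParseError(path, line_no, "expected exactly 2 fields")
        term, protein = tokens
        terms.setdefault(term, set()).add(protein)
        proteins.add(protein)
    if background_size is None:
        background_size = len(proteins)
    return AnnotationSet(
        {term: frozenset(s) for term, s in terms.items()}, background_size
    )


def write_annotations(annotations: AnnotationSet, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for term in sorted(annotations.terms):
            for protein in sorted(annotations.terms[term]):
                fh.write(f"{term}\t{protein}\n")


_CLUSTERING_HEADER = "module_id\trole\tprotein"


def write_clustering(clustering: Clustering, path) -> None:
    """Write one row per (module, node) with its role; header line first."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(_CLUSTERING_HEADER + "\n")
        for module in clustering.modules:
            for role, protein in module.roles():
                fh.write(f"{module.module_id}\t{role}\t{protein}\n")


def read_clustering(path) -> Clustering:
    """Read a clustering TSV written by :func:`write_clustering`."""
    order: list[int | str] = []
    roles: dict[int | str, dict[str, set[str]]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != _CLUSTERING_HEADER:
            raise ParseError(path, 1, f"expected header {_CLUSTERING_HEADER!r}")
        for line_no, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(path, line_no, "expected 3 tab-separated fields")
            raw_id, role, protein = fields
            if role not in ("core", "attachment", "member"):
                raise ParseError(path, line_no, f"unknown role {role!r}")
            module_id: int | str = int(raw_id) if raw_id.isdigit() else raw_id
            if module_id not in roles:
                order.append(module_id)
                roles[module_id] = {"core": set(), "attachment": set(), "member": set()}
            roles[module_id][role].add(protein)
    modules = [
        Module(
            module_id=mid,
            core=frozenset(roles[mid]["core"]),
            attachments=frozenset(roles[mid]["attachment"]),
            unlabelled=frozenset(roles[mid]["member"]),
        )
        for mid in order
    ]
    return Clustering(modules=modules, algorithm="file", parameters={"source": str(path)})
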