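"""Edge-centric de Bruijn graphs and read overlap graphs.

In the edge-centric convention of order k, vertices are the (k−1)-mers and
every k-mer ``x`` of the spectrum contributes one edge from its (k−1)-prefix
to its (k−1)-suffix.  The vertex set is induced from the edges, so isolated
vertices cannot exist.  ``build_closure_graph`` builds the order-(k+1) graph
of the closure of a spectrum ``S``; its vertex set equals ``S`` whenever
``S`` is the spectrum of reads all longer than k.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable

from .seqs import KmerSpectrum, ReadSet, closure


@dataclass(frozen=True, order=True)
class Edge:
    label: str
    source: str
    target: str

    @classmethod
    def from_label(cls, label: str) -> "Edge":
        return cls(label, label[:-1], label[1:])


class DeBruijnGraph:
    """Edge-centric de Bruijn graph: one edge per k-mer, (k−1)-mer vertices.

    Adjacency lists are sorted lexicographically by edge label, which makes
    every traversal in this package deterministic without a seed.
    """

    __slots__ = ("order", "edges", "vertices", "adjacency", "in_adjacency", "__dict__")

    def __init__(self, order: int, labels: Iterable[str]):
        if order < 2:
            raise ValueError(f"de Bruijn graph order must be >= 2, got {order}")
        labels = sorted(set(labels))
        if not labels:
            raise ValueError("de Bruijn graph requires at least one edge")
        for x in labels:
            if len(x) != order:
                raise ValueError(f"edge label {x!r} has length {len(x)}, expected {order}")
        self.order = order
        self.edges: tuple[Edge, ...] = tuple(Edge.from_label(x) for x in labels)
        adj: dict[str, list[str]] = {}
        in_adj: dict[str, list[str]] = {}
        for e in self.edges:
            adj.setdefault(e.source, []).append(e.label)
            adj.setdefault(e.target, [])
            in_adj.setdefault(e.target, []).append(e.label)
            in_adj.setdefault(e.source, [])
        self.adjacency: dict[str, tuple[str, ...]] = {
            v: tuple(sorted(labels)) for v, labels in adj.items()
        }
        self.in_adjacency: dict[str, tuple[str, ...]] = {
            v: tuple(sorted(labels)) for v, labels in in_adj.items()
        }
        self.vertices: frozenset[str] = frozenset(self.adjacency)

    @classmethod
    def from_spectrum(cls, S: KmerSpectrum) -> "DeBruijnGraph":
        return cls(S.k, S.kmers)

    @cached_property
    def edge_labels(self) -> frozenset[str]:
        return frozenset(e.label for e in self.edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def out_degree(self, v: str) -> int:
        return len(self.adjacency[v])

    def in_degree(self, v: str) -> int:
        return len(self.in_adjacency[v])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DeBruijnGraph):
            return NotImplemented
        return self.order == other.order and self.edge_labels == other.edge_labels

    def __hash__(self) -> int:
        return hash((self.order, self.edge_labels))

    def __repr__(self) -> str:
        return (
            f"DeBruijnGraph(order={self.order}, vertices={self.n_vertices}, "
            f"edges={self.n_edges})"
        )


def build_dbg(S: KmerSpectrum) -> DeBruijnGraph:
    """dBG of order k of a k-mer set: vertices (k−1)-mers, edges k-mers."""
    return DeBruijnGraph.from_spectrum(S)


def build_closure_graph(S: KmerSpectrum) -> DeBruijnGraph:
    """The order-(k+1) de Bruijn graph of closure(S).

    When ``S`` is a spectrum of reads all strictly longer than k, the
    vertex set of the result is exactly ``S.kmers``.
    """
    return build_dbg(closure(S))


@dataclass(frozen=True)
class OverlapGraph:
    """Directed overlap graph: vertices are distinct reads, arcs are maximal
    proper suffix-prefix overlaps of length >= ``min_overlap``."""

    min_overlap: int
    vertices: frozenset[str]
    arcs: frozenset[tuple[str, str, int]]

    def successors(self, v: str) -> list[str]:
        return sorted(y for (x, y, _o) in self.arcs if x == v)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


def build_overlap_graph(R: ReadSet, min_overlap: int) -> OverlapGraph:
    """All-pairs maximal overlap graph (duplicate reads collapsed first).

    For each ordered pair of distinct reads (x, y) the single arc carries
    the maximum overlap length o with suffix(x, o) == prefix(y, o), if
    o >= min_overlap.  x -> x self-arcs are excluded.
    """
    if min_overlap < 1:
        raise ValueError(f"min_overlap must be >= 1, got {min_overlap}")
    reads = sorted(set(R.reads))
    arcs: set[tuple[str, str, int]] = set()
    for x in reads:
        for y in reads:
            if x == y:
                continue
            for o in range(min(len(x), len(y)), min_overlap - 1, -1):
                if x[-o:] == y[:o]:
                    arcs.add((x, y, o))
                    break
    return OverlapGraph(min_overlap, frozenset(reads), frozenset(arcs))


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------


def _dbg_gfa(G: DeBruijnGraph) -> str:
    # Edge-style GFA1: segments are the k-mer edge labels; two segments are
    # linked when one edge's target vertex is the other's source vertex, so
    # consecutive segments overlap by k-1 characters.
    k = G.order
    lines = ["H\tVN:Z:1.0"]
    for e in G.edges:
        lines.append(f"S\t{e.label}\t{e.label}")
    links = []
    for e in G.edges:
        for nxt in G.adjacency[e.target]:
            links.append((e.label, nxt))
    for x, y in sorted(links):
        lines.append(f"L\t{x}\t+\t{y}\t+\t{k - 1}M")
    return "\n".join(lines) + "\n"


def _dbg_dot(G: DeBruijnGraph) -> str:
    lines = ["digraph dbg {"]
    for v in sorted(G.vertices):
        lines.append(f'  "{v}";')
    for e in G.edges:
        lines.append(f'  "{e.source}" -> "{e.target}" [label="{e.label}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def _dbg_json(G: DeBruijnGraph) -> str:
    payload = {
        "type": "debruijn",
        "order": G.order,
        "vertices": sorted(G.vertices),
        "edges": [e.label for e in G.edges],
    }
    return json.dumps(payload, sort_keys=True, indent=1) + "\n"


def _overlap_dot(G: OverlapGraph) -> str:
    lines = ["digraph overlap {"]
    for v in sorted(G.vertices):
        lines.append(f'  "{v}";')
    for x, y, o in sorted(G.arcs):
        lines.append(f'  "{x}" -> "{y}" [label="{o}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def _overlap_json(G: OverlapGraph) -> str:
    payload = {
        "type": "overlap",
        "min_overlap": G.min_overlap,
        "vertices": sorted(G.vertices),
        "arcs": sorted(list(a) for a in G.arcs),
    }
    return json.dumps(payload, sort_keys=True, indent=1) + "\n"


def export_graph(G: DeBruijnGraph | OverlapGraph, fmt: str) -> str:
    """Serialize a graph as ``gfa1``, ``dot`` or ``json`` text (byte-stable)."""
    if isinstance(G, DeBruijnGraph):
        table = {"gfa1": _dbg_gfa, "dot": _dbg_dot, "json": _dbg_json}
    else:
        table = {"dot": _overlap_dot, "json": _overlap_json}
    try:
        return table[fmt](G)
    except KeyError:
        raise ValueError(f"unknown export format {fmt!r} for {type(G).__name__}") from None


def graph_from_json(text: str) -> DeBruijnGraph:
    payload = json.loads(text)
    if payload.get("type") != "debruijn":
        raise ValueError("not a de Bruijn graph JSON dump")
    return DeBruijnGraph(payload["order"], payload["edges"])


def graph_from_gfa(text: str) -> DeBruijnGraph:
    """Rebuild an edge-style de Bruijn graph from GFA1 S-lines."""
    labels = [
        line.split("\t")[2]
        for line in text.splitlines()
        if line.startswith("S\t")
    ]
    if not labels:
        raise ValueError("GFA text contains no S-lines")
    return DeBruijnGraph(len(labels[0]), labels)
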