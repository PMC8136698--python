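"""Eulerian and Hamiltonian cycles in de Bruijn graphs.

This module holds the algorithmic core of the package:

* ``eulerian_cycle`` — deterministic Hierholzer, linear in the edge count;
* ``enumerate_eulerian_cycles`` — exhaustive backtracking with rotation
  canonicalization (small graphs; guarded by a limit);
* ``count_eulerian_cycles`` — exact count via the BEST theorem (Matrix-Tree
  arborescence determinant in integer arithmetic times out-degree
  factorials), an independent oracle for the enumerator;
* ``euler_to_hamilton`` / ``hamilton_to_euler`` — the label-preserving
  bijection between Eulerian cycles in the order-k graph of a spectrum S
  and Hamiltonian cycles in the order-(k+1) graph of closure(S);
* ``brute_force_hamiltonian`` — exponential backtracking over vertices,
  kept as an independent oracle for the bijection.

Cycles are cyclic objects: two label sequences are the same cycle iff one
is a rotation of the other (reversal is NOT identified — the graphs are
directed).  The canonical form of a cycle is the lexicographically least
rotation of its label sequence.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from math import factorial
from typing import Iterable, Optional, Union

from .graphs import DeBruijnGraph, OverlapGraph
from .seqs import KmerSpectrum, least_rotation_index, rotate
from . import graphs as _graphs


class CycleValidationError(ValueError):
    """A label sequence does not form a valid cycle of the expected kind."""


class NotEulerianError(ValueError):
    """Raised when an operation requires an Eulerian graph; carries the
    diagnosis explaining which condition failed."""

    def __init__(self, diagnosis: "EulerianDiagnosis"):
        self.diagnosis = diagnosis
        parts = []
        if diagnosis.unbalanced_vertices:
            parts.append(
                "unbalanced vertices (vertex, in, out): "
                + ", ".join(f"({v}, {i}, {o})" for v, i, o in diagnosis.unbalanced_vertices)
            )
        if not diagnosis.connected:
            parts.append("graph is not strongly connected")
        super().__init__("graph is not Eulerian: " + "; ".join(parts))


class EnumerationOverflowError(RuntimeError):
    """More cycles than the enumeration limit; carries the partial result."""

    def __init__(self, limit: int, partial: frozenset):
        self.limit = limit
        self.partial = partial
        super().__init__(f"more than {limit} cycles found; aborting enumeration")


class VertexCapExceeded(RuntimeError):
    """Brute-force Hamiltonian search refused on too many vertices."""


@dataclass(frozen=True)
class EdgeCycle:
    """A cyclic sequence of edge labels (k-mers) in an order-k graph."""

    labels: tuple[str, ...]
    order: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if not self.labels:
            raise CycleValidationError("a cycle must contain at least one edge")
        for x in self.labels:
            if len(x) != self.order:
                raise CycleValidationError(
                    f"edge label {x!r} has length {len(x)}, expected {self.order}"
                )

    def __len__(self) -> int:
        return len(self.labels)

    def canonical(self) -> "EdgeCycle":
        return EdgeCycle(rotate(self.labels, least_rotation_index(self.labels)), self.order)

    def rotated_to(self, label: str) -> "EdgeCycle":
        """Rotation of the cycle starting at the first occurrence of ``label``."""
        return EdgeCycle(rotate(self.labels, self.labels.index(label)), self.order)


@dataclass(frozen=True)
class VertexCycle:
    """A cyclic sequence of vertex labels; ``order`` is the host graph's
    order (so labels have length order−1).  ``order`` is None for cycles in
    overlap graphs, whose vertices are whole reads."""

    labels: tuple[str, ...]
    order: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if not self.labels:
            raise CycleValidationError("a cycle must contain at least one vertex")
        if self.order is not None:
            for x in self.labels:
                if len(x) != self.order - 1:
                    raise CycleValidationError(
                        f"vertex label {x!r} has length {len(x)}, expected {self.order - 1}"
                    )

    def __len__(self) -> int:
        return len(self.labels)

    def canonical(self) -> "VertexCycle":
        return VertexCycle(rotate(self.labels, least_rotation_index(self.labels)), self.order)


def _chain_ok(labels: tuple[str, ...], overlap: int) -> bool:
    """Consecutive labels (cyclically) agree on ``overlap`` characters."""
    n = len(labels)
    if overlap == 0:
        return True
    return all(labels[i][-overlap:] == labels[(i + 1) % n][:overlap] for i in range(n))


def is_valid_chain(C: Union[EdgeCycle, VertexCycle]) -> bool:
    """Check the suffix/prefix overlap invariant of a cycle's labels."""
    if isinstance(C, EdgeCycle):
        return _chain_ok(C.labels, C.order - 1)
    if C.order is None:
        raise CycleValidationError("overlap-graph cycles have no fixed-overlap chain")
    return _chain_ok(C.labels, C.order - 2)


def is_eulerian_cycle(C: EdgeCycle, G: DeBruijnGraph) -> bool:
    """True iff C uses every edge of G exactly once and chains correctly."""
    return (
        C.order == G.order
        and len(C.labels) == G.n_edges
        and len(set(C.labels)) == len(C.labels)
        and set(C.labels) == G.edge_labels
        and _chain_ok(C.labels, G.order - 1)
    )


def is_hamiltonian_cycle(C: VertexCycle, G: DeBruijnGraph) -> bool:
    """True iff C visits every vertex of G exactly once along edges of G."""
    if len(C.labels) != G.n_vertices or set(C.labels) != G.vertices:
        return False
    if len(set(C.labels)) != len(C.labels):
        return False
    n = len(C.labels)
    for i in range(n):
        u, v = C.labels[i], C.labels[(i + 1) % n]
        # edge u -> v exists iff the merged (order)-mer is an edge label
        if u[1:] != v[:-1] or (u + v[-1]) not in G.edge_labels:
            return False
    return True


@dataclass(frozen=True)
class EulerianDiagnosis:
    is_eulerian: bool
    unbalanced_vertices: tuple[tuple[str, int, int], ...]
    connected: bool


def diagnose_eulerian(G: DeBruijnGraph) -> EulerianDiagnosis:
    """Check the classical Euler conditions: balance and strong connectivity
    (on the non-isolated vertices, which is all of them by construction)."""
    unbalanced = tuple(
        (v, G.in_degree(v), G.out_degree(v))
        for v in sorted(G.vertices)
        if G.in_degree(v) != G.out_degree(v)
    )
    connected = _strongly_connected(G)
    return EulerianDiagnosis(not unbalanced and connected, unbalanced, connected)


def _reachable(start: str, adj: dict[str, tuple[str, ...]], forward: bool) -> set[str]:
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for lab in adj[v]:
            w = lab[1:] if forward else lab[:-1]
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return seen


def _strongly_connected(G: DeBruijnGraph) -> bool:
    start = min(G.vertices)
    fwd = _reachable(start, G.adjacency, forward=True)
    if len(fwd) != G.n_vertices:
        return False
    bwd = _reachable(start, G.in_adjacency, forward=False)
    return len(bwd) == G.n_vertices


def eulerian_cycle(G: DeBruijnGraph) -> EdgeCycle:
    """Deterministic Hierholzer: start at the lexicographically smallest
    vertex, consume out-edges in sorted label order, splice sub-tours as
    they close.  Linear in the number of edges."""
    diag = diagnose_eulerian(G)
    if not diag.is_eulerian:
        raise NotEulerianError(diag)
    start = min(G.vertices)
    ptr = {v: 0 for v in G.vertices}
    adj = G.adjacency
    stack: list[tuple[str, Optional[str]]] = [(start, None)]
    out: list[str] = []
    while stack:
        v, via = stack[-1]
        i = ptr[v]
        if i < len(adj[v]):
            ptr[v] = i + 1
            lab = adj[v][i]
            stack.append((lab[1:], lab))
        else:
            stack.pop()
            if via is not None:
                out.append(via)
    out.reverse()
    assert len(out) == G.n_edges  # every edge consumed exactly once
    return EdgeCycle(tuple(out), G.order)


def enumerate_eulerian_cycles(G: DeBruijnGraph, limit: int = 10_000) -> frozenset[EdgeCycle]:
    """All distinct Eulerian cycles (up to rotation) by backtracking.

    Starts from a fixed vertex; every complete traversal is canonicalized
    by least rotation, so each cyclic cycle is counted once even though the
    search rediscovers it once per visit of the start vertex.  Raises
    ``EnumerationOverflowError`` (carrying the partial result) if more than
    ``limit`` distinct cycles are found.
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    diag = diagnose_eulerian(G)
    if not diag.is_eulerian:
        raise NotEulerianError(diag)
    m = G.n_edges
    sys.setrecursionlimit(max(sys.getrecursionlimit(), 4 * m + 100))
    start = min(G.vertices)
    adj = G.adjacency
    used: dict[str, list[bool]] = {v: [False] * len(adj[v]) for v in G.vertices}
    path: list[str] = []
    results: set[tuple[str, ...]] = set()

    def dfs(v: str) -> None:
        if len(path) == m:
            if v == start:
                canon = rotate(tuple(path), least_rotation_index(path))
                results.add(canon)
                if len(results) > limit:
                    raise EnumerationOverflowError(
                        limit,
                        frozenset(EdgeCycle(t, G.order) for t in results),
                    )
            return
        flags = used[v]
        for idx, lab in enumerate(adj[v]):
            if not flags[idx]:
                flags[idx] = True
                path.append(lab)
                dfs(lab[1:])
                path.pop()
                flags[idx] = False

    dfs(start)
    return frozenset(EdgeCycle(t, G.order) for t in results)


def _bareiss_det(m: list[list[int]]) -> int:
    """Exact determinant of an integer matrix by fraction-free elimination."""
    n = len(m)
    if n == 0:
        return 1
    a = [row[:] for row in m]
    sign = 1
    prev = 1
    for i in range(n - 1):
        if a[i][i] == 0:
            for j in range(i + 1, n):
                if a[j][i] != 0:
                    a[i], a[j] = a[j], a[i]
                    sign = -sign
                    break
            else:
                return 0
        for j in range(i + 1, n):
            for col in range(i + 1, n):
                a[j][col] = (a[j][col] * a[i][i] - a[j][i] * a[i][col]) // prev
            a[j][i] = 0
        prev = a[i][i]
    return sign * a[n - 1][n - 1]


def count_eulerian_cycles(G: DeBruijnGraph) -> int:
    """Exact number of Eulerian cycles up to rotation, via the BEST theorem.

    ec(G) = t_w(G) * prod_v (outdeg(v) − 1)!  where t_w is the number of
    arborescences oriented toward an arbitrary root w, computed as the
    determinant of the reduced out-degree Laplacian (Matrix-Tree), in exact
    integer arithmetic.  Since every edge label is distinct, an Eulerian
    cycle has no rotational symmetry and this count coincides with the
    number of rotation-equivalence classes returned by
    ``enumerate_eulerian_cycles``.
    """
    diag = diagnose_eulerian(G)
    if not diag.is_eulerian:
        raise NotEulerianError(diag)
    verts = sorted(G.vertices)
    index = {v: i for i, v in enumerate(verts)}
    n = len(verts)
    # Out-degree Laplacian with self-loops excluded (they cancel anyway).
    lap = [[0] * n for _ in range(n)]
    for e in G.edges:
        if e.source == e.target:
            continue
        i, j = index[e.source], index[e.target]
        lap[i][i] += 1
        lap[i][j] -= 1
    reduced = [row[1:] for row in lap[1:]]  # root = verts[0]
    trees = _bareiss_det(reduced)
    count = trees
    for v in verts:
        count *= factorial(G.out_degree(v) - 1)
    return count


# ---------------------------------------------------------------------------
# The Euler <-> Hamilton correspondence
# ---------------------------------------------------------------------------


def euler_to_hamilton(C1: EdgeCycle) -> VertexCycle:
    """Reinterpret the edge labels of an Eulerian cycle in the order-k graph
    as the vertex labels of a Hamiltonian cycle in the order-(k+1) closure
    graph.  The label sequence is preserved exactly."""
    if len(set(C1.labels)) != len(C1.labels) or not _chain_ok(C1.labels, C1.order - 1):
        raise CycleValidationError("input is not a valid edge cycle without repeats")
    return VertexCycle(C1.labels, C1.order + 1)


def hamilton_to_euler(C2: VertexCycle, S: KmerSpectrum) -> EdgeCycle:
    """Inverse of ``euler_to_hamilton``: a Hamiltonian cycle of the closure
    graph of ``S``, read as an Eulerian cycle of the order-k graph of ``S``."""
    if C2.order is None or C2.order != S.k + 1:
        raise CycleValidationError(
            f"cycle order {C2.order} does not match closure graph order {S.k + 1}"
        )
    if set(C2.labels) != S.kmers or len(C2.labels) != len(S.kmers):
        raise CycleValidationError("cycle does not visit exactly the k-mers of S once each")
    if not _chain_ok(C2.labels, S.k - 1):
        raise CycleValidationError("consecutive vertex labels do not overlap correctly")
    return EdgeCycle(C2.labels, S.k)


def hamiltonian_cycle(S: KmerSpectrum) -> VertexCycle:
    """A Hamiltonian cycle of the order-(k+1) closure graph of ``S``, found
    in time linear in |S| by running Hierholzer in the order-k graph and
    mapping across the correspondence."""
    return euler_to_hamilton(eulerian_cycle(_graphs.build_dbg(S)))


def brute_force_hamiltonian(
    G: Union[DeBruijnGraph, OverlapGraph],
    limit: int = 10_000,
    max_vertices: int = 15,
) -> frozenset[VertexCycle]:
    """All Hamiltonian cycles (up to rotation) by exhaustive backtracking.

    Exponential in general — refuses graphs with more than ``max_vertices``
    vertices unless the cap is raised explicitly.  Used as the independent
    oracle on the Hamiltonian side of the correspondence.
    """
    if isinstance(G, DeBruijnGraph):
        succ = {v: [lab[1:] for lab in G.adjacency[v]] for v in G.vertices}
        order: Optional[int] = G.order
        verts = G.vertices
    else:
        succ = {v: G.successors(v) for v in G.vertices}
        order = None
        verts = G.vertices
    n = len(verts)
    if n > max_vertices:
        raise VertexCapExceeded(
            f"{n} vertices exceed the brute-force cap of {max_vertices}"
        )
    start = min(verts)
    sys.setrecursionlimit(max(sys.getrecursionlimit(), 4 * n + 100))
    visited = {v: False for v in verts}
    visited[start] = True
    path = [start]
    results: set[tuple[str, ...]] = set()

    def dfs(v: str) -> None:
        if len(path) == n:
            if start in succ[v]:
                canon = rotate(tuple(path), least_rotation_index(path))
                results.add(canon)
                if len(results) > limit:
                    raise EnumerationOverflowError(
                        limit,
                        frozenset(VertexCycle(t, order) for t in results),
                    )
            return
        for w in succ[v]:
            if not visited[w]:
                visited[w] = True
                path.append(w)
                dfs(w)
                path.pop()
                visited[w] = False

    dfs(start)
    return frozenset(VertexCycle(t, order) for t in results)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def cycle_to_json(C: Union[EdgeCycle, VertexCycle]) -> str:
    import json

    kind = "edge" if isinstance(C, EdgeCycle) else "vertex"
    return json.dumps(
        {"kind": kind, "order": C.order, "labels": list(C.labels)}, sort_keys=True
    )


def cycle_from_json(text: str) -> Union[EdgeCycle, VertexCycle]:
    import json

    payload = json.loads(text)
    if payload["kind"] == "edge":
        return EdgeCycle(tuple(payload["labels"]), payload["order"])
    return VertexCycle(tuple(payload["labels"]), payload["order"])
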