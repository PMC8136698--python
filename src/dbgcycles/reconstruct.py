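"""Spelling cycles into circular genomes, canonical rotations, and unitigs.

A cycle of n k-mer labels spells a circular genome of length n.  The
linearized form writes n + k − 1 characters: one full period followed by a
repeat of the first k − 1 characters, so that every k-mer of the cycle is a
visible substring (the wraparound convention).

Unitigs are the strings spelled by maximal non-branching paths — every
internal vertex has in-degree and out-degree exactly 1.  They are the
unambiguous output of assembly: each one is a substring of every possible
genome reconstruction, whereas a full reconstruction is only one of possibly
many cycles consistent with the same spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cycles import CycleValidationError, EdgeCycle, _chain_ok
from .graphs import DeBruijnGraph
from .seqs import least_rotation_index, rotate


@dataclass(frozen=True)
class Reconstruction:
    """A circular genome spelled by an Eulerian cycle."""

    circular_seq: str
    linearized: str
    source_cycle: EdgeCycle

    @property
    def length(self) -> int:
        return len(self.circular_seq)

    def contains(self, s: str) -> bool:
        """Circular substring query: does ``s`` occur in the genome when it
        is read around the circle (possibly across the wrap point)?"""
        n = len(self.circular_seq)
        reps = 2 + len(s) // max(1, n)
        return s in self.circular_seq * reps


def spell(C: EdgeCycle) -> Reconstruction:
    """Spell a cycle: the first label followed by the last character of each
    subsequent label gives the n + k − 1 character linearization; the first
    n characters are one period of the circular genome."""
    if not _chain_ok(C.labels, C.order - 1):
        raise CycleValidationError("labels do not chain with k-1 overlaps")
    n = len(C.labels)
    linearized = C.labels[0] + "".join(x[-1] for x in C.labels[1:])
    return Reconstruction(linearized[:n], linearized, C)


def canonical_rotation(s: str) -> str:
    """Lexicographically least rotation of a string (Booth); idempotent."""
    if not s:
        raise ValueError("canonical rotation of an empty string is undefined")
    return rotate(s, least_rotation_index(s))


@dataclass(frozen=True)
class Unitig:
    """A maximal non-branching path, spelled as a string.

    ``internal_vertices`` counts path vertices whose in- and out-degree are
    both 1 (for a circular unitig: all of them).  ``edge_labels`` is kept so
    that tests can verify the unitigs partition the edge set.
    """

    seq: str
    internal_vertices: int
    circular: bool
    edge_labels: tuple[str, ...]


def _spell_path(labels: list[str]) -> str:
    return labels[0] + "".join(x[-1] for x in labels[1:])


def unitigs(G: DeBruijnGraph) -> tuple[Unitig, ...]:
    """Maximal non-branching paths of G, each edge in exactly one unitig.

    Paths are grown from every out-edge of a branching vertex (one whose
    in-degree or out-degree differs from 1) and extended while the current
    endpoint is non-branching.  Edges left over belong to components that
    are simple cycles; these are emitted as circular unitigs, canonicalized
    by least rotation of their label sequence and spelled with the k−1
    wraparound.  Linear in the number of edges.
    """
    branching = {
        v for v in G.vertices if not (G.in_degree(v) == 1 and G.out_degree(v) == 1)
    }
    used: set[str] = set()
    out: list[Unitig] = []
    for v in sorted(branching):
        for lab in G.adjacency[v]:
            path = [lab]
            used.add(lab)
            t = lab[1:]
            while t not in branching:
                nxt = G.adjacency[t][0]  # unique out-edge of a 1/1 vertex
                path.append(nxt)
                used.add(nxt)
                t = nxt[1:]
            out.append(
                Unitig(_spell_path(path), len(path) - 1, False, tuple(path))
            )
    # Remaining edges form vertex-disjoint simple cycles (all vertices 1/1).
    for e in G.edges:
        if e.label in used:
            continue
        path = [e.label]
        used.add(e.label)
        t = e.label[1:]
        while t != e.source:
            nxt = G.adjacency[t][0]
            path.append(nxt)
            used.add(nxt)
            t = nxt[1:]
        canon = list(rotate(tuple(path), least_rotation_index(path)))
        # spelled like a linear path; the closing overlap makes the last
        # k-1 characters repeat the first k-1 (wraparound form)
        out.append(Unitig(_spell_path(canon), len(canon), True, tuple(canon)))
    return tuple(sorted(out, key=lambda u: (u.seq, u.edge_labels)))
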