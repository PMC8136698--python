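"""Core string primitives: prefixes/suffixes, k-spectra, and spectrum closure.

The assembly model used throughout this package works on *sets* of k-mers
(multiplicity is never tracked).  The k-spectrum of a read set is the set of
distinct length-k substrings of its reads; the closure of a k-mer set ``S``
is the set of every (k+1)-mer whose length-k prefix and length-k suffix both
belong to ``S`` — i.e. every (k+1)-mer that can be chained from two
overlapping members of ``S``, whether or not it was observed in any read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

#: Default nucleotide alphabet.  All types accept a custom alphabet so that
#: tests can exercise tiny or non-DNA alphabets.
DNA = frozenset("ACGT")


def prefix(t: str, i: int) -> str:
    """First ``i`` characters of ``t``; requires ``0 <= i <= len(t)``."""
    if i < 0 or i > len(t):
        raise ValueError(f"prefix length {i} out of range for string of length {len(t)}")
    return t[:i]


def suffix(t: str, i: int) -> str:
    """Last ``i`` characters of ``t``; requires ``0 <= i <= len(t)``."""
    if i < 0 or i > len(t):
        raise ValueError(f"suffix length {i} out of range for string of length {len(t)}")
    return t[len(t) - i :]


def _check_alphabet(s: str, alphabet: frozenset[str], what: str) -> None:
    bad = set(s) - alphabet
    if bad:
        raise ValueError(f"{what} {s!r} contains characters outside the alphabet: {sorted(bad)}")


@dataclass(frozen=True)
class ReadSet:
    """An unordered collection of reads (strings over a fixed alphabet).

    ``min_length`` is the length of the shortest read; spectra of order up
    to ``min_length`` are well defined for every read.
    """

    reads: tuple[str, ...]
    alphabet: frozenset[str] = DNA

    def __post_init__(self) -> None:
        object.__setattr__(self, "reads", tuple(self.reads))
        object.__setattr__(self, "alphabet", frozenset(self.alphabet))
        if not self.reads:
            raise ValueError("ReadSet requires at least one read")
        for r in self.reads:
            if not r:
                raise ValueError("reads must be non-empty strings")
            _check_alphabet(r, self.alphabet, "read")

    @property
    def min_length(self) -> int:
        return min(len(r) for r in self.reads)

    def __iter__(self) -> Iterator[str]:
        return iter(self.reads)

    def __len__(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class KmerSpectrum:
    """A set of distinct k-mers together with its order ``k``."""

    k: int
    kmers: frozenset[str]
    alphabet: frozenset[str] = DNA

    def __post_init__(self) -> None:
        object.__setattr__(self, "kmers", frozenset(self.kmers))
        object.__setattr__(self, "alphabet", frozenset(self.alphabet))
        if self.k < 1:
            raise ValueError(f"spectrum order must be >= 1, got {self.k}")
        for x in self.kmers:
            if len(x) != self.k:
                raise ValueError(f"k-mer {x!r} has length {len(x)}, expected {self.k}")
            _check_alphabet(x, self.alphabet, "k-mer")

    def __iter__(self) -> Iterator[str]:
        return iter(self.kmers)

    def __len__(self) -> int:
        return len(self.kmers)

    def __contains__(self, x: object) -> bool:
        return x in self.kmers

    def sorted(self) -> list[str]:
        return sorted(self.kmers)


def spectrum(reads: ReadSet, k: int) -> KmerSpectrum:
    """The k-spectrum: all distinct length-k substrings over all reads."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > reads.min_length:
        raise ValueError(f"k={k} exceeds the minimum read length {reads.min_length}")
    kmers: set[str] = set()
    for r in reads:
        for i in range(len(r) - k + 1):
            kmers.add(r[i : i + k])
    return KmerSpectrum(k, frozenset(kmers), reads.alphabet)


def closure(S: KmerSpectrum) -> KmerSpectrum:
    """All (k+1)-mers whose k-prefix and k-suffix both belong to ``S``.

    Equivalently: for every ordered pair (x, z) in S x S whose k−1 overlap
    matches (suffix(x, k−1) == prefix(z, k−1)), the string ``x + z[-1]`` is
    in the result.  The result may contain (k+1)-mers never observed in any
    read; only constructibility from ``S`` matters.
    """
    if not S.kmers:
        raise ValueError("closure of an empty spectrum is undefined")
    k = S.k
    by_prefix: dict[str, set[str]] = {}
    for z in S:
        by_prefix.setdefault(z[: k - 1], set()).add(z[-1])
    out: set[str] = set()
    for x in S:
        for c in by_prefix.get(x[1:] if k > 1 else "", ()):
            out.add(x + c)
    return KmerSpectrum(k + 1, frozenset(out), S.alphabet)


def least_rotation_index(s) -> int:
    """Index of the lexicographically least rotation of a sequence (Booth).

    Works on strings and on tuples of comparable items.  Linear time.
    """
    n = len(s)
    if n == 0:
        raise ValueError("least rotation of an empty sequence is undefined")
    s2 = tuple(s) + tuple(s)
    f = [-1] * (2 * n)
    k = 0
    for j in range(1, 2 * n):
        sj = s2[j]
        i = f[j - k - 1]
        while i != -1 and sj != s2[k + i + 1]:
            if sj < s2[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s2[k + i + 1]:
            if sj < s2[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k % n


def rotate(s, j: int):
    """Rotation of a string or tuple starting at index ``j``."""
    j %= len(s)
    return s[j:] + s[:j]
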