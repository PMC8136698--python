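"""Sequence file I/O: FASTA, FASTQ and plain k-mer lists, gzip-transparent.

FASTA/FASTQ parsing is delegated to Bio.SeqIO.  A "kmer-list" file is plain
text with one sequence per line; blank lines and ``#`` comments are ignored,
and each line is treated as one read (so a file of k-mers is directly usable
as a spectrum of its own order).
"""

from __future__ import annotations

import gzip
import io as _stdio
import re
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .seqs import DNA, ReadSet

_GZIP_MAGIC = b"\x1f\x8b"


def _open_text(path: str | Path):
    """Open a possibly-gzipped file as text, sniffing the magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(path: str | Path) -> str:
    with _open_text(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if stripped.startswith(">"):
                return "fasta"
            if stripped.startswith("@"):
                return "fastq"
            return "kmer-list"
    raise ValueError(f"empty input file: {path}")


def _clean(seq: str, alphabet: frozenset[str], policy: str, record: str) -> list[str]:
    """Apply the out-of-alphabet policy to one uppercased sequence.

    ``split`` breaks the read at every bad character and keeps the
    fragments (the standard assembler behaviour for N bases); ``strict``
    raises instead.
    """
    bad = set(seq) - alphabet
    if not bad:
        return [seq]
    if policy == "strict":
        raise ValueError(
            f"record {record}: characters outside the alphabet: {sorted(bad)}"
        )
    pattern = "[^" + "".join(sorted(alphabet)) + "]+"
    return [frag for frag in re.split(pattern, seq) if frag]


def read_sequences(
    path: str | Path,
    fmt: str = "auto",
    *,
    alphabet: frozenset[str] = DNA,
    policy: str = "split",
    min_fragment: int = 1,
) -> ReadSet:
    """Read a FASTA/FASTQ/k-mer-list file (optionally gzipped) into a ReadSet.

    Sequences are uppercased.  Characters outside ``alphabet`` are handled
    per ``policy`` ("split" or "strict"); fragments shorter than
    ``min_fragment`` are dropped after splitting.  Qualities in FASTQ are
    ignored.
    """
    if fmt == "auto":
        fmt = _sniff_format(path)
    if fmt not in ("fasta", "fastq", "kmer-list"):
        raise ValueError(f"unknown format {fmt!r}")
    if policy not in ("split", "strict"):
        raise ValueError(f"unknown out-of-alphabet policy {policy!r}")

    reads: list[str] = []
    with _open_text(path) as fh:
        if fmt == "kmer-list":
            for lineno, line in enumerate(fh, 1):
                stripped = line.split("#", 1)[0].strip()
                if not stripped:
                    continue
                reads.extend(_clean(stripped.upper(), alphabet, policy, f"line {lineno}"))
        else:
            try:
                for idx, rec in enumerate(SeqIO.parse(fh, fmt)):
                    reads.extend(
                        _clean(str(rec.seq).upper(), alphabet, policy, f"{idx} ({rec.id})")
                    )
            except ValueError as exc:
                raise ValueError(f"malformed {fmt} record in {path}: {exc}") from exc
    reads = [r for r in reads if len(r) >= min_fragment]
    if not reads:
        raise ValueError(f"no usable sequences in {path}")
    return ReadSet(tuple(reads), alphabet)


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (header, sequence) pairs as FASTA (60-column wrapped)."""
    with open(path, "wt") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def format_fasta(records: Iterable[tuple[str, str]]) -> str:
    buf = _stdio.StringIO()
    for header, seq in records:
        buf.write(f">{header}\n")
        for i in range(0, len(seq), 60):
            buf.write(seq[i : i + 60] + "\n")
    return buf.getvalue()


def write_kmer_list(kmers: Iterable[str], path: str | Path) -> None:
    """Write sequences one per line (sorted for reproducibility)."""
    with open(path, "wt") as fh:
        for x in sorted(kmers):
            fh.write(x + "\n")
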