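"""Synthetic circular genomes and idealized read sets.

The generator realizes the idealized sequencing assumptions under which
cycle-based assembly statements hold exactly: the genome is a single
circular string; reads are error-free; and the read set tiles every
position of the circle (one read per rotation start), so the k-spectrum of
the reads equals the k-spectrum of the genome's wraparound linearization
for every k < read length.

Exact repeats can be planted to create reconstruction ambiguity.  Note the
threshold that matters for an order-k de Bruijn graph under set semantics:
a repeat of length k−1 in two distinct contexts duplicates a (k−1)-mer
vertex while keeping all k-mer edges distinct — the graph stays balanced
and typically acquires two or more Eulerian cycles.  A repeat of length
>= k duplicates k-mers themselves; the duplicates collapse to a single
edge and the graph usually loses balance, so no Eulerian cycle exists at
all.  ``ambiguity_scenario`` therefore plants (k−1)-length repeats.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .seqs import ReadSet


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one synthetic genome + read-set draw.

    repeat_spec is a list of (repeat_length, copies) pairs; each repeat is
    an exact motif overwritten at non-overlapping random positions.  The
    seed fully determines the genome and the reads.
    """

    genome_length: int
    read_length: int
    k: int
    seed: int
    alphabet: str = "ACGT"
    repeat_spec: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "repeat_spec", tuple(tuple(p) for p in self.repeat_spec))
        if not (1 <= self.k < self.read_length <= self.genome_length):
            raise ValueError(
                f"need 1 <= k < read_length <= genome_length, got "
                f"k={self.k}, read_length={self.read_length}, "
                f"genome_length={self.genome_length}"
            )
        for length, copies in self.repeat_spec:
            if length < 1 or copies < 1:
                raise ValueError(f"bad repeat_spec entry ({length}, {copies})")
            if length * copies >= self.genome_length:
                raise ValueError(
                    f"repeat of length {length} x {copies} copies does not fit "
                    f"in a genome of length {self.genome_length}"
                )


def simulate_genome(sc: SimScenario) -> str:
    """A random circular genome (returned as one linear period) with every
    specified repeat planted as exact copies at non-overlapping positions."""
    rng = random.Random(sc.seed)
    n = sc.genome_length
    g = rng.choices(sc.alphabet, k=n)
    occupied: list[tuple[int, int]] = []
    for length, copies in sc.repeat_spec:
        motif = rng.choices(sc.alphabet, k=length)
        placed = 0
        for _attempt in range(1000):
            if placed == copies:
                break
            start = rng.randrange(0, n - length + 1)
            span = (start, start + length)
            if any(span[0] < e and s < span[1] for s, e in occupied):
                continue
            occupied.append(span)
            g[span[0] : span[1]] = motif
            placed += 1
        if placed < copies:
            raise ValueError(
                f"could not place {copies} non-overlapping copies of a "
                f"length-{length} repeat in a genome of length {n}"
            )
    return "".join(g)


def simulate_reads(genome: str, sc: SimScenario) -> ReadSet:
    """Full positional tiling of the circular genome: one read per rotation
    start.  Guarantees the reads' k-spectrum equals the genome's for every
    k < read length (the idealized-assumption guarantee)."""
    if sc.read_length > len(genome):
        raise ValueError("read length exceeds genome length")
    doubled = genome + genome
    reads = tuple(doubled[i : i + sc.read_length] for i in range(len(genome)))
    return ReadSet(reads, frozenset(sc.alphabet))


def wraparound(genome: str, k: int) -> str:
    """The wraparound linearization: the circular genome written with its
    first k−1 characters repeated at the end."""
    return genome + genome[: k - 1]


def example_readset() -> tuple[ReadSet, int]:
    """The canonical two-read worked example: R = {TATTA, TAATA}, k = 3.

    Its order-3 de Bruijn graph has exactly two Eulerian cycles spelling
    the circular genomes ATTAAT and ATTATA — the smallest instance of
    repeat-driven reconstruction ambiguity used throughout the tests."""
    return ReadSet(("TATTA", "TAATA")), 3


def ambiguity_scenario(genome_length: int, k: int, seed: int) -> SimScenario:
    """A scenario that plants one (k−1)-length repeat twice: the classic
    source of multiple Eulerian cycles while the graph stays balanced."""
    return SimScenario(
        genome_length=genome_length,
        read_length=k + 2,
        k=k,
        seed=seed,
        repeat_spec=((k - 1, 2),),
    )


def validation_scenarios(seeds_per_cell: int = 5) -> tuple[SimScenario, ...]:
    """The standard battery used to exercise the Euler/Hamilton
    correspondence by exhaustive search on both sides.

    Genome lengths are paired with k so that both cycle enumerations stay
    tractable: order-2 graphs over four letters are dense (at most 16
    vertices and factorially many cycles), so small genomes are used there,
    while sparse high-order graphs run up to length 40.  Each cell is drawn
    with and without a planted (k−1)-repeat, 5 seeds each: 200 scenarios.
    """
    lengths_by_k = {
        2: (8, 10, 12, 14),
        3: (8, 12, 16, 20),
        4: (10, 14, 20, 28),
        5: (12, 18, 26, 34),
        6: (14, 22, 30, 40),
    }
    out: list[SimScenario] = []
    for k, lengths in lengths_by_k.items():
        for n in lengths:
            for planted in (False, True):
                for seed in range(seeds_per_cell):
                    repeat = ((k - 1, 2),) if planted else ()
                    out.append(
                        SimScenario(
                            genome_length=n,
                            read_length=k + 2,
                            k=k,
                            seed=1000 * k + 10 * n + seed + (100_000 if planted else 0),
                            repeat_spec=repeat,
                        )
                    )
    return tuple(out)


# ---------------------------------------------------------------------------
# Scenario config files (key = value text)
# ---------------------------------------------------------------------------


def scenario_to_text(sc: SimScenario) -> str:
    repeats = ",".join(f"{length}x{copies}" for length, copies in sc.repeat_spec)
    lines = [
        f"genome_length = {sc.genome_length}",
        f"read_length = {sc.read_length}",
        f"k = {sc.k}",
        f"seed = {sc.seed}",
        f"alphabet = {sc.alphabet}",
        f"repeats = {repeats}",
    ]
    return "\n".join(lines) + "\n"


def scenario_from_text(text: str) -> SimScenario:
    fields: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ValueError(f"line {lineno}: expected 'key = value', got {stripped!r}")
        key, _, value = stripped.partition("=")
        fields[key.strip()] = value.strip()
    repeats: tuple[tuple[int, int], ...] = ()
    if fields.get("repeats"):
        repeats = tuple(
            (int(part.split("x")[0]), int(part.split("x")[1]))
            for part in fields["repeats"].split(",")
        )
    try:
        return SimScenario(
            genome_length=int(fields["genome_length"]),
            read_length=int(fields["read_length"]),
            k=int(fields["k"]),
            seed=int(fields["seed"]),
            alphabet=fields.get("alphabet", "ACGT"),
            repeat_spec=repeats,
        )
    except KeyError as exc:
        raise ValueError(f"missing scenario field {exc}") from exc
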