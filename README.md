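# dbgcycles

Edge-centric de Bruijn graphs for idealized genome assembly: k-spectra and
their closure, Eulerian cycle finding and exact counting, the
label-preserving correspondence between Eulerian and Hamiltonian cycles,
genome spelling, and unitigs — with a small CLI on top.

## The problem

Given error-free reads from a single circular genome, break them into their
k-mers.  The **k-spectrum** `sp^k(R)` is the set of distinct k-mers of the
read set `R`.  The **edge-centric de Bruijn graph** `dBG^k(S)` of a k-mer
set `S` has the (k−1)-mers of `S` as vertices and one edge per k-mer `x`,
running from its prefix `pre_{k−1}(x)` to its suffix `suf_{k−1}(x)`.  Under
idealized coverage, every genome consistent with the reads is spelled by an
Eulerian cycle of `G1 = dBG^k(sp^k(R))`.

The **closure** of `S` is the set of all (k+1)-mers `y` with
`pre_k(y) ∈ S` and `suf_k(y) ∈ S`.  Writing
`G2 = dBG^{k+1}(closure(S))`, two structural facts drive everything here:

1. the vertex set of `G2` is exactly `S` (whenever `S` is the spectrum of
   reads all longer than k), and
2. a sequence of k-mers is an Eulerian cycle of `G1` **iff** the same
   sequence is a Hamiltonian cycle of `G2` — a one-to-one, label-preserving
   correspondence.  Consequently a Hamiltonian cycle of `G2` can be found
   in `O(|S|)` time by running Hierholzer's algorithm in `G1`, even though
   Hamiltonian cycle is NP-hard in general graphs.

Because repeats make the Eulerian cycle non-unique, a single cycle is an
arbitrary pick among all genomes consistent with the data.  The package
therefore also computes what *is* unambiguous: **unitigs**, the strings
spelled by maximal non-branching paths, each of which occurs in every
reconstruction.  To quantify the ambiguity, all Eulerian cycles can be
enumerated by backtracking, or counted exactly with the **BEST theorem**
(`ec(G) = t_w(G) · ∏_v (out°(v) − 1)!`, arborescence count times out-degree
factorials, evaluated in exact integer arithmetic).

## Worked example

The canonical two-read instance `R = {TATTA, TAATA}`, `k = 3`
(`spectrum = {TAT, ATT, TTA, TAA, AAT, ATA}`):

```sh
$ printf '>r1\nTATTA\n>r2\nTAATA\n' > reads.fasta
$ dbgcycles build reads.fasta -k 3 --out demo
G1: 4 vertices / 6 edges
G2: 6 vertices / 10 edges
$ dbgcycles enumerate reads.fasta -k 3 --out demo
Eulerian cycles in G1: 2
Hamiltonian cycles in G2: 2 (brute_force)
```

Two Eulerian cycles means two distinct circular genomes explain the same
reads.  `demo/reconstructions.fasta` holds both, linearized with the k−1
wraparound (the genomes are the first 6 characters; rotated differently
they read ATTAATAT and ATTATAAT):

```
>reconstruction_1 length=6 circular=true k=3
AATATTAA
>reconstruction_2 length=6 circular=true k=3
AATTATAA
```

The Hamiltonian count (computed independently by brute force in `G2`) is
also 2: the correspondence at work.  The unambiguous output is the unitigs,
which occur in **both** genomes:

```sh
$ dbgcycles assemble reads.fasta -k 3 --mode unitigs --out demo
4 unitigs -> demo/unitigs.fasta   # ATA, ATTA, TAAT, TAT
```

`dbgcycles assemble --mode euler` and `--mode hamilton` produce
byte-identical FASTA — one route runs Hierholzer in `G1`, the other finds a
Hamiltonian cycle of `G2` and maps it back, and the correspondence
guarantees the same label sequence.

The library mirrors the CLI one-to-one
(`spectrum`, `closure`, `build_dbg`, `build_closure_graph`,
`eulerian_cycle`, `enumerate_eulerian_cycles`, `count_eulerian_cycles`,
`euler_to_hamilton` / `hamilton_to_euler`, `brute_force_hamiltonian`,
`spell`, `unitigs`, and the `simulate` module for synthetic genomes).

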