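# Methods

## Model and scope

The package works in the idealized single-strand assembly setting: one
circular genome over {A,C,G,T}, error-free reads, and complete coverage in
the sense that the reads' k-spectrum equals the genome's.  Reverse
complements are deliberately not modeled, and k-mer multiplicities are
never tracked: a spectrum is a *set* of k-mers, so a k-mer occurring twice
in the genome contributes one edge.  All claims verified by the test suite
are claims about this model; real sequencing data (errors, double-stranded
DNA, uneven coverage, multiplicity information) is out of scope.

## Definitions and conventions

* **Spectrum** `sp^k(R)`: distinct length-k substrings over all reads.
  Valid for `k ≤ min read length`; graph-level results additionally assume
  `k < min read length` (so every k-mer sits inside some (k+1)-mer).
* **Edge-centric de Bruijn graph** `dBG^k(S)`: vertices are the (k−1)-mers
  occurring as prefixes/suffixes of `S`; each k-mer is one edge.  The
  vertex set is induced from the edges, so isolated vertices cannot exist.
  Orders below 2 are rejected (vertices would be empty strings).
* **Closure**: all (k+1)-mers whose k-prefix and k-suffix are both in `S`
  — including ones never observed in a read.  `dBG^{k+1}(closure(S))` is
  the line digraph of `dBG^k(S)`; its vertex set equals `S` whenever `S`
  is a spectrum with `k <` min read length.
* **Cycles are rotation classes.**  Two label sequences denote the same
  cycle iff one is a rotation of the other; reversal is *not* identified
  (the graphs are directed).  The canonical representative is the
  lexicographically least rotation, found with Booth's algorithm.  Since
  edge labels within an Eulerian cycle are distinct, a cycle has no
  rotational symmetry, and the BEST-theorem count (see below) counts
  exactly these rotation classes.
* **Spelling.**  A cycle of n k-mer labels spells a circular genome of
  length n; the linearized form is `x_0` followed by the last character of
  each subsequent label — n + k − 1 characters whose final k−1 equal the
  first k−1 (wraparound).  Reconstructions are compared as circular
  strings via the canonical (least) rotation; substring queries against a
  reconstruction are circular (`Reconstruction.contains`), since a motif
  may span the wrap point of any particular linearization.

## Algorithms

* **Hierholzer** (`eulerian_cycle`): iterative, linear in the edge count.
  Determinism without a seed: traversal starts at the lexicographically
  smallest vertex and consumes out-edges in sorted label order; closed
  sub-tours are spliced as the stack unwinds.  Non-Eulerian inputs raise
  an error carrying the diagnosis (unbalanced vertices, connectivity),
  computed by degree comparison plus a two-pass reachability check.
* **Enumeration** (`enumerate_eulerian_cycles`): backtracking over unused
  out-edges from a fixed start vertex; every complete traversal is
  canonicalized by least rotation, which deduplicates the d°(start)
  rediscoveries of each cycle.  A limit (default 10,000) guards the
  factorial growth; exceeding it raises an explicit overflow error
  carrying the partial result — never a silent truncation.
* **Exact counting** (`count_eulerian_cycles`): BEST theorem,
  `ec(G) = t_w(G) · ∏_v (out°(v) − 1)!`, with the arborescence count
  `t_w` obtained from the reduced out-degree Laplacian determinant
  (Matrix-Tree), evaluated by Bareiss fraction-free elimination in exact
  integer arithmetic — floating point is never used, so counts are exact
  at any magnitude.  Self-loops are excluded from the Laplacian (their
  contributions cancel) but counted in the out-degree factorials.
* **The correspondence** (`euler_to_hamilton` / `hamilton_to_euler`): the
  identity on label sequences, plus validation that the input is a genuine
  Eulerian (resp. Hamiltonian) cycle.  `hamiltonian_cycle(S)` finds a
  Hamiltonian cycle of the closure graph in O(|S|) time by running
  Hierholzer in `dBG^k(S)` and reinterpreting edge labels as vertices.
* **Brute-force Hamiltonian** (`brute_force_hamiltonian`): exponential
  backtracking over vertices, kept purely as the independent oracle for
  the Hamiltonian side; it refuses graphs above a vertex cap (default 15)
  unless the cap is raised explicitly.
* **Unitigs**: maximal paths whose internal vertices have in-degree =
  out-degree = 1, grown from every out-edge of each branching vertex;
  leftover edges form vertex-disjoint simple cycles, emitted as circular
  unitigs canonicalized by least rotation.  Every edge lands in exactly
  one unitig; linear time.
* **Overlap graphs**: one arc per ordered read pair carrying the *maximal*
  suffix-prefix overlap ≥ the minimum-overlap parameter (duplicate reads
  collapsed, self-arcs excluded).  Whether multiple overlap lengths should
  yield parallel arcs is left open by the usual definition; the single
  maximal arc is this package's choice.

## Synthetic data

`simulate_genome` draws a uniform random circular genome and overwrites it
with exact repeat motifs at non-overlapping random positions;
`simulate_reads` tiles the circle with one read per starting position.
Tiling (rather than random sampling) makes the idealized coverage
assumption hold *deterministically*: `sp^k(reads) = sp^k(genome)` for
every `k <` read length, which is what makes the downstream cycle
statements testable at all.  A fixed seed determines all outputs; there is
no global random state.

A repeat's effect depends on its length relative to k.  A repeat of
length k−1 in two distinct contexts duplicates a vertex while keeping all
edges distinct: the graph stays balanced and typically gains additional
Eulerian cycles (reconstruction ambiguity).  A repeat of length ≥ k
duplicates k-mers, which collapse under set semantics and usually
unbalance the graph — then *no* Eulerian cycle exists, and correspondingly
no Hamiltonian cycle of the closure graph.  `ambiguity_scenario` therefore
plants (k−1)-length repeats.  For the same reason the de Bruijn graph of a
random genome is only Eulerian when all its k-mer occurrences are
distinct; with genome length n over 4 letters, chance collisions make this
rare below roughly `n² ≪ 2·4^k` (a birthday bound), which is why the
ambiguity demonstrations run at k = 4, genome length 30.

`validation_scenarios()` is the standard battery for the correspondence
tests: genome lengths 8–40 paired with k ∈ {2..6} so that exhaustive
enumeration on both sides stays in seconds (order-2 graphs over four
letters are dense — at most 16 vertices and factorially many cycles — so
small genomes are used there; sparse high-order graphs run up to length
40), read length k+2, with and without a planted (k−1)-repeat, five seeds
per cell: 200 scenarios, of which (at these seeds) roughly half are
Eulerian and the rest exercise the empty-empty side of the
correspondence.  The large-scale Hierholzer check runs one graph of
100,000 edges (genome length 10^5, k = 21, where chance k-mer collisions
are vanishingly unlikely).

## Numerical and degenerate-input choices

* Empty read sets, empty spectra, order-1 graphs, and empty-string
  rotations are rejected with explicit errors rather than given
  conventions.
* `closure({x})` of a non-self-overlapping k-mer is the empty set; the
  empty spectrum is representable, but building a graph from it is not.
* Ties everywhere (adjacency order, start vertices, output ordering) are
  broken lexicographically, making every output byte-stable across runs.
* Reads containing characters outside the alphabet are split at those
  characters by default (fragments kept), or rejected in strict mode.
* GFA1 export writes segments per k-mer edge label with (k−1)-character
  overlap links — the edge-centric graph presented node-centrically at
  order k, which is what GFA viewers expect.

## Known limitations

* Enumeration and brute-force Hamiltonian search are exponential and are
  meant for small instances (oracles, teaching, the worked example); the
  linear-time outputs are Hierholzer's cycle and the unitigs.
* No Eulerian *paths* (linear genomes), no reverse-complement
  canonicalization, no multiplicities, no error model — each would change
  the statements being verified, not just the implementation.
* The BEST count coincides with enumeration because edge labels are
  distinct (simple digraph); it is not written for multigraphs, which
  cannot arise from a k-mer set.
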