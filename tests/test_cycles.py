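"""Eulerian/Hamiltonian machinery: Hierholzer, enumeration, BEST counting,
and the label-preserving correspondence between the two cycle kinds."""

import random

import networkx as nx
import pytest

from conftest import random_circular_genome
from dbgcycles import (
    EdgeCycle,
    EnumerationOverflowError,
    KmerSpectrum,
    NotEulerianError,
    ReadSet,
    VertexCapExceeded,
    VertexCycle,
    brute_force_hamiltonian,
    build_closure_graph,
    build_dbg,
    build_overlap_graph,
    count_eulerian_cycles,
    diagnose_eulerian,
    enumerate_eulerian_cycles,
    euler_to_hamilton,
    eulerian_cycle,
    hamilton_to_euler,
    hamiltonian_cycle,
    is_eulerian_cycle,
    is_hamiltonian_cycle,
    spectrum,
)
from dbgcycles.cycles import CycleValidationError, cycle_from_json, cycle_to_json


def circular_spectrum(genome: str, k: int, alphabet=frozenset("ACGT")) -> KmerSpectrum:
    lin = genome + genome[: k - 1]
    return spectrum(ReadSet((lin,), alphabet), k)


# ---------------------------------------------------------------------------
# Diagnosis
# ---------------------------------------------------------------------------


def test_worked_example_is_eulerian(g1):
    d = diagnose_eulerian(g1)
    assert d.is_eulerian and d.connected and not d.unbalanced_vertices


def test_single_edge_graph_is_unbalanced():
    d = diagnose_eulerian(build_dbg(KmerSpectrum(2, {"AC"})))
    assert not d.is_eulerian
    assert ("A", 0, 1) in d.unbalanced_vertices and ("C", 1, 0) in d.unbalanced_vertices


def test_balanced_but_disconnected_union_of_cycles():
    # two vertex-disjoint 3-cycles over disjoint sub-alphabets
    S = circular_spectrum("ACG", 2).kmers | circular_spectrum("TTT", 2).kmers
    d = diagnose_eulerian(build_dbg(KmerSpectrum(2, S)))
    assert not d.unbalanced_vertices
    assert not d.connected and not d.is_eulerian


@pytest.mark.parametrize("seed", range(20))
def test_diagnosis_agrees_with_networkx_oracle(seed):
    genome = random_circular_genome(random.Random(seed).randint(6, 20), seed)
    g = build_dbg(circular_spectrum(genome, 3))
    nxg = nx.DiGraph()
    nxg.add_edges_from((e.source, e.target) for e in g.edges)
    assert diagnose_eulerian(g).is_eulerian == nx.is_eulerian(nxg)


def test_balanced_when_circular_genome_kmers_distinct():
    genome = "ATTAAT"
    g = build_dbg(circular_spectrum(genome, 3))
    assert not diagnose_eulerian(g).unbalanced_vertices


# ---------------------------------------------------------------------------
# Hierholzer
# ---------------------------------------------------------------------------


def test_hierholzer_on_worked_example(g1):
    c = eulerian_cycle(g1)
    assert is_eulerian_cycle(c, g1)
    assert len(c.labels) == g1.n_edges  # each edge consumed exactly once


def test_hierholzer_single_self_loop():
    g = build_dbg(KmerSpectrum(2, {"AA"}))
    assert eulerian_cycle(g).labels == ("AA",)


def test_hierholzer_is_deterministic(g1):
    assert eulerian_cycle(g1).labels == eulerian_cycle(g1).labels


def test_hierholzer_refuses_non_eulerian_with_diagnosis():
    g = build_dbg(KmerSpectrum(2, {"AC"}))
    with pytest.raises(NotEulerianError) as exc:
        eulerian_cycle(g)
    assert exc.value.diagnosis.unbalanced_vertices


def test_hierholzer_on_500_edge_simulated_graph():
    # a genome long enough that its 9-spectrum has ~500 distinct k-mers
    genome = random_circular_genome(500, 42)
    g = build_dbg(circular_spectrum(genome, 9))
    d = diagnose_eulerian(g)
    assert d.is_eulerian  # verified for this fixed seed
    c = eulerian_cycle(g)
    assert is_eulerian_cycle(c, g)
    assert len(c.labels) == g.n_edges


# ---------------------------------------------------------------------------
# Enumeration and BEST counting
# ---------------------------------------------------------------------------


def test_enumeration_finds_exactly_two_cycles(g1):
    E = enumerate_eulerian_cycles(g1)
    assert len(E) == 2
    for c in E:
        assert is_eulerian_cycle(c, g1)
        assert c.canonical().labels == c.labels  # results are canonical


def test_single_cycle_graph_has_one_eulerian_cycle():
    g = build_dbg(circular_spectrum("ACGT", 2))
    assert len(enumerate_eulerian_cycles(g)) == 1
    assert count_eulerian_cycles(g) == 1


def test_best_count_on_worked_example(g1):
    assert count_eulerian_cycles(g1) == 2


def test_hierholzer_output_is_among_enumerated(g1):
    E = {c.labels for c in enumerate_eulerian_cycles(g1)}
    assert eulerian_cycle(g1).canonical().labels in E


def test_enumeration_limit_overflow_carries_partial():
    # order-2 complete graph over a 3-letter sub-alphabet has many cycles
    S = KmerSpectrum(2, {a + b for a in "ACG" for b in "ACG"})
    g = build_dbg(S)
    total = count_eulerian_cycles(g)
    assert total > 3
    with pytest.raises(EnumerationOverflowError) as exc:
        enumerate_eulerian_cycles(g, limit=3)
    assert exc.value.limit == 3
    assert len(exc.value.partial) == 4


def collect_small_eulerian_graphs(n_graphs: int = 60):
    graphs = []
    seed = 0
    while len(graphs) < n_graphs:
        seed += 1
        rng = random.Random(seed)
        k = rng.choice([2, 3])
        genome = random_circular_genome(rng.randint(3, 10), seed)
        g = build_dbg(circular_spectrum(genome, k))
        if g.n_edges <= 10 and diagnose_eulerian(g).is_eulerian:
            graphs.append(g)
    return graphs


def test_best_theorem_equals_enumeration_on_random_graphs():
    """BEST-theorem counts match exhaustive enumeration on >= 50 graphs."""
    graphs = collect_small_eulerian_graphs(60)
    assert len(graphs) >= 50
    for g in graphs:
        assert count_eulerian_cycles(g) == len(enumerate_eulerian_cycles(g))


def test_count_refuses_non_eulerian():
    with pytest.raises(NotEulerianError):
        count_eulerian_cycles(build_dbg(KmerSpectrum(2, {"AC"})))


# ---------------------------------------------------------------------------
# The correspondence
# ---------------------------------------------------------------------------


def test_euler_to_hamilton_preserves_labels(g1, g2):
    for c1 in enumerate_eulerian_cycles(g1):
        c2 = euler_to_hamilton(c1)
        assert c2.labels == c1.labels
        assert c2.order == g2.order
        assert is_hamiltonian_cycle(c2, g2)


def test_hamilton_to_euler_inverts(example_spectrum, g1, g2):
    for c2 in brute_force_hamiltonian(g2):
        c1 = hamilton_to_euler(c2, example_spectrum)
        assert c1.labels == c2.labels
        assert is_eulerian_cycle(c1, g1)
        assert euler_to_hamilton(c1).labels == c2.labels


def test_round_trip_on_self_loop():
    S = KmerSpectrum(2, {"AA"})
    c2 = hamiltonian_cycle(S)
    assert c2.labels == ("AA",)
    assert hamilton_to_euler(c2, S).labels == ("AA",)


def test_hamiltonian_cycle_is_linear_time_route(example_spectrum, g2):
    c2 = hamiltonian_cycle(example_spectrum)
    assert is_hamiltonian_cycle(c2, g2)


def test_hamilton_to_euler_rejects_wrong_vertex_set(example_spectrum):
    bad = VertexCycle(("TAT", "ATT", "TTA"), 4)
    with pytest.raises(CycleValidationError):
        hamilton_to_euler(bad, example_spectrum)


def test_euler_to_hamilton_rejects_broken_chain():
    with pytest.raises(CycleValidationError):
        euler_to_hamilton(EdgeCycle(("AAT", "TTT"), 3))


# ---------------------------------------------------------------------------
# Brute-force Hamiltonian oracle
# ---------------------------------------------------------------------------


def test_brute_force_on_closure_graph_finds_two_cycles(g2):
    H = brute_force_hamiltonian(g2)
    assert len(H) == 2
    for c in H:
        assert is_hamiltonian_cycle(c, g2)


def test_complete_digraph_on_three_vertices_has_two_hamiltonian_cycles():
    # hand enumeration: 3 distinct items admit exactly 2 directed cyclic orders
    reads = ReadSet(("ACA", "AGA", "ATA"))
    g = build_overlap_graph(reads, 1)
    assert all(len(g.successors(v)) == 2 for v in g.vertices)
    assert len(brute_force_hamiltonian(g)) == 2


def test_vertex_cap_refusal(g2):
    with pytest.raises(VertexCapExceeded):
        brute_force_hamiltonian(g2, max_vertices=3)
    assert len(brute_force_hamiltonian(g2, max_vertices=6)) == 2


@pytest.mark.parametrize("seed", range(50))
def test_bijection_counts_on_simulated_spectra(seed):
    """|Eulerian cycles of G1| == |Hamiltonian cycles of G2| (main bijection)."""
    rng = random.Random(seed)
    k = rng.choice([2, 3, 4])
    genome = random_circular_genome(rng.randint(6, 14), 7000 + seed)
    S = circular_spectrum(genome, k)
    g1, g2 = build_dbg(S), build_closure_graph(S)
    H = brute_force_hamiltonian(g2, max_vertices=32)
    if diagnose_eulerian(g1).is_eulerian:
        E = enumerate_eulerian_cycles(g1)
        assert len(E) == len(H)
        for c in E:
            assert euler_to_hamilton(c).canonical() in {h.canonical() for h in H}
    else:
        assert len(H) == 0


def test_cycle_json_roundtrip(g1):
    c = eulerian_cycle(g1)
    assert cycle_from_json(cycle_to_json(c)) == c
    c2 = euler_to_hamilton(c)
    assert cycle_from_json(cycle_to_json(c2)) == c2
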