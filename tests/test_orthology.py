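"""Alignment scores vs brute-force DP, hit-graph filters, MCL behaviour."""

import numpy as np
import networkx as nx
import pytest

from oracles import sw_score_oracle
from panlineage import orthology
from panlineage.orthology import (
    AlignParams,
    align_pair,
    build_hit_graph,
    families_from_partition,
    mcl_cluster,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, lo=20, hi=80):
    return "".join(rng.choice(list(AA), int(rng.integers(lo, hi + 1))))


def test_self_alignment_is_perfect():
    s = "MKVLAWQRDEYHNSTPGCIF"
    hit = align_pair(s, s)
    assert hit.identity == 100.0
    assert hit.coverage_a == 100.0 and hit.coverage_b == 100.0


def test_sw_score_matches_quadratic_oracle():
    rng = np.random.default_rng(42)
    for _ in range(50):
        a = random_protein(rng)
        b = random_protein(rng)
        if rng.random() < 0.5:  # include related pairs
            b = "".join(
                c if rng.random() > 0.2 else rng.choice(list(AA)) for c in a
            )
        hit = align_pair(a, b)
        assert hit.score == sw_score_oracle(a, b)


def test_banded_equals_full_for_high_identity_pairs():
    rng = np.random.default_rng(3)
    for _ in range(20):
        a = random_protein(rng, 100, 200)
        b = "".join(c if rng.random() > 0.04 else rng.choice(list(AA)) for c in a)
        full = align_pair(a, b, AlignParams(band=-1))
        banded = align_pair(a, b, AlignParams(band=48))
        assert full.score == banded.score
        assert full.identity == banded.identity


def test_unrelated_sequences_fail_evalue_cutoff():
    rng = np.random.default_rng(0)
    fails = 0
    n = 40
    for _ in range(n):
        a = random_protein(rng, 300, 300)
        b = random_protein(rng, 300, 300)
        if align_pair(a, b).evalue > 1e-4:
            fails += 1
    assert fails >= 0.95 * n


def test_illegal_residue_rejected():
    with pytest.raises(ValueError):
        align_pair("MKV", "MK1")
    with pytest.raises(ValueError):
        align_pair("", "MK")


def _toy_proteomes(rng, n_strains=4, n_families=5, length=90, div=0.03):
    ancestors = [random_protein(rng, length, length) for _ in range(n_families)]
    proteomes = {}
    truth = {}
    for s in range(n_strains):
        sid = f"st{s}"
        genes = []
        for f, anc in enumerate(ancestors):
            seq = "".join(
                c if rng.random() > div else rng.choice(list(AA)) for c in anc
            )
            gid = f"{sid}_g{f}"
            genes.append((gid, seq))
            truth.setdefault(f, set()).add(gid)
        proteomes[sid] = genes
    return proteomes, truth


def test_hit_graph_families_form_cliques_and_graph_is_symmetric():
    rng = np.random.default_rng(5)
    proteomes, truth = _toy_proteomes(rng)
    graph = build_hit_graph(proteomes, AlignParams())
    for members in truth.values():
        sub = graph.subgraph(members)
        assert sub.number_of_edges() == len(members) * (len(members) - 1) // 2
    for u, v in graph.edges:
        assert graph.has_edge(v, u)
    # no cross-family edges at ~3% within-family divergence
    gene_fam = {g: f for f, m in truth.items() for g in m}
    assert all(gene_fam[u] == gene_fam[v] for u, v in graph.edges)


def test_prefilter_matches_exhaustive_candidates():
    rng = np.random.default_rng(6)
    proteomes, _ = _toy_proteomes(rng, n_strains=3, n_families=4)
    g1 = build_hit_graph(proteomes, AlignParams(use_prefilter=True))
    g2 = build_hit_graph(proteomes, AlignParams(use_prefilter=False))
    assert set(map(frozenset, g1.edges)) == set(map(frozenset, g2.edges))


def test_low_identity_edge_dropped():
    # two halves identical, rest unrelated -> local identity high but
    # coverage of either sequence < 50 fails the coverage rule
    rng = np.random.default_rng(8)
    core = random_protein(rng, 30, 30)
    a = core + random_protein(rng, 70, 70)
    b = core + random_protein(rng, 70, 70)
    graph = build_hit_graph(
        {"s1": [("a", a)], "s2": [("b", b)]},
        AlignParams(use_prefilter=False),
    )
    assert graph.number_of_edges() == 0


# ---------------------------------------------------------------------------
# MCL
# ---------------------------------------------------------------------------

def test_mcl_two_disjoint_triangles():
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)], weight=1.0)
    partition = mcl_cluster(g)
    assert sorted(sorted(c) for c in partition) == [[0, 1, 2], [3, 4, 5]]


def test_mcl_isolated_node_is_singleton():
    g = nx.Graph()
    g.add_edge(0, 1, weight=1.0)
    g.add_node(99)
    partition = mcl_cluster(g)
    assert {99} in partition


def test_mcl_barbell_splits_at_inflation_two():
    g = nx.Graph()
    for block in (range(5), range(5, 10)):
        block = list(block)
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                g.add_edge(block[i], block[j], weight=1.0)
    g.add_edge(4, 5, weight=1.0)  # bridge
    partition = mcl_cluster(g, inflation=2.0)
    assert sorted(sorted(c) for c in partition) == [[0, 1, 2, 3, 4], [5, 6, 7, 8, 9]]


def test_mcl_never_merges_components():
    rng = np.random.default_rng(2)
    g = nx.Graph()
    offset = 0
    comps = []
    for size in (3, 5, 7):
        nodes = list(range(offset, offset + size))
        for i in nodes:
            for j in nodes:
                if i < j and rng.random() < 0.7:
                    g.add_edge(i, j, weight=float(rng.uniform(0.5, 2)))
        for n in nodes:
            g.add_node(n)
        comps.append(set(nodes))
        offset += size
    partition = mcl_cluster(g)
    for cluster in partition:
        assert any(cluster <= comp for comp in nx.connected_components(g))


def test_inflation_preserves_column_stochasticity():
    rng = np.random.default_rng(9)
    M = rng.random((12, 12))
    M /= M.sum(axis=0, keepdims=True)
    for r in (1.5, 2.0, 4.0):
        P = orthology._inflate(M, r)
        np.testing.assert_allclose(P.sum(axis=0), 1.0, atol=1e-9)
    P = orthology._prune(M, 1e-2)
    np.testing.assert_allclose(P.sum(axis=0), 1.0, atol=1e-9)


def test_mcl_requires_valid_inflation():
    g = nx.Graph()
    g.add_edge(0, 1, weight=1.0)
    with pytest.raises(ValueError):
        mcl_cluster(g, inflation=1.0)


# ---------------------------------------------------------------------------
# families_from_partition
# ---------------------------------------------------------------------------

def test_families_ordered_by_size_then_gene_id():
    partition = [{"c", "d"}, {"a", "b", "e", "f"}]
    strains = {g: f"s{i}" for i, g in enumerate("abcdef")}
    fams = families_from_partition(partition, strains)
    assert fams[0].gf_id == "GF00001" and fams[0].size == 4
    assert fams[1].size == 2


def test_families_invariant_under_input_order():
    rng = np.random.default_rng(10)
    proteomes, _ = _toy_proteomes(rng, n_strains=3, n_families=3)
    fams1, _ = orthology.build_families(proteomes)
    shuffled = {
        sid: list(reversed(genes)) for sid, genes in reversed(proteomes.items())
    }
    fams2, _ = orthology.build_families(shuffled)
    sets1 = {f.gene_ids() for f in fams1}
    sets2 = {f.gene_ids() for f in fams2}
    assert sets1 == sets2


def test_duplicate_gene_in_partition_rejected():
    with pytest.raises(ValueError):
        families_from_partition([{"a"}, {"a", "b"}], {"a": "s", "b": "s"})
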