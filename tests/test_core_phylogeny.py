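"""Progressive alignment, NJ additivity, bootstrap consensus, rooting."""

import dendropy
import numpy as np
import pytest

from oracles import nw_score_oracle, random_additive_tree
from panlineage.core_phylogeny import (
    Tree,
    align_family,
    bootstrap_consensus,
    concatenate,
    global_align,
    jc_distance_matrix,
    majority_consensus,
    nj_tree,
    root_on_outgroup,
)

NT = np.array(list("ACGT"))


def rand_seq(rng, n):
    return "".join(rng.choice(NT, n))


def mutate(seq, rate, rng):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([c for c in "ACGT" if c != out[i]])
    return "".join(out)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def test_identical_sequences_align_gap_free():
    aln = align_family([("a", "ACGTACGT"), ("b", "ACGTACGT"), ("c", "ACGTACGT")])
    assert aln.n_columns == 8
    assert not (aln.rows < 0).any()


def test_pairwise_score_matches_dp_oracle():
    rng = np.random.default_rng(0)
    score, ga, gb = global_align("ACGT", "ACT")
    assert score == nw_score_oracle("ACGT", "ACT")
    assert len(ga) == len(gb)
    assert ga.replace("-", "") == "ACGT" and gb.replace("-", "") == "ACT"
    assert sum(c == "-" for c in ga + gb) == 1  # single gap column
    for _ in range(30):
        a = rand_seq(rng, int(rng.integers(5, 40)))
        b = rand_seq(rng, int(rng.integers(5, 40)))
        score, _, _ = global_align(a, b)
        assert score == nw_score_oracle(a, b)


def test_column_count_at_least_max_input_length():
    rng = np.random.default_rng(1)
    seqs = [(f"t{i}", rand_seq(rng, int(rng.integers(20, 40)))) for i in range(5)]
    aln = align_family(seqs)
    assert aln.n_columns >= max(len(s) for _, s in seqs)
    for t, s in seqs:
        assert aln.row_str(t).replace("-", "") == s


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        align_family([("a", "ACGT"), ("b", "")])


def test_concatenate_lengths_and_sources():
    aln1 = align_family([("a", "ACGTACGTAC"), ("b", "ACGTACGTAC")], source="GF1")
    aln2 = align_family([("a", "TTTTTTTTTT"), ("b", "TTTTTTTTTT")], source="GF2")
    cat = concatenate([aln1, aln2])
    assert cat.n_columns == aln1.n_columns + aln2.n_columns
    assert set(cat.column_sources) == {"GF1", "GF2"}
    assert cat.column_sources.count("GF1") == aln1.n_columns


def test_concatenate_missing_taxon_names_block():
    aln1 = align_family([("a", "ACGTAC"), ("b", "ACGTAC")], source="GF1")
    aln2 = align_family([("a", "ACGTAC"), ("c", "ACGTAC")], source="GF2")
    with pytest.raises(ValueError, match="GF2"):
        concatenate([aln1, aln2], taxa=["a", "b"])


# ---------------------------------------------------------------------------
# NJ
# ---------------------------------------------------------------------------

def _splits(tree: Tree):
    return tree.bipartitions()


def test_nj_recovers_known_four_taxon_tree():
    # tree ((A:1,B:2):5,(C:3,D:4)); additive distances
    labels = ["A", "B", "C", "D"]
    D = np.array(
        [
            [0, 3, 9, 10],
            [3, 0, 10, 11],
            [9, 10, 0, 7],
            [10, 11, 7, 0],
        ],
        dtype=float,
    )
    tree = nj_tree(D, labels)
    assert _splits(tree) == {frozenset({"C", "D"})}
    # branch lengths recovered exactly: leaf distances reproduce D
    dmat = _tree_distances(tree, labels)
    np.testing.assert_allclose(dmat, D, atol=1e-9)


def _tree_distances(tree: Tree, labels):
    t = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
    pdm = t.phylogenetic_distance_matrix()
    taxa = {x.label: x for x in t.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return out


def test_nj_exactly_recovers_random_additive_matrices():
    rng = np.random.default_rng(2)
    for trial in range(30):
        n = int(rng.integers(4, 7))
        D, labels, true_splits = random_additive_tree(n, rng)
        tree = nj_tree(D, labels)
        assert _splits(tree) == true_splits
        np.testing.assert_allclose(_tree_distances(tree, labels), D, atol=1e-8)


def test_nj_three_taxa_unique_topology():
    D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
    tree = nj_tree(D, ["x", "y", "z"])
    assert sorted(tree.leaf_names()) == ["x", "y", "z"]
    assert _splits(tree) == set()


def test_nj_invariant_under_taxon_permutation():
    rng = np.random.default_rng(3)
    D, labels, _ = random_additive_tree(6, rng)
    t1 = nj_tree(D, labels)
    perm = rng.permutation(6)
    t2 = nj_tree(D[np.ix_(perm, perm)], [labels[i] for i in perm])
    assert _splits(t1) == _splits(t2)  # Robinson-Foulds distance 0


def test_nj_rejects_asymmetric_matrix():
    with pytest.raises(ValueError):
        nj_tree(np.array([[0, 1], [2, 0]], dtype=float), ["a", "b"])


# ---------------------------------------------------------------------------
# bootstrap + consensus
# ---------------------------------------------------------------------------

def _clade_alignment(rng, n_per_clade=3, L=600, clade_div=0.25, tip_div=0.01):
    root = rand_seq(rng, L)
    seqs = []
    for c in range(4):
        anc = mutate(root, clade_div, rng)
        for t in range(n_per_clade):
            seqs.append((f"c{c}_t{t}", mutate(anc, tip_div, rng)))
    return align_family(seqs)


def test_distinct_clades_get_full_support():
    rng = np.random.default_rng(4)
    aln = _clade_alignment(rng)
    tree = bootstrap_consensus(aln, n_reps=50, seed=9)
    sup = tree.bipartitions(with_support=True)
    for c in range(4):
        clade = {f"c{c}_t{t}" for t in range(3)}
        s = tree.support_of_clade(clade)
        assert s is not None and s == pytest.approx(100.0)
    assert all(v is None or v > 50 for v in sup.values())


def test_single_replicate_supports_are_binary():
    rng = np.random.default_rng(5)
    aln = _clade_alignment(rng, n_per_clade=2, L=300)
    tree = bootstrap_consensus(aln, n_reps=1, seed=1)
    sups = [v for v in tree.bipartitions(with_support=True).values() if v is not None]
    assert sups and all(v in (0.0, 100.0) for v in sups)


def test_majority_consensus_matches_dendropy_oracle():
    rng = np.random.default_rng(6)
    taxa = [f"T{i}" for i in range(8)]
    trees = []
    for _ in range(9):
        D, labels, _ = random_additive_tree(8, rng)
        noise = rng.uniform(0, 2.0, D.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        trees.append(nj_tree(D + noise, labels))
    mine = majority_consensus(trees)
    dtrees = dendropy.TreeList(
        [
            dendropy.Tree.get(data=t.to_newick(), schema="newick")
            for t in trees
        ],
        taxon_namespace=dendropy.TaxonNamespace(taxa),
    )
    oracle = dtrees.consensus(min_freq=0.5)
    ref = min(taxa)
    expected = set()
    for nd in oracle.preorder_internal_node_iter(exclude_seed_node=True):
        side = {lf.taxon.label for lf in nd.leaf_iter()}
        if ref in side:
            side = set(taxa) - side
        if 2 <= len(side) <= len(taxa) - 2:
            expected.add(frozenset(side))
    assert mine.bipartitions() == expected


def test_consensus_bipartitions_mutually_compatible():
    rng = np.random.default_rng(7)
    trees = []
    for _ in range(7):
        D, labels, _ = random_additive_tree(7, rng)
        trees.append(nj_tree(D, labels))
    cons = majority_consensus(trees)
    splits = list(cons.bipartitions())
    for i, a in enumerate(splits):
        for b in splits[i + 1 :]:
            assert a <= b or b <= a or not (a & b)


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

def test_outgroup_becomes_sister_to_rest():
    D, labels, _ = random_additive_tree(5, np.random.default_rng(8))
    tree = nj_tree(D, labels)
    rooted = root_on_outgroup(tree, "T0")
    assert len(rooted.root.children) == 2
    names = [
        {l.name for l in c.leaves()} for c in rooted.root.children
    ]
    assert {"T0"} in names


def test_rooting_idempotent():
    D, labels, _ = random_additive_tree(5, np.random.default_rng(9))
    tree = nj_tree(D, labels)
    once = root_on_outgroup(tree, "T2")
    twice = root_on_outgroup(once, "T2")
    assert once.to_newick() == twice.to_newick()


def test_rooting_preserves_leaf_distances():
    D, labels, _ = random_additive_tree(6, np.random.default_rng(10))
    tree = nj_tree(D, labels)
    rooted = root_on_outgroup(tree, "T3")
    np.testing.assert_allclose(
        _tree_distances(rooted, labels), _tree_distances(tree, labels), atol=1e-8
    )


def test_missing_outgroup_rejected():
    D, labels, _ = random_additive_tree(4, np.random.default_rng(11))
    with pytest.raises(ValueError):
        root_on_outgroup(nj_tree(D, labels), "nope")


def test_jc_distance_matches_formula():
    rows = np.array([[0, 1, 2, 3, 0, 1], [0, 1, 2, 3, 0, 2]], dtype=np.int8)
    D = jc_distance_matrix(rows)
    p = 1 / 6
    expected = -0.75 * np.log(1 - 4 * p / 3)
    assert D[0, 1] == pytest.approx(expected)
    # saturated pair capped
    rows2 = np.array([[0] * 8, [1] * 8], dtype=np.int8)
    assert jc_distance_matrix(rows2)[0, 1] == 3.0
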