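"""Core-genome phylogeny: alignment, NJ, bootstrap, majority-rule consensus.

Single-copy core gene families are aligned per family with a deterministic
progressive aligner (pairwise global scores +1 match / -1 mismatch / -2 gap,
single-linkage guide order, frequency-profile merges), concatenated, and
summarised as a neighbor-joining tree under Jukes-Cantor distances.
Branch support comes from bootstrap resampling of alignment columns
(majority-rule consensus of the replicate trees).  Distance-based NJ is
used deliberately: the claims made on the tree are topology-level (family
clades, outgroup placement) and NJ is exactly testable through additivity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np
import scipy.cluster.hierarchy as sch

from ._kernels import profile_align

__all__ = [
    "Alignment",
    "Node",
    "Tree",
    "align_family",
    "global_align",
    "concatenate",
    "jc_distance_matrix",
    "nj_tree",
    "bootstrap_consensus",
    "majority_consensus",
    "root_on_outgroup",
]

_LUT = np.full(256, -1, np.int8)
for _i, _c in enumerate("ACGT"):
    _LUT[ord(_c)] = _i
_DECODE = np.array(list("ACGT-"))


def _encode_row(seq: str) -> np.ndarray:
    arr = _LUT[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    return arr


@dataclass
class Alignment:
    """Equal-length gapped nucleotide rows with per-column source labels."""

    taxa: list[str]
    rows: np.ndarray  # int8 taxa x columns; 0..3 = ACGT, -1 = gap
    column_sources: list[str]

    def __post_init__(self) -> None:
        if self.rows.ndim != 2 or self.rows.shape[0] != len(self.taxa):
            raise ValueError("rows must be taxa x columns")
        if len(self.column_sources) != self.rows.shape[1]:
            raise ValueError("one source label per column required")

    @property
    def n_columns(self) -> int:
        return self.rows.shape[1]

    def row_str(self, taxon: str) -> str:
        i = self.taxa.index(taxon)
        out = self.rows[i].copy()
        out[out < 0] = 4
        return "".join(_DECODE[out])


def _profile(rows: np.ndarray) -> np.ndarray:
    """(L, 5) float32 frequency profile over (A, C, G, T, gap)."""
    m, L = rows.shape
    freq = np.empty((L, 5), np.float32)
    for s in range(4):
        freq[:, s] = (rows == s).sum(axis=0)
    freq[:, 4] = (rows < 0).sum(axis=0)
    return freq / m


def _apply_map(rows: np.ndarray, idx: np.ndarray) -> np.ndarray:
    out = np.full((rows.shape[0], idx.shape[0]), -1, np.int8)
    sel = idx >= 0
    out[:, sel] = rows[:, idx[sel]]
    return out


def global_align(a: str, b: str) -> tuple[float, str, str]:
    """Pairwise global alignment (+1 match, -1 mismatch, -2 gap)."""
    ra = _encode_row(a)[None, :]
    rb = _encode_row(b)[None, :]
    if ra.shape[1] == 0 or rb.shape[1] == 0:
        raise ValueError("empty sequence")
    score, ia, ib = profile_align(
        _profile(ra), _profile(rb), 1.0, -1.0, -2.0
    )
    ga = _apply_map(ra, ia)[0]
    gb = _apply_map(rb, ib)[0]
    ga[ga < 0] = 4
    gb[gb < 0] = 4
    return float(score), "".join(_DECODE[ga]), "".join(_DECODE[gb])


def align_family(
    seqs: Sequence[tuple[str, str]], source: str = ""
) -> Alignment:
    """Progressive multiple alignment of homologous nucleotide sequences.

    Guide order: single linkage over pairwise edit distances; merges are
    frequency-profile global alignments under the +1/-1/-2 scoring.
    Deterministic for a given input order.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    taxa = [t for t, _ in seqs]
    for t, s in seqs:
        if not s:
            raise ValueError(f"empty sequence for {t}")
    rows = [_encode_row(s)[None, :] for _, s in seqs]
    n = len(rows)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = edlib.align(seqs[i][1], seqs[j][1], task="distance")["editDistance"]
            D[i, j] = D[j, i] = d
    Z = sch.linkage(D[np.triu_indices_from(D, k=1)], method="single")
    clusters: dict[int, tuple[list[int], np.ndarray]] = {
        i: ([i], rows[i]) for i in range(n)
    }
    for step, (ci, cj, _, _) in enumerate(Z):
        ta, ra = clusters.pop(int(ci))
        tb, rb = clusters.pop(int(cj))
        _, ia, ib = profile_align(_profile(ra), _profile(rb), 1.0, -1.0, -2.0)
        merged = np.vstack([_apply_map(ra, ia), _apply_map(rb, ib)])
        clusters[n + step] = (ta + tb, merged)
    order, aligned = clusters.popitem()[1]
    # restore input taxon order
    perm = np.argsort(np.argsort(order))
    inv = np.empty(len(order), dtype=int)
    for pos, taxon_idx in enumerate(order):
        inv[taxon_idx] = pos
    aligned = aligned[inv]
    L = aligned.shape[1]
    return Alignment(taxa=taxa, rows=aligned.astype(np.int8),
                     column_sources=[source] * L)


def concatenate(
    alignments: Sequence[Alignment], taxa: Sequence[str] | None = None
) -> Alignment:
    """Column-wise concatenation of per-family alignments.

    Every block must cover every taxon (single-copy core families
    guarantee this); a missing taxon raises an error naming the block.
    """
    if not alignments:
        raise ValueError("no alignments to concatenate")
    if taxa is None:
        taxa = list(alignments[0].taxa)
    blocks = []
    sources: list[str] = []
    for aln in alignments:
        missing = [t for t in taxa if t not in aln.taxa]
        if missing:
            src = aln.column_sources[0] if aln.column_sources else "?"
            raise ValueError(f"block {src!r} missing taxa {missing}")
        idx = [aln.taxa.index(t) for t in taxa]
        blocks.append(aln.rows[idx])
        sources.extend(aln.column_sources)
    return Alignment(
        taxa=list(taxa), rows=np.hstack(blocks), column_sources=sources
    )


def jc_distance_matrix(rows: np.ndarray, cap: float = 3.0) -> np.ndarray:
    """Jukes-Cantor distances between gapped rows.

    p-distances are computed over sites where both rows are ungapped;
    saturated (p >= 3/4) or incomparable pairs are capped at ``cap``.
    """
    rows = np.asarray(rows)
    valid = (rows >= 0).astype(np.float32)
    matches = np.zeros((rows.shape[0], rows.shape[0]), np.float32)
    for s in range(4):
        ind = (rows == s).astype(np.float32)
        matches += ind @ ind.T
    pairs = valid @ valid.T
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 1.0 - matches / pairs
        arg = 1.0 - 4.0 * p / 3.0
        d = -0.75 * np.log(arg)
    d[~np.isfinite(d)] = cap
    d[pairs == 0] = cap
    d = np.minimum(d, cap)
    np.fill_diagonal(d, 0.0)
    return d.astype(float)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class Node:
    name: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def copy(self) -> "Node":
        return Node(
            self.name, self.length, self.support, [c.copy() for c in self.children]
        )


@dataclass
class Tree:
    root: Node

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.root.leaves()]

    def copy(self) -> "Tree":
        return Tree(self.root.copy())

    def bipartitions(self, with_support: bool = False):
        """Non-trivial splits, each as the frozenset excluding the
        lexicographically smallest taxon; optionally with supports."""
        all_taxa = frozenset(self.leaf_names())
        ref = min(all_taxa)
        out: dict[frozenset, float | None] = {}

        def rec(node: Node) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset()
            for c in node.children:
                below |= rec(c)
            if node is not self.root and 2 <= len(below) <= len(all_taxa) - 2:
                side = below if ref not in below else all_taxa - below
                if 2 <= len(side) <= len(all_taxa) - 2:
                    prev = out.get(side)
                    if prev is None or (node.support or 0) > (prev or 0):
                        out[side] = node.support
            return below

        rec(self.root)
        if with_support:
            return out
        return set(out)

    def support_of_clade(self, taxa: set[str]) -> float | None:
        """Support of the split separating ``taxa`` from the rest, if present."""
        all_taxa = frozenset(self.leaf_names())
        ref = min(all_taxa)
        want = frozenset(taxa)
        side = want if ref not in want else all_taxa - want
        return self.bipartitions(with_support=True).get(side)

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                base = node.name or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = "" if node.support is None else str(int(round(node.support)))
                base = f"({inner}){label}"
            if node.length is not None:
                base += f":{node.length:.10g}"
            return base

        return fmt(self.root) + ";"


def _min_leaf(node: Node) -> str:
    return min(l.name for l in node.leaves())


def nj_tree(D: np.ndarray, labels: Sequence[str]) -> Tree:
    """Canonical neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    (sorted) pair of cluster labels, where a cluster is labelled by its
    smallest leaf.  Negative branch lengths are clamped to zero with the
    deficit moved to the sister branch.  The result is unrooted (trifurcate
    root for n >= 3).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or np.abs(np.diag(D)).max() > 1e-12:
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if len(labels) != n:
        raise ValueError("labels must match matrix size")
    nodes = [Node(name=l) for l in labels]
    if n == 1:
        return Tree(nodes[0])
    if n == 2:
        half = D[0, 1] / 2.0
        nodes[0].length = half
        nodes[1].length = half
        return Tree(Node(children=nodes))
    W = D.copy()
    clusters: list[Node] = [nodes[i] for i in range(n)]
    keys: list[str] = [_min_leaf(c) for c in clusters]
    while len(clusters) > 3:
        m = len(clusters)
        r = W.sum(axis=1)
        Q = (m - 2) * W - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        tol = 1e-10 * max(1.0, abs(qmin))
        ti, tj = np.where(Q <= qmin + tol)
        best = None
        for a, b in zip(ti.tolist(), tj.tolist()):
            if a >= b:
                continue
            key = tuple(sorted((keys[a], keys[b])))
            if best is None or key < best[2]:
                best = (a, b, key)
        i, j, _ = best
        dij = W[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        ci, cj = clusters[i], clusters[j]
        ci.length = float(li)
        cj.length = float(lj)
        parent = Node(children=[ci, cj])
        newd = (W[i] + W[j] - dij) / 2.0
        keep = [k for k in range(m) if k not in (i, j)]
        W2 = np.empty((m - 1, m - 1))
        W2[:-1, :-1] = W[np.ix_(keep, keep)]
        W2[-1, :-1] = newd[keep]
        W2[:-1, -1] = newd[keep]
        W2[-1, -1] = 0.0
        W = W2
        clusters = [clusters[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]
    dij, dik, djk = W[0, 1], W[0, 2], W[1, 2]
    lengths = (
        max(0.0, (dij + dik - djk) / 2.0),
        max(0.0, (dij + djk - dik) / 2.0),
        max(0.0, (dik + djk - dij) / 2.0),
    )
    for node, l in zip(clusters, lengths):
        node.length = float(l)
    kids = sorted(clusters, key=_min_leaf)
    return Tree(Node(children=kids))


def majority_consensus(
    trees: Sequence[Tree], min_support: float = 50.0
) -> Tree:
    """Majority-rule consensus: splits present in > ``min_support`` % of
    trees, added greedily in decreasing support under compatibility."""
    if not trees:
        raise ValueError("no trees")
    taxa = sorted(trees[0].leaf_names())
    counts: Counter = Counter()
    for t in trees:
        if sorted(t.leaf_names()) != taxa:
            raise ValueError("trees must share one taxon set")
        for bp in t.bipartitions():
            counts[bp] += 1
    n = len(trees)
    cands = [
        (100.0 * c / n, bp)
        for bp, c in counts.items()
        if 100.0 * c / n > min_support
    ]
    cands.sort(key=lambda x: (-x[0], -len(x[1]), sorted(x[1])))
    chosen: list[tuple[float, frozenset]] = []
    for sup, bp in cands:
        if all(
            bp <= other or other <= bp or not (bp & other)
            for _, other in chosen
        ):
            chosen.append((sup, bp))
    return _tree_from_splits(taxa, chosen)


def _tree_from_splits(
    taxa: Sequence[str], splits: Sequence[tuple[float, frozenset]]
) -> Tree:
    root = Node(children=[Node(name=t) for t in taxa])
    for sup, bp in sorted(splits, key=lambda x: -len(x[1])):
        node = root
        while True:
            for child in node.children:
                leaves = {l.name for l in child.leaves()}
                if bp <= leaves and not child.is_leaf and bp != frozenset(leaves):
                    node = child
                    break
            else:
                break
        inside = [c for c in node.children if {l.name for l in c.leaves()} <= bp]
        covered = set()
        for c in inside:
            covered |= {l.name for l in c.leaves()}
        if covered != set(bp):
            continue  # incompatible with current resolution; skip defensively
        for c in inside:
            node.children.remove(c)
        node.children.append(Node(support=sup, children=inside))
    return Tree(root)


def bootstrap_consensus(
    alignment: Alignment,
    n_reps: int = 100,
    seed: int = 0,
    cap: float = 3.0,
) -> Tree:
    """Bootstrap NJ trees over resampled columns; majority-rule consensus.

    Each replicate resamples alignment columns with replacement, computes
    Jukes-Cantor distances (incomparable pairs capped at ``cap``) and an NJ
    tree; node supports are the percentage of replicates containing the
    corresponding bipartition.
    """
    if len(alignment.taxa) < 4:
        raise ValueError("bootstrap consensus needs >= 4 taxa")
    rng = np.random.default_rng(seed)
    rows = alignment.rows
    n, L = rows.shape
    # Column resampling only reweights columns, so per-pair mismatch and
    # gap column indices can be precomputed once (sparse for the
    # low-divergence alignments this stage sees) and each replicate's
    # p-distance obtained by summing resample weights — algebraically
    # identical to recomputing distances on the resampled matrix.
    gaps = rows < 0
    mism_idx: list[np.ndarray] = []
    gap_idx: list[np.ndarray] = []
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    for i, j in pairs:
        either_gap = gaps[i] | gaps[j]
        mism_idx.append(np.flatnonzero(~either_gap & (rows[i] != rows[j])))
        gap_idx.append(np.flatnonzero(either_gap))
    trees = []
    for _ in range(n_reps):
        w = np.bincount(rng.integers(0, L, L), minlength=L).astype(np.float64)
        D = np.zeros((n, n))
        for (i, j), mi, gi in zip(pairs, mism_idx, gap_idx):
            valid = L - (w[gi].sum() if gi.size else 0.0)
            if valid <= 0:
                D[i, j] = D[j, i] = cap
                continue
            p = (w[mi].sum() if mi.size else 0.0) / valid
            arg = 1.0 - 4.0 * p / 3.0
            d = cap if arg <= 0 else min(cap, -0.75 * np.log(arg))
            D[i, j] = D[j, i] = d
        trees.append(nj_tree(D, alignment.taxa))
    return majority_consensus(trees)


def root_on_outgroup(tree: Tree, outgroup: str) -> Tree:
    """Root on the midpoint of the outgroup's pendant edge (idempotent)."""
    if outgroup not in tree.leaf_names():
        raise ValueError(f"outgroup {outgroup!r} not among taxa")
    root = tree.root
    if len(root.children) == 2 and any(
        c.is_leaf and c.name == outgroup for c in root.children
    ):
        return tree.copy()
    # build adjacency over node objects
    import itertools

    counter = itertools.count()
    ids: dict[int, Node] = {}
    adj: dict[int, list[tuple[int, float | None, float | None]]] = {}

    def build(node: Node) -> int:
        nid = next(counter)
        ids[nid] = node
        adj.setdefault(nid, [])
        for c in node.children:
            cid = build(c)
            adj[nid].append((cid, c.length, c.support))
            adj[cid].append((nid, c.length, c.support))
        return nid

    build(tree.root)
    leaf_id = next(
        nid for nid, node in ids.items() if node.is_leaf and node.name == outgroup
    )
    (parent_id, w, _sup) = adj[leaf_id][0]
    half = None if w is None else w / 2.0

    def rebuild(nid: int, from_id: int) -> Node:
        node = ids[nid]
        kids = [
            (cid, l, s) for cid, l, s in adj[nid] if cid != from_id
        ]
        if node.is_leaf:
            return Node(name=node.name)
        children = []
        for cid, l, s in kids:
            child = rebuild(cid, nid)
            if child.length is None:
                child.length = l
            elif l is not None:
                # degree-2 collapse below: merge the two edge lengths
                child.length += l
            if child.support is None:
                child.support = s
            children.append(child)
        if len(children) == 1:
            # collapse the degree-2 node created at the old root position
            return children[0]
        # supports travel with edges (set by the caller), not with nodes
        return Node(children=children)

    out_leaf = Node(name=outgroup, length=half)
    rest = rebuild(parent_id, leaf_id)
    rest.length = half
    return Tree(Node(children=[out_leaf, rest]))
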