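"""Gene-family construction: all-against-all protein alignment + MCL.

The similarity search follows the classical reciprocal protocol: every gene
pair is scored with a local Smith-Waterman alignment (BLOSUM62, affine gaps
open 11 / extend 1) and an edge is kept when the E-value, percent identity
and coverage thresholds all pass.  Because the scorer is symmetric the kept
graph is reciprocal by construction.  Families are the clusters of the
Markov Cluster Algorithm run on the score-weighted graph.

The E-value is a Karlin-Altschul style approximation
``E = K * m * n * exp(-lambda * S)`` with gapped constants
(lambda = 0.267, K = 0.041); it is an approximation to BLAST's statistics,
not a replication, and can be bypassed with ``use_evalue=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
from Bio.Align import substitution_matrices

from ._kernels import sw_align, sw_align_batch

__all__ = [
    "AlignParams",
    "PairwiseHit",
    "HitEdge",
    "GeneFamily",
    "align_pair",
    "build_hit_graph",
    "mcl_cluster",
    "families_from_partition",
    "build_families",
]

_PROTEIN_CODES = frozenset(ord(c) - 65 for c in "ACDEFGHIKLMNPQRSTVWYX")


def _blosum62() -> np.ndarray:
    B = substitution_matrices.load("BLOSUM62")
    sub = np.full((26, 26), -4, np.int32)
    for x in B.alphabet:
        for y in B.alphabet:
            if x.isalpha() and y.isalpha():
                sub[ord(x) - 65, ord(y) - 65] = int(B[x, y])
    return sub


_BLOSUM62 = _blosum62()


@dataclass(frozen=True)
class AlignParams:
    """Scoring and filtering parameters for the similarity search.

    ``gap_open``/``gap_ext`` follow the BLAST convention: a gap of length g
    costs ``gap_open + gap_ext * g``.  ``coverage_mode`` selects whether the
    coverage threshold must hold for *either* sequence (the default, the
    literal "50% of either protein sequence" reading) or for *both*.
    ``band < 0`` evaluates the full DP matrix; a non-negative band restricts
    the alignment to a diagonal corridor (exact for the near-collinear,
    high-identity pairs the synthetic cohorts produce).
    """

    gap_open: int = 11
    gap_ext: int = 1
    lambda_: float = 0.267
    k_const: float = 0.041
    max_evalue: float = 1e-4
    min_identity: float = 50.0
    min_coverage: float = 50.0
    coverage_mode: str = "either"  # either | both
    use_evalue: bool = True
    band: int = -1
    prefilter_k: int = 6
    prefilter_min_shared: int = 2
    use_prefilter: bool = True


class PairwiseHit(NamedTuple):
    score: int
    identity: float
    coverage_a: float
    coverage_b: float
    evalue: float


@dataclass(frozen=True)
class HitEdge:
    """One kept (reciprocal) similarity edge between two genes."""

    query_gene: str
    subject_gene: str
    identity: float
    coverage_q: float
    coverage_s: float
    score: float
    evalue: float


@dataclass
class GeneFamily:
    """A cluster of homologous genes across strains."""

    gf_id: str
    members: dict[str, list[str]] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return sum(len(v) for v in self.members.values())

    @property
    def n_strains(self) -> int:
        return len(self.members)

    def gene_ids(self) -> frozenset[str]:
        return frozenset(g for v in self.members.values() for g in v)


def _encode_protein(seq: str, label: str = "?") -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8).astype(np.int64) - 65
    bad = set(arr.tolist()) - _PROTEIN_CODES
    if bad or len(seq) == 0:
        letters = sorted(chr(b + 65) for b in bad)
        raise ValueError(
            f"sequence {label}: empty or illegal residues {letters}"
        )
    return arr.astype(np.uint8)


def align_pair(
    a: str, b: str, params: AlignParams = AlignParams()
) -> PairwiseHit:
    """Local Smith-Waterman alignment of two protein sequences.

    Returns score (raw), percent identity over alignment columns, coverage
    of each sequence (% of its length spanned by the local alignment) and
    the approximate E-value.
    """
    ea = _encode_protein(a, "a")
    eb = _encode_protein(b, "b")
    score, matches, cols, a0, a1, b0, b1 = sw_align(
        ea, eb, _BLOSUM62, params.gap_open + params.gap_ext, params.gap_ext,
        params.band,
    )
    if cols == 0:
        return PairwiseHit(0, 0.0, 0.0, 0.0, np.inf)
    identity = 100.0 * matches / cols
    cov_a = 100.0 * (a1 - a0) / len(a)
    cov_b = 100.0 * (b1 - b0) / len(b)
    evalue = params.k_const * len(a) * len(b) * float(np.exp(-params.lambda_ * score))
    return PairwiseHit(int(score), identity, cov_a, cov_b, evalue)


def _candidate_pairs(
    encoded: list[np.ndarray], k: int, min_shared: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pairs of gene indices (i < j) sharing >= min_shared distinct k-mers."""
    kmer_ids: dict[bytes, int] = {}
    rows: list[np.ndarray] = []
    for arr in encoded:
        b = arr.tobytes()
        seen = {b[i : i + k] for i in range(0, len(b) - k + 1)}
        ids = np.fromiter(
            (kmer_ids.setdefault(km, len(kmer_ids)) for km in seen),
            dtype=np.int64,
            count=len(seen),
        )
        rows.append(ids)
    indptr = np.zeros(len(rows) + 1, dtype=np.int64)
    indptr[1:] = np.cumsum([len(r) for r in rows])
    indices = np.concatenate(rows) if rows else np.empty(0, np.int64)
    data = np.ones(indices.shape[0], dtype=np.int32)
    X = sp.csr_matrix(
        (data, indices, indptr), shape=(len(rows), len(kmer_ids))
    )
    C = (X @ X.T).tocoo()
    mask = (C.data >= min_shared) & (C.row < C.col)
    return C.row[mask].astype(np.int64), C.col[mask].astype(np.int64)


def build_hit_graph(
    proteomes: Mapping[str, Sequence[tuple[str, str]]],
    params: AlignParams = AlignParams(),
) -> nx.Graph:
    """Build the reciprocal similarity graph over all genes of all strains.

    Nodes are gene ids (with a ``strain`` attribute); an undirected edge is
    kept iff E-value <= ``max_evalue`` (when ``use_evalue``), identity >=
    ``min_identity`` and the coverage rule passes; edge weight is the raw
    alignment score.  A shared-k-mer prefilter skips pairs that cannot
    plausibly reach the identity threshold; it can be switched off for
    oracle comparisons.
    """
    if len(proteomes) < 2:
        raise ValueError("need proteomes from at least 2 strains")
    gene_ids: list[str] = []
    gene_strain: list[str] = []
    encoded: list[np.ndarray] = []
    seen: set[str] = set()
    for strain, genes in proteomes.items():
        for gid, seq in genes:
            if gid in seen:
                raise ValueError(f"duplicate gene id {gid!r}")
            seen.add(gid)
            gene_ids.append(gid)
            gene_strain.append(strain)
            encoded.append(_encode_protein(seq, gid))
    graph = nx.Graph()
    for gid, strain in zip(gene_ids, gene_strain):
        graph.add_node(gid, strain=strain)

    if params.use_prefilter:
        pi, pj = _candidate_pairs(
            encoded, params.prefilter_k, params.prefilter_min_shared
        )
    else:
        n = len(encoded)
        grid = np.triu_indices(n, k=1)
        pi, pj = grid[0].astype(np.int64), grid[1].astype(np.int64)

    lengths = np.array([e.shape[0] for e in encoded], dtype=np.int64)
    offsets = np.zeros(len(encoded), dtype=np.int64)
    if len(encoded):
        offsets[1:] = np.cumsum(lengths)[:-1]
    seqcat = (
        np.concatenate(encoded) if encoded else np.empty(0, np.uint8)
    )
    go = params.gap_open + params.gap_ext
    ge = params.gap_ext
    chunk = 200_000
    for lo in range(0, pi.shape[0], chunk):
        ci = pi[lo : lo + chunk]
        cj = pj[lo : lo + chunk]
        res = sw_align_batch(
            seqcat, offsets, lengths, ci, cj, _BLOSUM62, go, ge, params.band
        )
        score = res[:, 0].astype(float)
        cols = res[:, 2].astype(float)
        ok = cols > 0
        identity = np.zeros(res.shape[0])
        identity[ok] = 100.0 * res[ok, 1] / cols[ok]
        ok &= identity >= params.min_identity
        la = lengths[ci].astype(float)
        lb = lengths[cj].astype(float)
        cov_a = 100.0 * (res[:, 4] - res[:, 3]) / la
        cov_b = 100.0 * (res[:, 6] - res[:, 5]) / lb
        if params.coverage_mode == "either":
            ok &= np.maximum(cov_a, cov_b) >= params.min_coverage
        else:
            ok &= np.minimum(cov_a, cov_b) >= params.min_coverage
        if params.use_evalue:
            evalue = params.k_const * la * lb * np.exp(-params.lambda_ * score)
            ok &= evalue <= params.max_evalue
        else:
            evalue = np.full(res.shape[0], np.nan)
        for t in np.flatnonzero(ok):
            graph.add_edge(
                gene_ids[ci[t]],
                gene_ids[cj[t]],
                weight=float(score[t]),
                identity=float(identity[t]),
                coverage_q=float(cov_a[t]),
                coverage_s=float(cov_b[t]),
                evalue=float(evalue[t]),
            )
    return graph


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def _inflate(M: np.ndarray, r: float) -> np.ndarray:
    P = M ** r
    return P / P.sum(axis=0, keepdims=True)


def _prune(M: np.ndarray, threshold: float) -> np.ndarray:
    M = np.where(M < threshold, 0.0, M)
    s = M.sum(axis=0, keepdims=True)
    s[s == 0.0] = 1.0
    return M / s


def _mcl_component(
    A: np.ndarray, inflation: float, prune: float, tol: float, max_iter: int
) -> tuple[list[list[int]], bool]:
    n = A.shape[0]
    A = A.astype(float).copy()
    # self-loops: max incident edge weight (standard regularization)
    selfw = A.max(axis=0)
    selfw[selfw <= 0] = 1.0
    np.fill_diagonal(A, selfw)
    M = A / A.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M  # expansion
        M = _inflate(M, inflation)
        M = _prune(M, prune)
        if prev.shape == M.shape and np.max(np.abs(M - prev)) < tol:
            converged = True
            break
    # attractors: nodes retaining probability mass on their own diagonal
    diag = np.diag(M)
    att = np.where(diag > 1e-6)[0]
    if att.size == 0:
        return [list(range(n))], converged
    support = M[att] > 1e-8  # attractor x node
    # group attractors sharing any supported node
    adj = (support @ support.T) > 0
    natt = att.size
    group = -np.ones(natt, dtype=int)
    g = 0
    for s in range(natt):
        if group[s] >= 0:
            continue
        stack = [s]
        group[s] = g
        while stack:
            u = stack.pop()
            for v in np.where(adj[u])[0]:
                if group[v] < 0:
                    group[v] = g
                    stack.append(v)
        g += 1
    clusters: list[set[int]] = [set() for _ in range(g)]
    for s, gi in enumerate(group):
        clusters[gi].add(int(att[s]))
    for j in range(n):
        col = M[att, j]
        best = col.max()
        if best <= 0:
            continue
        tied = np.where(col >= best - 1e-12)[0]
        cand_groups = sorted({int(group[t]) for t in tied}, key=lambda gi: min(clusters[gi]))
        clusters[cand_groups[0]].add(j)
    out = [sorted(c) for c in clusters if c]
    return out, converged


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    prune: float = 1e-5,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> list[set]:
    """Markov Cluster Algorithm on a non-negatively weighted graph.

    Expansion (squaring of the column-stochastic matrix with self-loops) and
    inflation (entrywise power ``inflation`` + column renormalization) are
    alternated, with pruning of entries below ``prune``, until the matrix
    changes by less than ``tol`` or ``max_iter`` iterations are reached
    (warning; the current partition is returned).  The algorithm is run per
    connected component, so clusters never span components.
    """
    if inflation <= 1.0:
        raise ValueError("inflation must be > 1")
    partition: list[set] = []
    unconverged = 0
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        if len(nodes) == 1:
            partition.append({nodes[0]})
            continue
        idx = {v: i for i, v in enumerate(nodes)}
        A = np.zeros((len(nodes), len(nodes)))
        for u, v, w in graph.edges(comp, data="weight", default=1.0):
            if u in idx and v in idx:
                if w < 0:
                    raise ValueError("edge weights must be non-negative")
                A[idx[u], idx[v]] = w
                A[idx[v], idx[u]] = w
        clusters, converged = _mcl_component(A, inflation, prune, tol, max_iter)
        if not converged:
            unconverged += 1
        for c in clusters:
            partition.append({nodes[i] for i in c})
    if unconverged:
        warnings.warn(
            f"MCL did not converge within {max_iter} iterations for "
            f"{unconverged} component(s); returning current partition",
            stacklevel=2,
        )
    return partition


def families_from_partition(
    partition: Iterable[set],
    gene_strain: Mapping[str, str],
) -> list[GeneFamily]:
    """Turn an MCL partition into deterministic GeneFamily objects.

    Families are ordered by (size descending, smallest member gene id) and
    ids assigned ``GF00001``, ``GF00002``, ...
    """
    clusters = [sorted(c) for c in partition]
    seen: set[str] = set()
    for c in clusters:
        for g in c:
            if g in seen:
                raise ValueError(f"gene {g!r} appears in more than one cluster")
            seen.add(g)
    clusters.sort(key=lambda c: (-len(c), c[0]))
    families = []
    for i, c in enumerate(clusters):
        fam = GeneFamily(gf_id=f"GF{i + 1:05d}")
        for g in c:
            fam.members.setdefault(gene_strain[g], []).append(g)
        families.append(fam)
    return families


def build_families(
    proteomes: Mapping[str, Sequence[tuple[str, str]]],
    params: AlignParams = AlignParams(),
    inflation: float = 2.0,
) -> tuple[list[GeneFamily], nx.Graph]:
    """Convenience wrapper: hit graph -> MCL -> gene families."""
    graph = build_hit_graph(proteomes, params)
    partition = mcl_cluster(graph, inflation=inflation)
    gene_strain = {g: d["strain"] for g, d in graph.nodes(data=True)}
    families = families_from_partition(partition, gene_strain)
    return families, graph


def fast_params() -> AlignParams:
    """Parameters tuned for near-collinear synthetic cohorts (banded DP)."""
    return AlignParams(band=48)


def _families_tsv(families: Sequence[GeneFamily]) -> str:
    lines = ["gene_id\tstrain_id\tgf_id"]
    for fam in families:
        for strain, genes in sorted(fam.members.items()):
            for g in genes:
                lines.append(f"{g}\t{strain}\t{fam.gf_id}")
    return "\n".join(lines) + "\n"


def write_families_tsv(families: Sequence[GeneFamily], path) -> None:
    from pathlib import Path

    Path(path).write_text(_families_tsv(families))


def read_families_tsv(path) -> list[GeneFamily]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    fams: dict[str, GeneFamily] = {}
    for row in df.itertuples(index=False):
        fam = fams.setdefault(row.gf_id, GeneFamily(gf_id=row.gf_id))
        fam.members.setdefault(row.strain_id, []).append(row.gene_id)
    return sorted(fams.values(), key=lambda f: f.gf_id)
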