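"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (quadratic DP, exhaustive
enumeration) and shares no code with the package implementation.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def blosum62(x: str, y: str) -> int:
    return int(_B62[x, y])


def sw_score_oracle(a: str, b: str, gap_open_total: int = 12, gap_ext: int = 1) -> int:
    """Full quadratic Smith-Waterman with affine gaps (Gotoh), score only.

    Gap of length g costs ``gap_open_total + gap_ext * (g - 1)``.
    """
    m, n = len(a), len(b)
    NEG = -(10**9)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open_total, E[i][j - 1] - gap_ext)
            F[i][j] = max(H[i - 1][j] - gap_open_total, F[i - 1][j] - gap_ext)
            d = H[i - 1][j - 1] + blosum62(a[i - 1], b[j - 1])
            H[i][j] = max(0, d, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def nw_score_oracle(
    a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> int:
    """Full quadratic global alignment score, linear gaps."""
    m, n = len(a), len(b)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        H[i][0] = H[i - 1][0] + gap
    for j in range(1, n + 1):
        H[0][j] = H[0][j - 1] + gap
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(
                H[i - 1][j - 1] + s, H[i - 1][j] + gap, H[i][j - 1] + gap
            )
    return H[m][n]


def mwu_exact_oracle(x, y) -> tuple[float, float]:
    """Exhaustive-enumeration Mann-Whitney: (U_min, two-sided exact p).

    Enumerates all C(n1+n2, n1) group labelings of the pooled sample.
    Assumes no ties.
    """
    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    n1, n2 = len(x), len(y)

    def u1_of(group_x) -> int:
        gx = list(group_x)
        gy = list(pooled)
        for v in gx:
            gy.remove(v)
        # number of (x, y) pairs with x > y
        return sum(1 for xi in gx for yj in gy if xi > yj)

    u_obs = u1_of(x)
    u_min_obs = min(u_obs, n1 * n2 - u_obs)
    total = 0
    hits = 0
    for comb in combinations(range(n1 + n2), n1):
        gx = [pooled[i] for i in comb]
        u = u1_of(gx)
        total += 1
        if u <= u_min_obs or u >= n1 * n2 - u_min_obs:
            hits += 1
    return float(u_min_obs), min(1.0, hits / total)


def spearman_oracle(x, y) -> float:
    """Rank (mid-ranks) then Pearson."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx = midranks(x)
    ry = midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom)


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random binary tree with positive branch lengths; returns
    (distance matrix, labels, set of non-trivial splits)."""
    labels = [f"T{i}" for i in range(n_taxa)]
    # random sequential joining
    nodes = {i: frozenset([labels[i]]) for i in range(n_taxa)}
    # adjacency with branch lengths over node ids
    next_id = n_taxa
    active = list(range(n_taxa))
    edges = []
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[i], active[j]
        parent = next_id
        next_id += 1
        edges.append((a, parent, float(rng.uniform(0.5, 5.0))))
        edges.append((b, parent, float(rng.uniform(0.5, 5.0))))
        nodes[parent] = nodes[a] | nodes[b]
        active = [k for k in active if k not in (a, b)] + [parent]
    center = next_id
    nodes[center] = frozenset()
    for a in active:
        edges.append((a, center, float(rng.uniform(0.5, 5.0))))
    # path distances between leaves
    adj: dict[int, list[tuple[int, float]]] = {}
    for u, v, w in edges:
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    D = np.zeros((n_taxa, n_taxa))
    for s in range(n_taxa):
        dist = {s: 0.0}
        stack = [s]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for t in range(n_taxa):
            D[s, t] = dist[t]
    all_taxa = frozenset(labels)
    ref = min(all_taxa)
    splits = set()
    for nid, below in nodes.items():
        if nid < n_taxa or not below:
            continue
        side = below if ref not in below else all_taxa - below
        if 2 <= len(side) <= n_taxa - 2:
            splits.add(side)
    return D, labels, splits
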