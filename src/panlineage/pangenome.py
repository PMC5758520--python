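"""Presence/absence matrix, core/dispensable partition and strain clustering.

The pan-genome of a cohort is summarised as a binary strains x gene-families
matrix (with a parallel copy-number matrix).  A family present in every
strain is *core*; in a strict subset, *dispensable*.  Strain relationships
are summarised by average-linkage hierarchical clustering of the presence
profiles under either a covariance-derived distance or 1 - Pearson r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats

from .io_formats import StrainRecord
from .orthology import GeneFamily

__all__ = [
    "PresenceMatrix",
    "StrainClustering",
    "build_presence_matrix",
    "select_single_copy_core",
    "strain_dendrogram",
    "orf_age_correlation",
]


@dataclass
class PresenceMatrix:
    """Strains x gene-families presence (0/1) and copy-number matrices."""

    presence: pd.DataFrame  # int8, strains x GF
    copy_number: pd.DataFrame  # int16, strains x GF
    labels: pd.Series  # per-GF: "core" | "dispensable"

    @property
    def strain_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def gf_ids(self) -> list[str]:
        return list(self.presence.columns)

    def core_gfs(self) -> list[str]:
        return list(self.labels.index[self.labels == "core"])

    def dispensable_gfs(self) -> list[str]:
        return list(self.labels.index[self.labels == "dispensable"])


def build_presence_matrix(
    families: Sequence[GeneFamily],
    strains: Sequence[StrainRecord] | Sequence[str],
) -> PresenceMatrix:
    """Build the presence and copy-number matrices from gene families.

    ``strains`` fixes the row order (records or bare ids).  A strain that
    carries no gene of any family is reported with a warning (its row is
    all zeros, which violates the column-sum invariant only if a family
    claims it).
    """
    strain_ids = [
        s.strain_id if isinstance(s, StrainRecord) else s for s in strains
    ]
    gf_ids = [f.gf_id for f in families]
    copy = np.zeros((len(strain_ids), len(gf_ids)), dtype=np.int16)
    sidx = {s: i for i, s in enumerate(strain_ids)}
    for j, fam in enumerate(families):
        for strain, genes in fam.members.items():
            if strain not in sidx:
                raise ValueError(
                    f"family {fam.gf_id} references unknown strain {strain!r}"
                )
            copy[sidx[strain], j] = len(genes)
    presence = (copy > 0).astype(np.int8)
    empty = [s for s, row in zip(strain_ids, presence) if row.sum() == 0]
    if empty:
        warnings.warn(f"strains with zero genes in any family: {empty}", stacklevel=2)
    colsum = presence.sum(axis=0)
    labels = pd.Series(
        np.where(colsum == len(strain_ids), "core", "dispensable"),
        index=gf_ids,
        name="label",
    )
    return PresenceMatrix(
        presence=pd.DataFrame(presence, index=strain_ids, columns=gf_ids),
        copy_number=pd.DataFrame(copy, index=strain_ids, columns=gf_ids),
        labels=labels,
    )


def select_single_copy_core(matrix: PresenceMatrix) -> list[str]:
    """Core families with exactly one copy in every strain.

    These are the loci usable for concatenated core phylogeny.  May be
    empty; that is not an error.
    """
    core = matrix.labels == "core"
    single = (matrix.copy_number == 1).all(axis=0)
    return [gf for gf in matrix.gf_ids if core[gf] and single[gf]]


@dataclass
class StrainClustering:
    """Average-linkage dendrogram over strains plus flat-cut access."""

    linkage: np.ndarray
    strain_ids: list[str]
    distance: str

    def flat_clusters(self, k: int) -> dict[str, int]:
        labels = sch.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.strain_ids, labels.tolist()))

    def to_newick(self) -> str:
        tree = sch.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.strain_ids[node.id]
            l = rec(node.get_left())
            r = rec(node.get_right())
            dl = node.dist - (0 if node.get_left().is_leaf() else node.get_left().dist)
            dr = node.dist - (
                0 if node.get_right().is_leaf() else node.get_right().dist
            )
            return f"({l}:{dl:.6g},{r}:{dr:.6g})"

        return rec(tree) + ";"


def _covariance_distance(X: np.ndarray) -> np.ndarray:
    C = np.cov(X)
    c_max = C.max()
    D = c_max - C
    dmax = D.max()
    if dmax > 0:
        D = D / dmax
    np.fill_diagonal(D, 0.0)
    return D


def _pearson_distance(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=1)
    n = X.shape[0]
    D = np.ones((n, n))
    ok = sd > 0
    if ok.any():
        R = np.corrcoef(X[ok])
        D[np.ix_(ok, ok)] = 1.0 - R
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, None)


def strain_dendrogram(
    matrix: PresenceMatrix, distance: str = "covariance"
) -> StrainClustering:
    """Hierarchically cluster strains on their gene-family presence profile.

    ``distance="covariance"`` uses ``(c_max - cov(row_i, row_j))`` rescaled
    to [0, 1]; ``"pearson"`` uses ``1 - r`` (a constant profile gets
    distance 1 to everything).  Agglomeration is average linkage.  The
    result is invariant to the column order of the matrix.
    """
    X = matrix.presence.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 strains")
    if distance == "covariance":
        D = _covariance_distance(X)
    elif distance == "pearson":
        D = _pearson_distance(X)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    condensed = D[np.triu_indices_from(D, k=1)]
    Z = sch.linkage(condensed, method="average")
    return StrainClustering(
        linkage=Z, strain_ids=matrix.strain_ids, distance=distance
    )


class SpearmanResult(NamedTuple):
    rho: float
    p_value: float
    n: int


def orf_age_correlation(
    strains: Sequence[StrainRecord],
    gene_counts: Sequence[int] | None = None,
) -> SpearmanResult:
    """Spearman correlation between per-strain gene count and host age.

    Tie-aware (mid-ranks); the p-value uses the t approximation, replaced
    by the exact permutation distribution when n <= 9.  Zero variance in
    either variable leaves rho undefined (NaN) with a warning.
    """
    ages = np.array([s.age_years for s in strains], dtype=float)
    if gene_counts is None:
        counts = np.array([s.n_genes for s in strains], dtype=float)
    else:
        counts = np.array(gene_counts, dtype=float)
    n = ages.shape[0]
    if n < 3:
        raise ValueError("need at least 3 strains")
    if np.ptp(ages) == 0 or np.ptp(counts) == 0:
        warnings.warn("zero variance: Spearman rho undefined", stacklevel=2)
        return SpearmanResult(np.nan, np.nan, n)
    rho, p = stats.spearmanr(counts, ages)
    if n <= 9:
        # exact permutation two-sided p
        ranks_a = stats.rankdata(ages)
        ranks_c = stats.rankdata(counts)
        obs = abs(_pearson(ranks_c, ranks_a))
        count = 0
        total = 0
        for perm in permutations(ranks_a):
            total += 1
            if abs(_pearson(ranks_c, np.array(perm))) >= obs - 1e-12:
                count += 1
        p = count / total
    return SpearmanResult(float(rho), float(p), n)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    return float((xc * yc).sum() / denom) if denom > 0 else 0.0
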