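"""Age-stratified gene-family enrichment.

For every dispensable gene family the host ages of carrier strains are
compared with those of non-carrier strains (Mann-Whitney U, two-sided); the
resulting p-values receive one global FDR correction (Storey q-values, or
plain Benjamini-Hochberg), and a family is called *younger*- or
*older*-enriched at ``q < alpha_q`` according to the carrier/non-carrier
median age difference.  In parallel, per-segment detection rates are
z-scored per family and hierarchically clustered to label families with the
infant / adult / elderly detection-profile group their rates follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats

from .io_formats import DEFAULT_SEGMENTATION, AgeSegmentation, StrainRecord
from .pangenome import PresenceMatrix

__all__ = [
    "EnrichmentResult",
    "filter_dispensable",
    "detection_rates",
    "mann_whitney_u",
    "qvalues",
    "classify_enrichment",
    "results_to_frame",
]

#: Default mapping of age segments to coarse blocks used for labeling
#: detection-rate clusters (bounds in years, half-open).
DEFAULT_AGE_BLOCKS: dict[str, tuple[float, float]] = {
    "infant": (0.0, 10.0),
    "adult": (10.0, 60.0),
    "elderly": (60.0, 105.0),
}


@dataclass
class EnrichmentResult:
    """Per-family enrichment statistics."""

    gf_id: str
    n_present: int
    detection_rate: dict[str, float] = field(default_factory=dict)
    zscores: dict[str, float] = field(default_factory=dict)
    U: float = np.nan
    p_value: float = 1.0
    q_value: float = 1.0
    direction: str = "none"  # younger | older | none
    age_cluster: str = "none"  # infant | adult | elderly | none


def filter_dispensable(
    matrix: PresenceMatrix,
    min_present: int = 6,
    max_present: int | None = None,
) -> list[str]:
    """Dispensable families present in ``min_present..max_present`` strains.

    The default window (6 to n_strains - 6) drops families too rare or too
    near-core to carry age signal.
    """
    n = len(matrix.strain_ids)
    if max_present is None:
        max_present = n - 6
    if min_present > max_present:
        raise ValueError(
            f"min_present ({min_present}) > max_present ({max_present})"
        )
    colsum = matrix.presence.sum(axis=0)
    disp = matrix.labels == "dispensable"
    return [
        gf
        for gf in matrix.gf_ids
        if disp[gf] and min_present <= int(colsum[gf]) <= max_present
    ]


def detection_rates(
    matrix: PresenceMatrix,
    strains: Sequence[StrainRecord],
    segmentation: AgeSegmentation = DEFAULT_SEGMENTATION,
    gf_subset: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-segment detection rate and per-family z-scores.

    rate(gf, segment) = carriers in segment / strains in segment.  Segments
    with no strains are dropped with a warning.  Each family row of the rate
    matrix is z-scored across segments; a constant row yields all zeros.
    """
    seg_of = {s.strain_id: s.age_segment for s in strains}
    gfs = list(gf_subset) if gf_subset is not None else matrix.gf_ids
    pres = matrix.presence[gfs]
    groups: dict[str, list[str]] = {}
    for sid in matrix.strain_ids:
        groups.setdefault(seg_of[sid], []).append(sid)
    labels = [l for l in segmentation.labels if l in groups]
    dropped = [l for l in segmentation.labels if l not in groups]
    if dropped:
        warnings.warn(f"empty age segments dropped: {dropped}", stacklevel=2)
    rates = pd.DataFrame(
        {l: pres.loc[groups[l]].mean(axis=0) for l in labels},
        index=gfs,
    )
    vals = rates.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (vals - mean) / np.where(sd == 0, 1.0, sd), 0.0)
    zscores = pd.DataFrame(z, index=gfs, columns=labels)
    return rates, zscores


class MannWhitneyResult(NamedTuple):
    U: float
    p_value: float


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test; U reported as min(U1, U2).

    The p-value is exact (full enumeration over labelings) when
    ``n1 + n2 <= 12`` and the pooled sample is tie-free, otherwise the
    normal approximation with tie-corrected variance and continuity
    correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    u1 = float(res.statistic)
    u_min = min(u1, x.size * y.size - u1)
    return MannWhitneyResult(u_min, float(res.pvalue))


def qvalues(p_list: Sequence[float], method: str = "storey") -> np.ndarray:
    """FDR q-values from a vector of p-values.

    ``storey`` estimates the null proportion pi0 on the lambda grid
    0.05..0.95 (step 0.05) with a cubic-polynomial smoother extrapolated at
    the top of the grid (clamped to (0, 1]); ``bh`` fixes pi0 = 1, which
    reduces the formula to Benjamini-Hochberg exactly.  q-values are
    monotone in p and capped at 1.
    """
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bh":
        pi0 = 1.0
    elif method == "storey":
        lams = np.arange(0.05, 0.951, 0.05)
        pi0s = np.array([(p > l).mean() / (1.0 - l) for l in lams])
        coef = np.polyfit(lams, pi0s, 3)
        pi0 = float(np.polyval(coef, lams.max()))
        pi0 = min(1.0, max(pi0, 1.0 / m))
    else:
        raise ValueError(f"unknown FDR method {method!r}")
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def _label_clusters(
    zscores: pd.DataFrame,
    cluster_of: dict[str, int],
    segmentation: AgeSegmentation,
    blocks: dict[str, tuple[float, float]],
    flat_threshold: float = 0.25,
) -> dict[int, str]:
    seg_block: dict[str, str] = {}
    for seg in segmentation.segments:
        mid = (seg.min_age + min(seg.max_age, 104.0)) / 2.0
        for name, (lo, hi) in blocks.items():
            if lo <= mid < hi:
                seg_block[seg.label] = name
                break
    labels: dict[int, str] = {}
    clusters = sorted(set(cluster_of.values()))
    for c in clusters:
        gfs = [g for g, ci in cluster_of.items() if ci == c]
        sub = zscores.loc[gfs]
        block_means = {}
        for name in blocks:
            cols = [l for l in sub.columns if seg_block.get(l) == name]
            if cols:
                block_means[name] = float(sub[cols].to_numpy().mean())
        if not block_means:
            labels[c] = "none"
            continue
        best = max(block_means, key=block_means.get)
        labels[c] = best if block_means[best] >= flat_threshold else "none"
    return labels


def classify_enrichment(
    matrix: PresenceMatrix,
    strains: Sequence[StrainRecord],
    segmentation: AgeSegmentation = DEFAULT_SEGMENTATION,
    alpha_q: float = 0.2,
    fdr_method: str = "storey",
    min_present: int = 6,
    max_present: int | None = None,
    k_clusters: int = 4,
    blocks: dict[str, tuple[float, float]] = DEFAULT_AGE_BLOCKS,
) -> list[EnrichmentResult]:
    """Classify dispensable families by host-age enrichment.

    For each family passing :func:`filter_dispensable` the carrier and
    non-carrier host ages enter a Mann-Whitney U test; one global FDR
    correction is applied over all tested families.  ``direction`` is
    ``younger`` when q < ``alpha_q`` and the carrier median age is below
    the non-carrier median (``older`` when reversed).  Families are also
    assigned an infant/adult/elderly detection-profile cluster from the
    z-scored per-segment detection rates (Pearson distance, average
    linkage, cut at ``k_clusters``).
    """
    ages = {s.strain_id: s.age_years for s in strains}
    age_vec = np.array([ages[s] for s in matrix.strain_ids])
    tested = filter_dispensable(matrix, min_present, max_present)
    results = [EnrichmentResult(gf_id=gf, n_present=0) for gf in tested]
    pvals = np.ones(len(tested))
    for i, gf in enumerate(tested):
        col = matrix.presence[gf].to_numpy().astype(bool)
        res = results[i]
        res.n_present = int(col.sum())
        carriers = age_vec[col]
        others = age_vec[~col]
        if carriers.size == 0 or others.size == 0:
            warnings.warn(f"{gf}: empty group, statistic undefined", stacklevel=2)
            continue
        mw = mann_whitney_u(carriers, others)
        res.U = mw.U
        res.p_value = mw.p_value
        pvals[i] = mw.p_value
    qvals = qvalues(pvals, method=fdr_method) if tested else np.array([])
    for res, q in zip(results, qvals):
        res.q_value = float(q)
        col = matrix.presence[res.gf_id].to_numpy().astype(bool)
        carriers = age_vec[col]
        others = age_vec[~col]
        if carriers.size and others.size and q < alpha_q:
            med_c = float(np.median(carriers))
            med_o = float(np.median(others))
            if med_c < med_o:
                res.direction = "younger"
            elif med_c > med_o:
                res.direction = "older"

    # detection-rate clusters
    if tested:
        rates, zscores = detection_rates(matrix, strains, segmentation, tested)
        for res in results:
            res.detection_rate = rates.loc[res.gf_id].to_dict()
            res.zscores = zscores.loc[res.gf_id].to_dict()
        if zscores.shape[1] >= 2 and len(tested) >= 2:
            D = _pearson_rows_distance(zscores.to_numpy(dtype=float))
            condensed = D[np.triu_indices_from(D, k=1)]
            Z = sch.linkage(condensed, method="average")
            flat = sch.fcluster(Z, t=min(k_clusters, len(tested)), criterion="maxclust")
            cluster_of = dict(zip(tested, flat.tolist()))
            labels = _label_clusters(zscores, cluster_of, segmentation, blocks)
            for res in results:
                res.age_cluster = labels[cluster_of[res.gf_id]]
    return results


def _pearson_rows_distance(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=1)
    n = X.shape[0]
    D = np.ones((n, n))
    ok = sd > 0
    if ok.any():
        R = np.corrcoef(X[ok])
        D[np.ix_(ok, ok)] = 1.0 - np.atleast_2d(R)
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, None)


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "gf_id": r.gf_id,
                "n_present": r.n_present,
                "U": r.U,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "direction": r.direction,
                "age_cluster": r.age_cluster,
            }
        )
    return pd.DataFrame(rows)
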