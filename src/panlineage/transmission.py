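"""Within-family strain transmission calling.

Two strains isolated from related subjects are called *transmitted* when
they look like recent copies of one clone: genome-wide average nucleotide
identity (ANI) at or above the clonal threshold (99.5% by default, with a
99.9% strict profile), corroborated either by a matching CRISPR spacer
array (full or partial spacer sharing) or — when neither strain carries an
array — by near-identical gene content (presence-profile Jaccard >= 0.95).

ANI follows the fragment convention: the query genome is cut into
consecutive 1,020-bp fragments, each fragment is aligned to the best
matching region of the subject genome (both strands), fragments below 70%
identity over 70% of their length are discarded, and the ANI is the mean
identity of the kept fragments, symmetrised over both directions.
Fragment placement uses exact 16-mer seeding followed by a windowed
edlib infix alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import edlib
import networkx as nx
import numpy as np

from .crispr_typing import CrisprArray, compare_spacer_arrays, reverse_complement
from .io_formats import StrainRecord
from .pangenome import PresenceMatrix

__all__ = [
    "AniParams",
    "AniResult",
    "TransmissionCall",
    "compute_ani",
    "gene_content_similarity",
    "call_transmissions",
    "transmitted_components",
]


@dataclass(frozen=True)
class AniParams:
    fragment_length: int = 1020
    min_fragment_identity: float = 0.70
    min_fragment_coverage: float = 0.70
    seed_k: int = 16
    seed_step: int = 16
    window_margin: int = 80
    min_genome_length: int = 10_000


class AniResult(NamedTuple):
    ani: float  # percent; NaN when not computable
    n_fragments: int


@dataclass
class TransmissionCall:
    """Evidence and verdict for one within-family strain pair."""

    strain_a: str
    strain_b: str
    family_id: str
    ani: float
    gene_jaccard: float
    spacer_class: str  # full | partial | none | absent
    verdict: str  # transmitted | not_transmitted


_LUT = np.full(256, 255, np.uint8)
for _i, _c in enumerate("ACGT"):
    _LUT[ord(_c)] = _i


def _encode(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _genome_string(record_or_contigs) -> str:
    if isinstance(record_or_contigs, StrainRecord):
        contigs = record_or_contigs.contigs
    else:
        contigs = record_or_contigs
    return "".join(seq for _, seq in contigs)


class _SeedIndex:
    """Exact k-mer position index over one genome string."""

    def __init__(self, genome: str, k: int):
        self.k = k
        self.length = len(genome)
        codes = _encode(genome.upper()).astype(np.int64)
        if self.length < k:
            self.hashes = {}
            return
        powers = (4 ** np.arange(k)).astype(np.int64)
        win = np.lib.stride_tricks.sliding_window_view(codes, k)
        h = win @ powers
        order = np.argsort(h, kind="stable")
        sh = h[order]
        bounds = np.flatnonzero(np.diff(sh)) + 1
        starts = np.concatenate([[0], bounds])
        self.hashes = {
            int(sh[s]): g for s, g in zip(starts, np.split(order, bounds))
        }

    def lookup(self, h: int) -> np.ndarray:
        return self.hashes.get(h, np.empty(0, np.int64))


def _fragment_identity(
    frag: str, genome: str, index: _SeedIndex, params: AniParams
) -> float:
    """Best identity of one fragment against the indexed genome (one strand)."""
    k = params.seed_k
    L = len(frag)
    if L < k:
        return 0.0
    codes = _encode(frag).astype(np.int64)
    powers = (4 ** np.arange(k)).astype(np.int64)
    offsets: list[int] = []
    for q in range(0, L - k + 1, params.seed_step):
        h = int(codes[q : q + k] @ powers)
        for t in index.lookup(h):
            offsets.append(int(t) - q)
    if not offsets:
        return 0.0
    offsets_arr = np.sort(np.array(offsets))
    # densest cluster of offsets within the window margin
    best_off = int(offsets_arr[0])
    best_n = 0
    i = 0
    for j in range(offsets_arr.shape[0]):
        while offsets_arr[j] - offsets_arr[i] > params.window_margin:
            i += 1
        if j - i + 1 > best_n:
            best_n = j - i + 1
            best_off = int(np.median(offsets_arr[i : j + 1]))
    w = params.window_margin
    lo = max(0, best_off - w)
    hi = min(index.length, best_off + L + w)
    window = genome[lo:hi]
    if len(window) < params.min_fragment_coverage * L:
        return 0.0
    res = edlib.align(frag, window, mode="HW", task="distance")
    dist = res["editDistance"]
    if dist < 0:
        return 0.0
    return 1.0 - dist / L


def compute_ani(
    genome_a,
    genome_b,
    params: AniParams = AniParams(),
) -> AniResult:
    """Symmetric fragment-based average nucleotide identity (percent).

    Inputs are :class:`StrainRecord` objects or ``[(contig_id, seq), ...]``
    lists.  Returns NaN with 0 fragments when no fragment passes the
    identity filter in either direction (e.g. unrelated genomes).
    """
    sa = _genome_string(genome_a).upper()
    sb = _genome_string(genome_b).upper()
    if len(sa) < params.min_genome_length or len(sb) < params.min_genome_length:
        raise ValueError("genomes must be at least 10 kb for fragment ANI")
    identities: list[float] = []
    n_used = 0
    for query, subject in ((sa, sb), (sb, sa)):
        index = _SeedIndex(subject, params.seed_k)
        dir_ids: list[float] = []
        F = params.fragment_length
        for start in range(0, len(query) - F + 1, F):
            frag = query[start : start + F]
            ident = _fragment_identity(frag, subject, index, params)
            if ident < params.min_fragment_identity:
                rc = reverse_complement(frag)
                ident = max(ident, _fragment_identity(rc, subject, index, params))
            if ident >= params.min_fragment_identity:
                dir_ids.append(ident)
        identities.append(float(np.mean(dir_ids)) if dir_ids else np.nan)
        n_used += len(dir_ids)
    if all(np.isnan(v) for v in identities):
        return AniResult(float("nan"), 0)
    return AniResult(100.0 * float(np.nanmean(identities)), n_used)


def gene_content_similarity(row_a: np.ndarray, row_b: np.ndarray) -> float:
    """Jaccard similarity of two presence rows (undefined -> NaN)."""
    a = np.asarray(row_a).astype(bool)
    b = np.asarray(row_b).astype(bool)
    union = int((a | b).sum())
    if union == 0:
        warnings.warn("both presence rows empty; Jaccard undefined", stacklevel=2)
        return float("nan")
    return float((a & b).sum() / union)


def _pair_spacer_class(
    arrays_a: Sequence[CrisprArray], arrays_b: Sequence[CrisprArray]
) -> str:
    if not arrays_a or not arrays_b:
        return "absent"
    best = "none"
    rank = {"none": 0, "partial": 1, "full": 2}
    for aa in arrays_a:
        for ab in arrays_b:
            m = compare_spacer_arrays(aa, ab)
            if rank[m.match_class] > rank[best]:
                best = m.match_class
    return best


def call_transmissions(
    records: Sequence[StrainRecord],
    matrix: PresenceMatrix | None,
    arrays_by_strain: dict[str, list[CrisprArray]] | None,
    ani_threshold: float = 99.5,
    jaccard_threshold: float = 0.95,
    ani_params: AniParams = AniParams(),
    all_pairs: bool = False,
) -> list[TransmissionCall]:
    """Evaluate within-family strain pairs and call transmissions.

    Verdict ``transmitted`` requires ANI >= ``ani_threshold`` AND spacer
    evidence (full/partial array match), or — when neither strain has an
    array — gene-content Jaccard >= ``jaccard_threshold``.  With
    ``all_pairs=True`` every strain pair is scanned instead of only
    within-family ones.
    """
    by_id = {r.strain_id: r for r in records}
    if arrays_by_strain is None:
        arrays_by_strain = {}
    pairs: list[tuple[str, str, str]] = []
    if all_pairs:
        ids = sorted(by_id)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                fam = by_id[a].family_id if by_id[a].family_id == by_id[b].family_id else ""
                pairs.append((a, b, fam))
    else:
        families: dict[str, list[str]] = {}
        for r in records:
            if r.family_id:
                families.setdefault(r.family_id, []).append(r.strain_id)
        for fam, members in sorted(families.items()):
            members = sorted(members)
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    pairs.append((a, b, fam))
        if not pairs:
            raise ValueError("no family with at least 2 strains")
    calls: list[TransmissionCall] = []
    for a, b, fam in pairs:
        ra, rb = by_id.get(a), by_id.get(b)
        if ra is None or rb is None or not ra.contigs or not rb.contigs:
            warnings.warn(f"missing genome for pair ({a}, {b}); skipped", stacklevel=2)
            continue
        ani, _ = compute_ani(ra, rb, ani_params)
        if matrix is not None and a in matrix.presence.index and b in matrix.presence.index:
            jac = gene_content_similarity(
                matrix.presence.loc[a].to_numpy(), matrix.presence.loc[b].to_numpy()
            )
        else:
            jac = float("nan")
        spacer_class = _pair_spacer_class(
            arrays_by_strain.get(a, []), arrays_by_strain.get(b, [])
        )
        transmitted = (
            not np.isnan(ani)
            and ani >= ani_threshold
            and (
                spacer_class in ("full", "partial")
                or (
                    spacer_class == "absent"
                    and not np.isnan(jac)
                    and jac >= jaccard_threshold
                )
            )
        )
        calls.append(
            TransmissionCall(
                strain_a=a,
                strain_b=b,
                family_id=fam,
                ani=float(ani),
                gene_jaccard=float(jac),
                spacer_class=spacer_class,
                verdict="transmitted" if transmitted else "not_transmitted",
            )
        )
    return calls


def transmitted_components(calls: Sequence[TransmissionCall]) -> list[set[str]]:
    """Connected components over transmitted pairs (multi-generation sets)."""
    g = nx.Graph()
    for c in calls:
        if c.verdict == "transmitted":
            g.add_edge(c.strain_a, c.strain_b)
    return [set(c) for c in nx.connected_components(g)]
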