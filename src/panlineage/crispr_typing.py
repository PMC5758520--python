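"""CRISPR repeat-spacer array detection, comparison and strain-specific PCR.

A CRISPR array is a run of near-identical direct repeats (23-55 bp)
separated by unique spacers; its ordered spacer content acts as a strain
fingerprint.  The detector seeds on exactly repeated 11-mers, extends the
repeat unit by column consensus across copies, and validates repeat length,
copy number, repeat identity and spacer geometry.  Arrays are compared by
the longest common subsequence of their spacer lists (orientation
harmonised by also trying the reverse complement).  For strain-specific PCR
the designer enumerates primer pairs anchored in spacers absent from every
other genome and screens them with an in-silico PCR emulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np

from .io_formats import StrainRecord

__all__ = [
    "CrisprArray",
    "SpacerMatch",
    "PrimerCandidate",
    "PrimerConstraints",
    "DetectorParams",
    "Amplicon",
    "detect_arrays",
    "detect_arrays_in_record",
    "compare_spacer_arrays",
    "design_strain_primers",
    "in_silico_pcr",
    "wallace_tm",
    "reverse_complement",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def wallace_tm(primer: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C) degrees C."""
    at = primer.count("A") + primer.count("T")
    gc = primer.count("G") + primer.count("C")
    return 2.0 * at + 4.0 * gc


@dataclass
class CrisprArray:
    """One detected (or planted) repeat-spacer locus, contig forward strand."""

    strain_id: str
    contig_id: str
    start: int  # 0-based half-open contig coordinates
    end: int
    repeat_consensus: str
    spacers: list[str] = field(default_factory=list)

    @property
    def n_spacers(self) -> int:
        return len(self.spacers)


@dataclass(frozen=True)
class SpacerMatch:
    """Pairwise spacer-array comparison."""

    n_shared: int
    order_consistent: bool
    match_class: str  # full | partial | none


@dataclass(frozen=True)
class DetectorParams:
    seed_k: int = 11
    seed_window: int = 1000
    repeat_length_range: tuple[int, int] = (23, 55)
    min_copies: int = 3
    min_repeat_identity: float = 0.9
    spacer_factor_range: tuple[float, float] = (0.6, 2.5)
    max_mean_spacer_identity: float = 0.6
    consensus_threshold: float = 0.9


@dataclass(frozen=True)
class PrimerConstraints:
    primer_length_range: tuple[int, int] = (18, 25)
    gc_range: tuple[float, float] = (40.0, 60.0)
    tm_range: tuple[float, float] = (55.0, 65.0)
    max_tm_gap: float = 3.0
    amplicon_range: tuple[int, int] = (80, 300)
    max_mismatches: int = 1


@dataclass
class PrimerCandidate:
    """An accepted strain-specific primer pair with its specificity map."""

    strain_id: str
    forward: str
    reverse: str
    contig_id: str
    amplicon_start: int  # 1-based inclusive
    amplicon_end: int
    amplicon_length: int
    specificity: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class Amplicon:
    contig_id: str
    start: int  # 1-based inclusive
    end: int
    length: int


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

_LUT = np.full(256, 255, np.uint8)
for _i, _c in enumerate("ACGT"):
    _LUT[ord(_c)] = _i


def _encode(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    if codes.shape[0] < k:
        return np.empty(0, np.int64)
    powers = (4 ** np.arange(k)).astype(np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes.astype(np.int64), k)
    return win @ powers


def _identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def detect_arrays(
    contig_id: str,
    seq: str,
    params: DetectorParams = DetectorParams(),
    strain_id: str = "",
) -> list[CrisprArray]:
    """Detect repeat-spacer arrays on one contig (forward orientation).

    Seeds are exactly repeated 11-mers whose consecutive occurrences lie
    within 1 kb of each other; each seed run is extended to the maximal
    repeat unit by requiring >= 90% column consensus across copies.  A
    candidate is accepted iff the repeat length is 23-55 bp with >= 3
    copies at >= 90% mean pairwise identity, spacer lengths are 0.6-2.5x
    the repeat length, and the spacers are mutually dissimilar (mean
    pairwise identity < 60%; a degenerate tandem repeat fails this).
    Overlapping candidates are resolved by most repeat copies, then
    leftmost start.
    """
    codes = _encode(seq.upper())
    n = codes.shape[0]
    k = params.seed_k
    if n < k * params.min_copies:
        return []
    hashes = _kmer_hashes(codes, k)
    order = np.argsort(hashes, kind="stable")
    sh = hashes[order]
    boundaries = np.flatnonzero(np.diff(sh)) + 1
    groups = np.split(order, boundaries)
    candidates: list[CrisprArray] = []
    seen_spans: list[tuple[int, int]] = []
    rmin, rmax = params.repeat_length_range
    for grp in groups:
        if grp.shape[0] < params.min_copies:
            continue
        pos = np.sort(grp)
        # maximal runs of occurrences with gaps in [rmin, seed_window]
        gaps = np.diff(pos)
        run_start = 0
        runs: list[np.ndarray] = []
        for gi, g in enumerate(gaps):
            if not (rmin <= g <= params.seed_window):
                if gi + 1 - run_start >= params.min_copies:
                    runs.append(pos[run_start : gi + 1])
                run_start = gi + 1
        if pos.shape[0] - run_start >= params.min_copies:
            runs.append(pos[run_start:])
        for run in runs:
            arr = _extend_candidate(seq, codes, run, k, params)
            if arr is None:
                continue
            span = (arr.start, arr.end)
            if span in seen_spans:  # same array re-seeded by another k-mer
                continue
            arr = CrisprArray(
                strain_id=strain_id,
                contig_id=contig_id,
                start=arr.start,
                end=arr.end,
                repeat_consensus=arr.repeat_consensus,
                spacers=arr.spacers,
            )
            candidates.append(arr)
            seen_spans.append(span)
    # resolve overlaps: most repeat copies then leftmost
    candidates.sort(key=lambda a: (-(a.n_spacers + 1), a.start))
    accepted: list[CrisprArray] = []
    for cand in candidates:
        if all(
            cand.end <= other.start or cand.start >= other.end
            for other in accepted
        ):
            accepted.append(cand)
    accepted.sort(key=lambda a: a.start)
    return accepted


def _consensus_frac(col: np.ndarray) -> float:
    counts = np.bincount(col, minlength=4)
    return counts.max() / col.shape[0]


def _extend_candidate(
    seq: str,
    codes: np.ndarray,
    run: np.ndarray,
    k: int,
    params: DetectorParams,
) -> CrisprArray | None:
    """Extend a seed run to the maximal repeat unit and validate the array."""
    n = codes.shape[0]
    c = run.shape[0]
    rmin, rmax = params.repeat_length_range
    thr = params.consensus_threshold
    # the repeat unit cannot be longer than the smallest period, else units
    # would overlap
    max_unit = min(rmax, int(np.diff(run).min()))
    left = 0
    while (
        run[0] - (left + 1) >= 0
        and k + left + 1 <= max_unit
        and _consensus_frac(codes[run - (left + 1)]) >= thr
    ):
        left += 1
    right = 0
    while (
        run[-1] + k + right < n
        and k + left + right + 1 <= max_unit
        and _consensus_frac(codes[run + k + right]) >= thr
    ):
        right += 1
    unit_len = k + left + right
    if not (rmin <= unit_len <= max_unit):
        return None
    starts = run - left
    # mean pairwise identity of repeat copies, column-wise
    cols = codes[starts[:, None] + np.arange(unit_len)[None, :]]  # c x unit
    pair_total = c * (c - 1) // 2
    col_matches = np.zeros(unit_len)
    for j in range(unit_len):
        counts = np.bincount(cols[:, j], minlength=4)
        col_matches[j] = (counts * (counts - 1) // 2).sum()
    mean_repeat_identity = float(col_matches.mean() / pair_total)
    if mean_repeat_identity < params.min_repeat_identity:
        return None
    flo, fhi = params.spacer_factor_range
    spacers = [
        seq[starts[i] + unit_len : starts[i + 1]] for i in range(c - 1)
    ]
    if not all(flo * unit_len <= len(sp) <= fhi * unit_len for sp in spacers):
        return None
    if len(spacers) >= 2:
        idents = [
            _identity(spacers[i], spacers[j])
            for i in range(len(spacers))
            for j in range(i + 1, len(spacers))
        ]
        if float(np.mean(idents)) >= params.max_mean_spacer_identity:
            return None
    consensus = "".join(
        "ACGT"[int(np.bincount(cols[:, j], minlength=4).argmax())]
        for j in range(unit_len)
    )
    return CrisprArray(
        strain_id="",
        contig_id="",
        start=int(starts[0]),
        end=int(starts[-1] + unit_len),
        repeat_consensus=consensus,
        spacers=spacers,
    )


def detect_arrays_in_record(
    record: StrainRecord, params: DetectorParams = DetectorParams()
) -> list[CrisprArray]:
    """Detect arrays on every contig of a strain."""
    out: list[CrisprArray] = []
    for cid, seq in record.contigs:
        out.extend(detect_arrays(cid, seq, params, strain_id=record.strain_id))
    return out


# ---------------------------------------------------------------------------
# Comparison
# ---------------------------------------------------------------------------

def _lcs(a: Sequence[str], b: Sequence[str]) -> int:
    la, lb = len(a), len(b)
    dp = np.zeros((la + 1, lb + 1), dtype=np.int32)
    for i in range(1, la + 1):
        ai = a[i - 1]
        for j in range(1, lb + 1):
            if ai == b[j - 1]:
                dp[i, j] = dp[i - 1, j - 1] + 1
            else:
                dp[i, j] = max(dp[i - 1, j], dp[i, j - 1])
    return int(dp[la, lb])


def compare_spacer_arrays(a: CrisprArray, b: CrisprArray) -> SpacerMatch:
    """Compare two spacer arrays (exact spacer equality, LCS over order).

    Orientation is harmonised by also scoring *b* reverse-complemented and
    keeping the better match.  ``full`` means identical ordered lists;
    ``none`` means no shared spacer; otherwise ``partial``.
    ``order_consistent`` is true when the LCS accounts for every shared
    spacer (the shared set appears in the same relative order).
    """
    if not a.spacers or not b.spacers:
        warnings.warn("empty spacer array in comparison", stacklevel=2)
        return SpacerMatch(0, True, "none")

    def score(b_spacers: list[str]) -> tuple[int, int]:
        shared = _lcs(a.spacers, b_spacers)
        inter = len(
            _multiset_intersection(a.spacers, b_spacers)
        )
        return shared, inter

    fwd = score(b.spacers)
    rev_spacers = [reverse_complement(s) for s in reversed(b.spacers)]
    rev = score(rev_spacers)
    (n_shared, inter), b_used = (
        (fwd, b.spacers) if fwd[0] >= rev[0] else (rev, rev_spacers)
    )
    if n_shared == 0:
        return SpacerMatch(0, True, "none")
    match_class = "full" if list(a.spacers) == list(b_used) else "partial"
    return SpacerMatch(n_shared, n_shared == inter, match_class)


def _multiset_intersection(a: Sequence[str], b: Sequence[str]) -> list[str]:
    from collections import Counter

    ca, cb = Counter(a), Counter(b)
    out: list[str] = []
    for key, na in ca.items():
        out.extend([key] * min(na, cb.get(key, 0)))
    return out


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------

def _binding_sites(
    primer: str, codes: np.ndarray, max_mismatches: int, three_prime_first: bool
) -> np.ndarray:
    """Start positions where *primer* binds the + strand of *codes*.

    Mismatches are limited to ``max_mismatches`` and disallowed in the
    primer's 3'-terminal 3 nt (the last 3 primer bases; for a reverse
    primer matched via its reverse complement this is the *first* 3 window
    positions, selected by ``three_prime_first``).
    """
    p = _encode(primer)
    L = p.shape[0]
    if codes.shape[0] < L:
        return np.empty(0, np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    mism = (win != p[None, :]).sum(axis=1)
    ok = mism <= max_mismatches
    if three_prime_first:
        exact3 = (win[:, :3] == p[None, :3]).all(axis=1)
    else:
        exact3 = (win[:, -3:] == p[None, -3:]).all(axis=1)
    return np.flatnonzero(ok & exact3)


def in_silico_pcr(
    forward: str,
    reverse: str,
    contigs: Sequence[tuple[str, str]],
    max_mismatches: int = 1,
    max_product: int = 2000,
) -> list[Amplicon]:
    """Emulate PCR: find convergent primer binding sites and report products.

    The forward primer is matched on the + strand, the reverse primer on
    the - strand (via its reverse complement on the + strand); convergent
    pairs within ``max_product`` yield amplicons with 1-based inclusive
    coordinates.  Products shorter than the two primers combined (e.g. the
    degenerate forward == revcomp(reverse) same-site case) are rejected.
    """
    if not (15 <= len(forward) <= 30 and 15 <= len(reverse) <= 30):
        raise ValueError("primers must be 15-30 nt")
    rc = reverse_complement(reverse)
    out: list[Amplicon] = []
    min_product = len(forward) + len(reverse)
    for cid, seq in contigs:
        codes = _encode(seq.upper())
        fsites = _binding_sites(forward, codes, max_mismatches, False)
        rsites = _binding_sites(rc, codes, max_mismatches, True)
        for f in fsites:
            for r in rsites:
                end = int(r) + len(rc)  # half-open end of product
                length = end - int(f)
                if min_product <= length <= max_product:
                    out.append(Amplicon(cid, int(f) + 1, end, length))
    return out


# ---------------------------------------------------------------------------
# Primer design
# ---------------------------------------------------------------------------

def _gc_percent(primer: str) -> float:
    return 100.0 * (primer.count("G") + primer.count("C")) / len(primer)


def _thermo_ok(primer: str, constraints: PrimerConstraints) -> bool:
    glo, ghi = constraints.gc_range
    tlo, thi = constraints.tm_range
    return glo <= _gc_percent(primer) <= ghi and tlo <= wallace_tm(primer) <= thi


def _spacer_offsets(array: CrisprArray) -> list[int]:
    """Contig start position of each spacer of an array."""
    offs = []
    pos = array.start + len(array.repeat_consensus)
    for sp in array.spacers:
        offs.append(pos)
        pos += len(sp) + len(array.repeat_consensus)
    return offs


def design_strain_primers(
    target_array: CrisprArray,
    target_record: StrainRecord,
    all_records: Sequence[StrainRecord],
    constraints: PrimerConstraints = PrimerConstraints(),
) -> PrimerCandidate | None:
    """Design a strain-specific primer pair anchored in a unique spacer.

    A spacer is *unique* when neither it nor its reverse complement occurs
    in any other strain's genome.  Forward 18-25-mers are enumerated inside
    unique spacers (5'->3'), reverse primers from the downstream
    spacer/repeat region within the amplicon window; candidates must pass
    GC 40-60%, Wallace Tm 55-65 with pairwise gap <= 3, and the first pair
    whose in-silico PCR yields exactly one product in the target strain and
    none elsewhere is accepted.  Returns ``None`` when no strain-specific
    locus exists (expected for transmitted clone pairs).
    """
    others = [r for r in all_records if r.strain_id != target_record.strain_id]
    other_genomes = [
        (r.strain_id, "\n".join(seq for _, seq in r.contigs)) for r in others
    ]
    contig_seq = dict(target_record.contigs)[target_array.contig_id]
    offsets = _spacer_offsets(target_array)

    def is_unique(spacer: str) -> bool:
        rc = reverse_complement(spacer)
        return not any(
            spacer in genome or rc in genome for _, genome in other_genomes
        )

    unique_idx = [i for i, sp in enumerate(target_array.spacers) if is_unique(sp)]
    if not unique_idx:
        return None
    plo, phi = constraints.primer_length_range
    alo, ahi = constraints.amplicon_range
    for i in unique_idx:
        spacer = target_array.spacers[i]
        spos = offsets[i]
        for fs in range(0, len(spacer) - plo + 1):
            for fl in range(plo, min(phi, len(spacer) - fs) + 1):
                fwd = spacer[fs : fs + fl]
                if not _thermo_ok(fwd, constraints):
                    continue
                f_start = spos + fs
                region_end = min(len(contig_seq), f_start + ahi)
                for rl in range(plo, phi + 1):
                    # reverse primer 3' end at product end; scan products
                    # from the shortest admissible upward
                    for prod in range(max(alo, fl + rl), ahi + 1):
                        r_end = f_start + prod
                        if r_end > region_end:
                            break
                        site = contig_seq[r_end - rl : r_end]
                        rev = reverse_complement(site)
                        if not _thermo_ok(rev, constraints):
                            continue
                        if abs(wallace_tm(fwd) - wallace_tm(rev)) > constraints.max_tm_gap:
                            continue
                        target_amps = in_silico_pcr(
                            fwd,
                            rev,
                            target_record.contigs,
                            constraints.max_mismatches,
                        )
                        if len(target_amps) != 1:
                            continue
                        off_target = 0
                        specificity = {}
                        for other in others:
                            amps = in_silico_pcr(
                                fwd, rev, other.contigs, constraints.max_mismatches
                            )
                            specificity[other.strain_id] = len(amps)
                            off_target += len(amps)
                            if off_target:
                                break
                        if off_target:
                            continue
                        amp = target_amps[0]
                        specificity[target_record.strain_id] = 1
                        return PrimerCandidate(
                            strain_id=target_record.strain_id,
                            forward=fwd,
                            reverse=rev,
                            contig_id=amp.contig_id,
                            amplicon_start=amp.start,
                            amplicon_end=amp.end,
                            amplicon_length=amp.length,
                            specificity=specificity,
                        )
    return None
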