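"""Numba dynamic-programming kernels shared by orthology and phylogeny.

All sequences are encoded as uint8 arrays (``ord(char) - 65``), substitution
matrices as 26x26 int32 arrays indexed the same way.  Gap convention for the
local protein aligner: a gap of length g costs ``open + ext * g`` — i.e. the
classical "open 11 / extend 1" pair is passed as ``gap_open=12, gap_ext=1``
(first gapped column pays open+ext).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10 ** 9)


@njit(cache=True)
def sw_align(a, b, sub, gap_open, gap_ext, band):
    """Smith-Waterman local alignment with affine gaps.

    Parameters
    ----------
    a, b : uint8 arrays
    sub : (26, 26) int32 substitution matrix
    gap_open : total cost of the first gapped column (open + ext)
    gap_ext : cost per additional gapped column
    band : half-width of the evaluated diagonal band; ``band < 0`` evaluates
        the full DP matrix.  The band is centred on the diagonal range implied
        by the length difference, so equal-length high-identity pairs are
        scored exactly for any band covering their indel drift.

    Returns
    -------
    (score, matches, columns, a_start, a_end, b_start, b_end)
        0-based half-open coordinates of the optimal local alignment;
        ``columns`` counts alignment columns including gap columns.
    """
    m = a.shape[0]
    n = b.shape[0]
    if band < 0:
        dmin = -m
        dmax = n
    else:
        dmin = min(0, n - m) - band
        dmax = max(0, n - m) + band
    Hprev = np.zeros(n + 1, np.int32)
    Hcur = np.zeros(n + 1, np.int32)
    F = np.full(n + 1, NEG, np.int32)
    TB = np.zeros((m + 1, n + 1), np.uint8)  # 0 stop, 1 diag, 2 up, 3 left
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        srow = sub[a[i - 1]]
        jlo = i + dmin
        if jlo < 1:
            jlo = 1
        jhi = i + dmax
        if jhi > n:
            jhi = n
        e = NEG
        hleft = 0
        hdiag = Hprev[jlo - 1]
        Hcur[jlo - 1] = 0
        for j in range(jlo, jhi + 1):
            e = max(hleft - gap_open, e - gap_ext)
            fj = max(Hprev[j] - gap_open, F[j] - gap_ext)
            F[j] = fj
            h = hdiag + srow[b[j - 1]]
            t = 1
            if fj > h:
                h = fj
                t = 2
            if e > h:
                h = e
                t = 3
            if h <= 0:
                h = 0
                t = 0
            hdiag = Hprev[j]
            Hcur[j] = h
            hleft = h
            TB[i, j] = t
            if h > best:
                best = h
                bi = i
                bj = j
        tmp = Hprev
        Hprev = Hcur
        Hcur = tmp
    # traceback from the best cell
    i = bi
    j = bj
    matches = 0
    cols = 0
    while i > 0 and j > 0:
        t = TB[i, j]
        if t == 0:
            break
        cols += 1
        if t == 1:
            if a[i - 1] == b[j - 1]:
                matches += 1
            i -= 1
            j -= 1
        elif t == 2:
            i -= 1
        else:
            j -= 1
    return best, matches, cols, i, bi, j, bj


@njit(cache=True)
def profile_align(fa, fb, match, mismatch, gap):
    """Global (Needleman-Wunsch) profile-profile alignment, linear gaps.

    ``fa``/``fb`` are (L, 5) float32 column-frequency profiles over
    (A, C, G, T, gap).  Column score is the expected pairwise score between
    symbols drawn from the two columns: ``match`` for identical bases,
    ``mismatch`` for different bases, ``gap`` for base-vs-gap, 0 for
    gap-vs-gap.  A newly introduced gap column is charged ``gap`` times the
    non-gap fraction of the column it is placed against.

    Returns ``(score, ia, ib)`` where ``ia``/``ib`` map merged alignment
    columns to source columns (-1 for a new gap).
    """
    la = fa.shape[0]
    lb = fb.shape[0]
    sum_a = np.empty(la, np.float32)
    sum_b = np.empty(lb, np.float32)
    for i in range(la):
        sum_a[i] = fa[i, 0] + fa[i, 1] + fa[i, 2] + fa[i, 3]
    for j in range(lb):
        sum_b[j] = fb[j, 0] + fb[j, 1] + fb[j, 2] + fb[j, 3]
    H = np.zeros((la + 1, lb + 1), np.float32)
    TB = np.zeros((la + 1, lb + 1), np.uint8)  # 1 diag, 2 up (gap in b), 3 left
    for i in range(1, la + 1):
        H[i, 0] = H[i - 1, 0] + gap * sum_a[i - 1]
        TB[i, 0] = 2
    for j in range(1, lb + 1):
        H[0, j] = H[0, j - 1] + gap * sum_b[j - 1]
        TB[0, j] = 3
    for i in range(1, la + 1):
        fai = fa[i - 1]
        sa = sum_a[i - 1]
        ga = fai[4]
        for j in range(1, lb + 1):
            fbj = fb[j - 1]
            pmatch = (
                fai[0] * fbj[0]
                + fai[1] * fbj[1]
                + fai[2] * fbj[2]
                + fai[3] * fbj[3]
            )
            sb = sum_b[j - 1]
            col = (
                match * pmatch
                + mismatch * (sa * sb - pmatch)
                + gap * (sa * fbj[4] + ga * sb)
            )
            d = H[i - 1, j - 1] + col
            u = H[i - 1, j] + gap * sa
            l = H[i, j - 1] + gap * sb
            h = d
            t = 1
            if u > h:
                h = u
                t = 2
            if l > h:
                h = l
                t = 3
            H[i, j] = h
            TB[i, j] = t
    # traceback
    i = la
    j = lb
    length = 0
    while i > 0 or j > 0:
        t = TB[i, j]
        length += 1
        if t == 1:
            i -= 1
            j -= 1
        elif t == 2:
            i -= 1
        else:
            j -= 1
    ia = np.empty(length, np.int32)
    ib = np.empty(length, np.int32)
    i = la
    j = lb
    k = length - 1
    while i > 0 or j > 0:
        t = TB[i, j]
        if t == 1:
            ia[k] = i - 1
            ib[k] = j - 1
            i -= 1
            j -= 1
        elif t == 2:
            ia[k] = i - 1
            ib[k] = -1
            i -= 1
        else:
            ia[k] = -1
            ib[k] = j - 1
            j -= 1
        k -= 1
    return H[la, lb], ia, ib


@njit(cache=True)
def sw_align_batch(seqcat, offsets, lengths, pair_i, pair_j, sub, gap_open,
                   gap_ext, band):
    """Vectorized driver: :func:`sw_align` over an array of sequence pairs.

    Sequences live concatenated in ``seqcat`` with per-sequence offsets and
    lengths; returns an (n_pairs, 7) int32 array of the per-pair tuples.
    """
    n = pair_i.shape[0]
    out = np.empty((n, 7), np.int32)
    for t in range(n):
        i = pair_i[t]
        j = pair_j[t]
        a = seqcat[offsets[i] : offsets[i] + lengths[i]]
        b = seqcat[offsets[j] : offsets[j] + lengths[j]]
        score, matches, cols, a0, a1, b0, b1 = sw_align(
            a, b, sub, gap_open, gap_ext, band
        )
        out[t, 0] = score
        out[t, 1] = matches
        out[t, 2] = cols
        out[t, 3] = a0
        out[t, 4] = a1
        out[t, 5] = b0
        out[t, 6] = b1
    return out
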