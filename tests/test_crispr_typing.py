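"""CRISPR array detection, spacer comparison, in-silico PCR, primer design."""

import numpy as np
import pytest

from panlineage.crispr_typing import (
    Amplicon,
    CrisprArray,
    compare_spacer_arrays,
    design_strain_primers,
    detect_arrays,
    in_silico_pcr,
    reverse_complement,
    wallace_tm,
)
from panlineage.io_formats import StrainRecord

NT = np.array(list("ACGT"))


def rand_seq(rng, n):
    return "".join(rng.choice(NT, n))


def plant(rng, genome_len, n_spacers=4, repeat_len=30, spacer_len=34, pos=None):
    repeat = rand_seq(rng, repeat_len)
    spacers = [rand_seq(rng, spacer_len) for _ in range(n_spacers)]
    block = repeat + "".join(s + repeat for s in spacers)
    backbone = rand_seq(rng, genome_len)
    if pos is None:
        pos = genome_len // 2
    seq = backbone[:pos] + block + backbone[pos:]
    return seq, pos, pos + len(block), repeat, spacers


def test_planted_array_recovered_verbatim():
    rng = np.random.default_rng(0)
    seq, start, end, repeat, spacers = plant(rng, 50_000)
    found = detect_arrays("c1", seq, strain_id="S1")
    assert len(found) == 1
    arr = found[0]
    assert (arr.start, arr.end) == (start, end)
    assert arr.repeat_consensus == repeat
    assert arr.spacers == spacers


def test_two_repeat_copies_rejected():
    rng = np.random.default_rng(1)
    seq, *_ = plant(rng, 20_000, n_spacers=1)  # 2 repeat copies only
    assert detect_arrays("c1", seq) == []


def test_random_sequence_has_no_arrays():
    empties = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        if detect_arrays("c1", rand_seq(rng, 100_000)) == []:
            empties += 1
    assert empties >= 19


def test_long_array_in_paper_spacer_range():
    rng = np.random.default_rng(2)
    seq, start, end, repeat, spacers = plant(
        rng, 60_000, n_spacers=30, repeat_len=36, spacer_len=35
    )
    (arr,) = detect_arrays("c1", seq)
    assert arr.spacers == spacers
    assert 24 <= arr.n_spacers <= 58


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------

def _arr(spacers, sid="s", repeat="R" * 0 + "ACGTACGTACGTACGTACGTACG"):
    return CrisprArray(sid, "c", 0, 1, repeat, list(spacers))


def test_identical_arrays_full_match():
    rng = np.random.default_rng(3)
    spacers = [rand_seq(rng, 34) for _ in range(30)]
    m = compare_spacer_arrays(_arr(spacers), _arr(spacers))
    assert m.match_class == "full"
    assert m.n_shared == 30
    assert m.order_consistent


def test_internal_deletion_gives_partial_29_of_30():
    rng = np.random.default_rng(4)
    spacers = [rand_seq(rng, 34) for _ in range(30)]
    deleted = spacers[:12] + spacers[13:]
    m = compare_spacer_arrays(_arr(spacers), _arr(deleted))
    assert m.match_class == "partial"
    assert m.n_shared == 29
    assert m.order_consistent


def test_disjoint_arrays_none():
    rng = np.random.default_rng(5)
    a = [rand_seq(rng, 34) for _ in range(5)]
    b = [rand_seq(rng, 34) for _ in range(5)]
    assert compare_spacer_arrays(_arr(a), _arr(b)).match_class == "none"


def test_reverse_complement_orientation_harmonised():
    rng = np.random.default_rng(6)
    spacers = [rand_seq(rng, 34) for _ in range(8)]
    flipped = [reverse_complement(s) for s in reversed(spacers)]
    m = compare_spacer_arrays(_arr(spacers), _arr(flipped))
    assert m.match_class == "full"
    assert m.n_shared == 8


def test_comparison_symmetric_and_bounded():
    rng = np.random.default_rng(7)
    shared = [rand_seq(rng, 34) for _ in range(6)]
    a = _arr(shared + [rand_seq(rng, 34) for _ in range(3)])
    b = _arr([rand_seq(rng, 34) for _ in range(2)] + shared)
    mab = compare_spacer_arrays(a, b)
    mba = compare_spacer_arrays(b, a)
    assert mab.n_shared == mba.n_shared == 6
    assert mab.match_class == mba.match_class == "partial"
    assert mab.n_shared <= min(a.n_spacers, b.n_spacers)


def test_empty_array_warns_none():
    with pytest.warns(UserWarning):
        m = compare_spacer_arrays(_arr([]), _arr(["ACGT" * 9]))
    assert m.match_class == "none"


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------

def test_pcr_exact_amplicon():
    rng = np.random.default_rng(8)
    genome = rand_seq(rng, 5000)
    fwd = genome[1000:1020]
    rev = reverse_complement(genome[1130:1150])
    amps = in_silico_pcr(fwd, rev, [("c1", genome)])
    assert amps == [Amplicon("c1", 1001, 1150, 150)]


def test_pcr_no_binding_sites():
    rng = np.random.default_rng(9)
    genome = rand_seq(rng, 3000)
    assert in_silico_pcr("A" * 20, "C" * 20, [("c1", genome)]) == []


def test_pcr_degenerate_same_site_rejected():
    rng = np.random.default_rng(10)
    genome = rand_seq(rng, 3000)
    fwd = genome[500:520]
    rev = reverse_complement(fwd)  # binds the same 20 bp
    assert in_silico_pcr(fwd, rev, [("c1", genome)]) == []


def test_pcr_one_mismatch_tolerated_but_not_at_three_prime():
    rng = np.random.default_rng(11)
    genome = rand_seq(rng, 4000)
    site = genome[2000:2020]
    rev = reverse_complement(genome[2150:2170])
    mid = list(site)
    mid[5] = "A" if mid[5] != "A" else "C"
    assert in_silico_pcr("".join(mid), rev, [("c1", genome)])
    tail = list(site)
    tail[-1] = "A" if tail[-1] != "A" else "C"
    assert in_silico_pcr("".join(tail), rev, [("c1", genome)]) == []


def test_pcr_primer_length_validated():
    with pytest.raises(ValueError):
        in_silico_pcr("ACGT", "ACGTACGTACGTACGTACGT", [("c", "ACGT" * 100)])


# ---------------------------------------------------------------------------
# primer design
# ---------------------------------------------------------------------------

def _strain_with_array(rng, sid, genome_len=30_000, n_spacers=6):
    seq, start, end, repeat, spacers = plant(
        rng, genome_len, n_spacers=n_spacers, repeat_len=36, spacer_len=36
    )
    rec = StrainRecord(sid, f"p_{sid}", contigs=[(f"{sid}_c1", seq)])
    arr = CrisprArray(sid, f"{sid}_c1", start, end, repeat, spacers)
    return rec, arr


def test_unique_spacer_yields_specific_primer_pair():
    rng = np.random.default_rng(12)
    recs, arrs = [], []
    for i in range(3):
        r, a = _strain_with_array(rng, f"S{i}")
        recs.append(r)
        arrs.append(a)
    cand = design_strain_primers(arrs[0], recs[0], recs)
    assert cand is not None
    nonzero = {s for s, c in cand.specificity.items() if c > 0}
    assert nonzero == {"S0"}
    assert 80 <= cand.amplicon_length <= 300
    assert 55 <= wallace_tm(cand.forward) <= 65
    # idempotent specificity re-check
    amps = in_silico_pcr(cand.forward, cand.reverse, recs[0].contigs)
    assert len(amps) == 1 and amps[0].length == cand.amplicon_length


def test_clone_pair_rejected_no_unique_spacer():
    rng = np.random.default_rng(13)
    rec, arr = _strain_with_array(rng, "S0")
    clone = StrainRecord("S1", "p1", contigs=[("S1_c1", rec.contigs[0][1])])
    clone_arr = CrisprArray("S1", "S1_c1", arr.start, arr.end, arr.repeat_consensus,
                            list(arr.spacers))
    assert design_strain_primers(arr, rec, [rec, clone]) is None
    assert design_strain_primers(clone_arr, clone, [rec, clone]) is None
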