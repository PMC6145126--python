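"""NG86 site/difference counting and Jukes-Cantor-corrected Ka/Ks."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from kinome_evo.kaks import (
    SENSE_CODONS,
    codon_align,
    count_differences,
    count_sites,
    jukes_cantor,
    kaks,
    ks_histogram,
    KaKsResult,
)
from _oracles import ref_diffs, ref_kaks, ref_sites

SENSE = sorted(SENSE_CODONS)


@pytest.mark.parametrize(
    "codon,expected_s",
    [
        ("GGG", 1.0),  # 4-fold degenerate third position, others fixed
        ("TTT", 1.0 / 3),  # only TTC synonymous among 9 neighbours
        ("ATG", 0.0),  # Met: no synonymous single-base neighbour
    ],
)
def test_site_counts_known_codons(codon, expected_s):
    s, n = count_sites(codon)
    assert s == pytest.approx(expected_s, abs=1e-12)
    assert s + n == pytest.approx(3.0, abs=1e-12)


def test_site_counts_sum_to_three_for_all_sense_codons():
    for codon in SENSE:
        s, n = count_sites(codon)
        assert s + n == pytest.approx(3.0, abs=1e-12)
        ref_s, _ = ref_sites(codon)
        assert s == pytest.approx(ref_s, abs=1e-12)


def test_stop_codon_rejected():
    with pytest.raises(ValueError):
        count_sites("TAA")
    with pytest.raises(ValueError):
        count_differences("TAA", "AAA")


def test_identical_codons_no_differences():
    assert count_differences("ATG", "ATG") == (0.0, 0.0)


def test_single_synonymous_change():
    assert count_differences("GGA", "GGG") == (1.0, 0.0)


def test_two_difference_pair_matches_pathway_enumeration():
    sd, nd = count_differences("TTT", "GTA")
    ref_sd, ref_nd = ref_diffs("TTT", "GTA")
    assert (sd, nd) == pytest.approx((ref_sd, ref_nd), abs=1e-12)
    assert sd + nd == 2.0


def test_difference_counts_match_oracle_exhaustively():
    """Every codon pair: pathway averaging equals brute-force enumeration."""
    rng = random.Random(7)
    pairs = [(rng.choice(SENSE), rng.choice(SENSE)) for _ in range(1500)]
    for ca, cb in pairs:
        sd, nd = count_differences(ca, cb)
        ref_sd, ref_nd = ref_diffs(ca, cb)
        assert abs(sd - ref_sd) < 1e-12 and abs(nd - ref_nd) < 1e-12, (ca, cb)
        n_diff = sum(a != b for a, b in zip(ca, cb))
        assert sd + nd == pytest.approx(n_diff, abs=1e-12)


def test_jukes_cantor_monotone_and_saturating():
    grid = [i / 1000 for i in range(0, 750)]
    values = [jukes_cantor(p) for p in grid]
    assert values[0] == 0.0
    assert all(b > a for a, b in zip(values, values[1:]))
    assert jukes_cantor(0.75) is None
    assert jukes_cantor(0.9) is None


def test_identical_sequences_zero_rates():
    seq = "ATGGCTGCAAAGGAG"
    res = kaks(seq, seq)
    assert res.ka == 0.0 and res.ks == 0.0
    assert res.ratio is None and res.selection == "undefined"


def test_kaks_symmetric():
    a = "ATGGCTGCAAAGGAGTTGCGA"
    b = "ATGGCAGCTAAAGAGTTGCGG"
    ra = kaks(a, b)
    rb = kaks(b, a)
    assert (ra.ks, ra.ka, ra.sd, ra.nd) == (rb.ks, rb.ka, rb.sd, rb.nd)


def test_kaks_matches_reference_on_random_pairs():
    rng = random.Random(3)
    for _ in range(60):
        n = rng.randrange(10, 40)
        a = "".join(rng.choice(SENSE) for _ in range(n))
        b = "".join(
            rng.choice(SENSE) if rng.random() < 0.3 else ca
            for ca in (a[i : i + 3] for i in range(0, len(a), 3))
        )
        res = kaks(a, b)
        ref_ks, ref_ka = ref_kaks(a, b)
        if ref_ks is None:
            assert res.ks is None
        else:
            assert res.ks == pytest.approx(ref_ks, abs=1e-12)
        if ref_ka is None:
            assert res.ka is None
        else:
            assert res.ka == pytest.approx(ref_ka, abs=1e-12)
        assert res.s_sites + res.n_sites == pytest.approx(3 * n, abs=1e-9)


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=25, deadline=None)
def test_site_totals_conserved(seed):
    rng = random.Random(seed)
    codons = [rng.choice(SENSE) for _ in range(30)]
    seq = "".join(codons)
    res = kaks(seq, seq)
    assert res.s_sites + res.n_sites == pytest.approx(90.0, abs=1e-9)


def test_codon_align_errors():
    with pytest.raises(ValueError):
        codon_align("ATGA", "ATGA")  # not a multiple of 3
    with pytest.raises(ValueError):
        codon_align("ATGTAAGGG", "ATGGGGGGG")  # internal stop
    with pytest.raises(ValueError):
        codon_align("ATGGGG", "ATG")  # unequal without alignment


def test_codon_align_with_protein_alignment_drops_gap_columns():
    # MA vs MGA: gap column removes the G codon
    pairs = codon_align("ATGGCT", "ATGGGTGCT", protein_alignment=("M-A", "MGA"))
    assert pairs == [("ATG", "ATG"), ("GCT", "GCT")]


def test_codon_align_translation_mismatch_rejected():
    with pytest.raises(ValueError):
        codon_align("ATGGCT", "ATGGCT", protein_alignment=("MV", "MA"))


def test_terminal_stop_codons_dropped():
    res = kaks("ATGGCTTAA", "ATGGCTTGA")
    assert res.sd == 0.0 and res.nd == 0.0


def test_selection_classes():
    syn_only = kaks("ATGGCTAAAGAAACCCTGGGA", "ATGGCTAAAGAAACCCTGGGG")
    assert syn_only.ka == 0.0 and syn_only.ratio == 0.0
    assert syn_only.selection == "purifying"
    nonsyn_only = kaks("ATGGCT", "ATGTCT")  # A->S, no synonymous change
    assert nonsyn_only.ks == 0.0 and nonsyn_only.ratio is None
    assert nonsyn_only.selection == "undefined"


def _mk_result(ks):
    return KaKsResult(
        gene_a="a", gene_b="b", s_sites=1, n_sites=2, sd=0, nd=0,
        ps=0, pn=0, ks=ks, ka=0.0, ratio=None, selection="undefined",
    )


def test_ks_histogram_binning():
    hist = ks_histogram([_mk_result(k) for k in (0.25, 0.27, 1.15)], 0.1)
    assert hist.counts == {2: 2, 11: 1}
    assert hist.peak_bins == [2]
    assert hist.bin_label(2) == "0.2-0.3"


def test_ks_histogram_empty_and_undefined():
    assert ks_histogram([], 0.1).counts == {}
    hist = ks_histogram([_mk_result(None), _mk_result(0.05)], 0.1)
    assert hist.n_undefined == 1 and hist.counts == {0: 1}
    with pytest.raises(ValueError):
        ks_histogram([], 0.0)
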