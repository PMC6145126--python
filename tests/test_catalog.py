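"""Kinase identification filters, family assignment and summaries."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from kinome_evo.catalog import (
    DomainHit,
    assign_family,
    build_catalog,
    count_introns,
    count_kinase_domains,
    filter_kinase_hits,
    parse_domain_hits,
    summarize_catalog,
)
from kinome_evo.models import Gene, KinaseRecord, Transcript


def _hit(**kw):
    base = dict(
        protein_id="p1",
        model_name="Pkinase",
        model_length=260,
        seq_evalue=1e-30,
        dom_evalue=1e-20,
        bit_score=200.0,
        hmm_from=1,
        hmm_to=260,
        ali_from=1,
        ali_to=260,
    )
    base.update(kw)
    return DomainHit(**base)


TABLE = """\
# target query mlen seqE domE bits hf ht af at
p1 Pkinase 260 1e-30 1e-25 210.5 3 250 10 255
p1 FamA_1 250 1e-40 1e-35 300.0 1 250 1 250
"""


def test_parse_hit_table():
    hits = parse_domain_hits(io.StringIO(TABLE))
    assert len(hits) == 2
    assert hits[0].hmm_from == 3 and hits[0].hmm_to == 250
    assert hits[1].bit_score == 300.0


def test_parse_empty_and_malformed():
    assert parse_domain_hits(io.StringIO("")) == []
    with pytest.raises(ValueError):
        parse_domain_hits(io.StringIO("p1 Pkinase 260 1e-30\n"))


def test_parse_rejects_invariant_violations(caplog):
    bad = "p1 Pkinase 260 1e-30 1e-25 210.5 3 270 10 255\n"  # hmm_to > length
    with caplog.at_level("WARNING"):
        hits = parse_domain_hits(io.StringIO(bad))
    assert hits == []
    assert "line 1" in caplog.text


def test_filter_coverage_boundary_inclusive():
    half = _hit(hmm_from=1, hmm_to=130)  # exactly 50% of 260
    assert filter_kinase_hits([half]) == [half]
    below = _hit(hmm_from=1, hmm_to=129)
    assert filter_kinase_hits([below]) == []


def test_filter_evalue_boundary_strict():
    at_cutoff = _hit(dom_evalue=1e-5, hmm_from=1, hmm_to=234)  # coverage 0.9
    assert filter_kinase_hits([at_cutoff]) == []
    just_below = _hit(dom_evalue=9.9e-6, hmm_from=1, hmm_to=234)
    assert filter_kinase_hits([just_below]) == [just_below]


@given(
    st.floats(min_value=1e-12, max_value=1e-3),
    st.floats(min_value=0.1, max_value=1.0),
)
@settings(max_examples=50, deadline=None)
def test_filter_monotone_in_both_thresholds(evalue_max, coverage):
    hits = [
        _hit(dom_evalue=10.0**-e, hmm_from=1, hmm_to=int(260 * c))
        for e in (2, 4, 6, 10, 20)
        for c in (0.2, 0.5, 0.8, 1.0)
    ]
    strict = set(map(id, filter_kinase_hits(hits, evalue_max, coverage)))
    relaxed = set(map(id, filter_kinase_hits(hits, evalue_max * 10, max(coverage / 2, 1e-6))))
    assert strict <= relaxed


def test_assign_family_argmax_and_group_prefix():
    hits = [
        _hit(model_name="RLK-Pelle_DLSV", bit_score=300.0),
        _hit(model_name="CAMK_CDPK", bit_score=120.0),
    ]
    family, group, tie, margin = assign_family(hits)
    assert family == "RLK-Pelle_DLSV" and group == "RLK-Pelle"
    assert not tie and margin == pytest.approx(180.0)


def test_assign_family_no_hits_unclassified():
    assert assign_family([]) == ("unclassified", "unclassified", False, None)


def test_assign_family_tie_lexicographic_and_flagged():
    hits = [
        _hit(model_name="FamB_2", bit_score=200.0),
        _hit(model_name="FamA_1", bit_score=200.0),
    ]
    family, group, tie, margin = assign_family(hits)
    assert family == "FamA_1" and tie and margin == 0.0


def test_domain_counting_merges_split_alignments():
    disjoint = [_hit(ali_from=10, ali_to=300), _hit(ali_from=400, ali_to=690)]
    assert count_kinase_domains(disjoint) == 2
    overlapping = [_hit(ali_from=10, ali_to=300), _hit(ali_from=20, ali_to=310)]
    assert count_kinase_domains(overlapping) == 1
    five = [_hit(ali_from=1 + 300 * i, ali_to=260 + 300 * i) for i in range(5)]
    assert count_kinase_domains(five) == 5


def _gene(gene_id, exon_counts_and_cds, chrom="chr1", start=1, end=10_000):
    transcripts = [
        Transcript(
            transcript_id=f"{gene_id}.t{i}",
            gene_id=gene_id,
            strand="+",
            exons=[(1 + 200 * k, 100 + 200 * k) for k in range(n_exons)],
            cds_length=cds,
        )
        for i, (n_exons, cds) in enumerate(exon_counts_and_cds)
    ]
    return Gene(gene_id=gene_id, chrom=chrom, start=start, end=end, strand="+",
                transcripts=transcripts)


def test_intron_count_uses_longest_cds_transcript():
    assert count_introns(_gene("g1", [(1, 300)])) == 0
    assert count_introns(_gene("g2", [(68, 600)])) == 67
    assert count_introns(_gene("g3", [(3, 300), (5, 600)])) == 4
    with pytest.raises(ValueError):
        count_introns(_gene("g4", []))


def _record(gene_id, family, group, chrom, n_domains=1):
    return KinaseRecord(
        gene_id=gene_id, protein_id=gene_id, family=family, group=group,
        n_kinase_domains=n_domains, intron_count=0, chrom=chrom,
        start=1, end=100, strand="+",
    )


def test_summary_totals_conserved():
    records = [
        _record(f"g{i}", "FamA_1", "FamA", "chr1") for i in range(6)
    ] + [
        _record(f"h{i}", "FamB_2", "FamB", "scaffold_7") for i in range(4)
    ]
    summary = summarize_catalog(records)
    assert summary.family_counts == {"FamA_1": 6, "FamB_2": 4}
    assert sum(summary.family_counts.values()) == summary.total == 10
    assert summary.scaffold_genes == 4
    assert summary.n_chromosome_genes + summary.scaffold_genes == summary.total


def test_summary_domain_multiplicity():
    multiplicities = {2: 57, 3: 9, 4: 3, 5: 1}
    records = [
        _record(f"g{k}_{i}", "FamA_1", "FamA", "chr1", n_domains=k)
        for k, count in multiplicities.items()
        for i in range(count)
    ]
    summary = summarize_catalog(records)
    assert summary.domain_multiplicity == multiplicities
    assert summary.n_multidomain == 70


def test_catalog_on_synthetic_genome_no_false_positives(small_genome, small_genome_files):
    from kinome_evo.gffio import read_gene_models

    hits = parse_domain_hits(io.StringIO(small_genome.hit_table()))
    genes = read_gene_models(small_genome_files["gff3"])
    records = build_catalog(hits, genes)
    identified = {r.gene_id for r in records}
    assert identified == set(small_genome.truth["kinases"])
    assert identified.isdisjoint(small_genome.truth["decoys"])
    for r in records:
        truth = small_genome.truth["kinases"][r.gene_id]
        assert r.family == truth["family"]
        assert r.n_kinase_domains == truth["n_domains"]
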