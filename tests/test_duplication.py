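"""Tandem calling boundaries and collinear-block chaining."""

import random

import pytest

from kinome_evo.duplication import (
    AnchorPair,
    call_tandem,
    classify_duplication,
    find_collinear_blocks,
)
from kinome_evo.models import Gene, KinaseRecord, Transcript
from kinome_evo.synthetic import SynthGenomeConfig, gen_genome
from _oracles import ref_longest_chain, ref_tandem_pairs


def _gene(gene_id, chrom, start, end):
    tx = Transcript(
        transcript_id=f"{gene_id}.t1", gene_id=gene_id, strand="+",
        exons=[(start, end)], cds_length=end - start + 1,
    )
    return Gene(gene_id=gene_id, chrom=chrom, start=start, end=end, strand="+",
                transcripts=[tx])


def _kinase(gene, family="FamA_1"):
    return KinaseRecord(
        gene_id=gene.gene_id, protein_id=gene.gene_id, family=family,
        group=family.split("_")[0], n_kinase_domains=1, intron_count=0,
        chrom=gene.chrom, start=gene.start, end=gene.end, strand="+",
    )


def _chromosome(specs):
    """specs: list of (gene_id, start, end); returns genes in order."""
    return [_gene(g, "chr1", s, e) for g, s, e in specs]


def test_adjacent_same_family_pair_is_tandem():
    genes = _chromosome([("a", 1000, 2000), ("b", 7000, 8000)])
    events, arrays = call_tandem([_kinase(genes[0]), _kinase(genes[1])], genes)
    assert len(events) == 1
    ev = events[0]
    assert ev.intervening_genes == 0 and ev.separation_bp == 5000 - 1 + 1
    assert arrays == [["a", "b"]]


def test_six_intervening_genes_not_tandem():
    specs = [("a", 1000, 2000)]
    specs += [(f"d{i}", 3000 + i * 2000, 4000 + i * 2000) for i in range(6)]
    specs += [("b", 20000, 21000)]
    genes = _chromosome(specs)
    kin = [_kinase(genes[0]), _kinase(genes[-1])]
    events, _ = call_tandem(kin, genes)
    assert events == []


def test_exactly_five_intervening_genes_is_tandem():
    specs = [("a", 1000, 2000)]
    specs += [(f"d{i}", 3000 + i * 2000, 4000 + i * 2000) for i in range(5)]
    specs += [("b", 18000, 19000)]
    genes = _chromosome(specs)
    events, _ = call_tandem([_kinase(genes[0]), _kinase(genes[-1])], genes)
    assert len(events) == 1 and events[0].intervening_genes == 5


def test_exactly_100kb_separation_not_tandem():
    genes = _chromosome([("a", 1000, 2000), ("b", 102_000, 103_000)])
    kin = [_kinase(g) for g in genes]
    events, _ = call_tandem(kin, genes)  # gap = 102000 - 2000 = 100000
    assert events == []
    closer = _chromosome([("a", 1000, 2001), ("b", 102_000, 103_000)])
    events, _ = call_tandem([_kinase(g) for g in closer], closer)
    assert len(events) == 1 and events[0].separation_bp == 99_999


def test_different_family_or_chromosome_never_tandem():
    genes = _chromosome([("a", 1000, 2000), ("b", 3000, 4000)])
    events, _ = call_tandem(
        [_kinase(genes[0], "FamA_1"), _kinase(genes[1], "FamB_2")], genes
    )
    assert events == []
    g2 = [_gene("a", "chr1", 1000, 2000), _gene("b", "chr2", 3000, 4000)]
    events, _ = call_tandem([_kinase(g2[0]), _kinase(g2[1])], g2)
    assert events == []


def test_tandem_matches_exhaustive_scan_on_random_genomes():
    """Caller output equals an O(n^2) reference scan over synthetic genomes."""
    for seed in range(12):
        sim = gen_genome(
            SynthGenomeConfig(
                n_chromosomes=3,
                genes_per_chromosome=120,
                n_tandem_arrays=seed % 4,
                tandem_array_size=2 + seed % 2,
                n_collinear_blocks=1,
                block_length=5,
                n_decoys=220,
                seed=seed,
            )
        )
        records = [
            KinaseRecord(
                gene_id=g, protein_id=g, family=info["family"], group=info["group"],
                n_kinase_domains=1, intron_count=0,
                chrom=next(x.chrom for x in sim.genes if x.gene_id == g),
                start=next(x.start for x in sim.genes if x.gene_id == g),
                end=next(x.end for x in sim.genes if x.gene_id == g),
                strand="+",
            )
            for g, info in sim.truth["kinases"].items()
        ]
        events, _ = call_tandem(records, sim.genes)
        called = {(e.gene_a, e.gene_b) for e in events}
        oracle = ref_tandem_pairs(
            [
                {"gene": r.gene_id, "family": r.family, "chrom": r.chrom,
                 "start": r.start, "end": r.end}
                for r in records
            ],
            [{"gene": g.gene_id, "chrom": g.chrom, "start": g.start} for g in sim.genes],
            max_intervening=5,
            max_bp=100_000,
        )
        assert called == oracle
        # planted arrays all recovered, near-miss pairs never called
        planted = {
            tuple(sorted(pair))
            for arr in sim.truth["tandem_arrays"]
            for pair in zip(arr, arr[1:])
        }
        assert planted <= called
        for pair in sim.truth["near_miss_pairs"]:
            assert tuple(sorted(pair)) not in called


def _anchors(points, chrom_a="chr1", chrom_b="chr2"):
    return [
        AnchorPair(
            gene_a=f"a{i}", gene_b=f"b{i}", chrom_a=chrom_a, chrom_b=chrom_b,
            rank_a=ra, rank_b=rb,
        )
        for i, (ra, rb) in enumerate(points)
    ]


def test_identical_order_single_block():
    anchors = _anchors([(i, i) for i in range(10)])
    blocks = find_collinear_blocks(anchors)
    assert len(blocks) == 1
    assert len(blocks[0].anchors) == 10
    assert blocks[0].orientation == "same"


def test_inverted_block_detected():
    anchors = _anchors([(i, 20 - i) for i in range(8)])
    blocks = find_collinear_blocks(anchors)
    assert len(blocks) == 1 and blocks[0].orientation == "inverted"


def test_random_permutation_no_block():
    rng = random.Random(42)
    while True:  # draw until no monotone run of 5 exists, verified by oracle
        perm = list(range(10))
        rng.shuffle(perm)
        points = list(enumerate(perm))
        if ref_longest_chain(points, max_gap=25) < 5:
            break
    assert find_collinear_blocks(_anchors(points)) == []


def test_gap_constraint_splits_chains():
    # rank_b jumps by 30 > max_gap in the middle
    points = [(i, i) for i in range(6)] + [(i, i + 30) for i in range(6, 12)]
    blocks = find_collinear_blocks(_anchors(points), min_block=5, max_gap=25)
    assert len(blocks) == 2
    assert all(len(b.anchors) == 6 for b in blocks)


def test_block_length_matches_bruteforce_oracle():
    rng = random.Random(1)
    for _ in range(15):
        n = rng.randrange(6, 13)
        points = [(rng.randrange(0, 30), rng.randrange(0, 30)) for _ in range(n)]
        points = list({p for p in points})
        best = ref_longest_chain(points, max_gap=25)
        blocks = find_collinear_blocks(_anchors(points), min_block=2, max_gap=25)
        found_best = max((len(b.anchors) for b in blocks), default=1)
        assert found_best == best


def test_planted_blocks_recovered_exactly(small_genome):
    blocks = find_collinear_blocks(small_genome.anchor_pairs())
    found = sorted(
        sorted((a.gene_a, a.gene_b) for a in b.anchors) for b in blocks
    )
    truth = sorted(
        sorted(map(tuple, b["anchors"])) for b in small_genome.truth["blocks"]
    )
    assert found == truth


def test_no_anchor_in_two_blocks():
    anchors = _anchors([(i, i) for i in range(20)])
    blocks = find_collinear_blocks(anchors, min_block=5)
    seen = set()
    for b in blocks:
        for a in b.anchors:
            assert (a.gene_a, a.gene_b) not in seen
            seen.add((a.gene_a, a.gene_b))


def test_origin_classification():
    genes = _chromosome([("a", 1000, 2000), ("b", 5000, 6000)])
    kin = [_kinase(genes[0]), _kinase(genes[1])]
    events, _ = call_tandem(kin, genes)
    blocks = find_collinear_blocks(
        _anchors([(i, i) for i in range(5)]), min_block=5
    )
    # fake membership: rename one anchor gene to "a"
    blocks[0].anchors[0] = AnchorPair(
        gene_a="a", gene_b="b0", chrom_a="chr1", chrom_b="chr2", rank_a=0, rank_b=0
    )
    labels = classify_duplication(kin, events, blocks)
    assert labels["a"] == "both"
    assert labels["b"] == "tandem"
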