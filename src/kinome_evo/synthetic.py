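"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators emulate the data shapes of a genome-wide kinase survey:

* :func:`gen_genome` — a multi-chromosome gene annotation with planted
  kinase families, tandem arrays obeying the <=5-intervening / <100 kb
  rule, collinear anchor blocks on chromosome pairs, and decoy genes
  whose domain hits are constructed to fail the E-value or
  model-coverage filter;
* :func:`gen_cds_pair` — codon-level diverged CDS pairs with controlled
  synonymous/nonsynonymous divergence for Ka/Ks recovery experiments;
* :func:`gen_expression` — FPKM matrices with planted clusters and a
  controlled fraction of lowly-expressed genes;
* :func:`gen_isoforms` — transcript models exhibiting requested
  alternative-splicing events.

All generators are pure functions of their config (seed included):
the same config yields byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from io import StringIO
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import DomainHit
from .duplication import AnchorPair
from .kaks import SENSE_CODONS, CODON_TO_AA, count_sites
from .models import Gene, Transcript
from .gffio import write_gff3

__all__ = [
    "SynthGenomeConfig",
    "CodonPairConfig",
    "ExpressionSimConfig",
    "GenomeSim",
    "CdsPair",
    "ExpressionSim",
    "gen_genome",
    "gen_cds_pair",
    "gen_expression",
    "gen_isoforms",
]

_SORTED_SENSE = sorted(SENSE_CODONS)

#: default tissue panel emulating a 14-tissue developmental survey
DEFAULT_TISSUES = (
    "flower",
    "fruit_S1",
    "fruit_S2",
    "fruit_S3",
    "fruit_S4",
    "fruit_S5",
    "fruit_S6",
    "fruit_S7",
    "leaf",
    "root",
    "green_tip",
    "white_base",
    "calyx",
    "stem",
)


class SizingError(ValueError):
    """Planted features exceed the configured genome capacity."""


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

@dataclass
class SynthGenomeConfig:
    n_chromosomes: int = 6
    genes_per_chromosome: int = 120
    n_families: int = 6
    family_sizes: list[int] | None = None
    n_tandem_arrays: int = 3
    tandem_array_size: int = 2
    n_collinear_blocks: int = 2
    block_length: int = 6
    n_decoys: int = 300
    intergenic_gap_bp: tuple[int, int] = (500, 5000)
    near_miss_gap_bp: int = 150_000
    plant_near_miss: bool = True
    n_multidomain: int = 4
    decoy_fail_mode: str | None = None  # force: evalue | coverage | no_hit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family_sizes is None:
            # per-family demand of the planted features, plus two
            # scattered members each
            demand = [0] * self.n_families
            for a in range(self.n_tandem_arrays):
                demand[a % self.n_families] += self.tandem_array_size
            if self.plant_near_miss and self.n_families:
                demand[0] += 2
            for _ in range(self.n_collinear_blocks):
                for k in range(self.block_length):
                    demand[k % self.n_families] += 2
            self.family_sizes = [d + 2 for d in demand]
        if len(self.family_sizes) != self.n_families:
            raise ValueError("family_sizes length must equal n_families")
        for name, value in (
            ("n_chromosomes", self.n_chromosomes),
            ("genes_per_chromosome", self.genes_per_chromosome),
            ("n_families", self.n_families),
            ("n_tandem_arrays", self.n_tandem_arrays),
            ("n_collinear_blocks", self.n_collinear_blocks),
            ("n_decoys", self.n_decoys),
        ):
            if value < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tandem_array_size < 2:
            raise ValueError("tandem_array_size must be >= 2")
        if self.n_collinear_blocks and self.block_length < 5:
            raise ValueError("block_length must be >= 5 (detector minimum)")
        if self.n_collinear_blocks and self.n_chromosomes < 2:
            raise SizingError("collinear blocks need at least two chromosomes")
        if self.decoy_fail_mode not in (None, "evalue", "coverage", "no_hit"):
            raise ValueError("decoy_fail_mode must be evalue|coverage|no_hit")
        lo, hi = self.intergenic_gap_bp
        if not (0 < lo <= hi):
            raise ValueError("intergenic_gap_bp must be a positive (min, max)")


@dataclass
class GenomeSim:
    """All synthetic genome outputs plus truth labels."""

    genes: list[Gene]
    cds: dict[str, str]
    proteins: dict[str, str]
    hits: list[DomainHit]
    truth: dict

    def hit_table(self) -> str:
        """The domain-hit table as whitespace-delimited text."""
        out = StringIO()
        out.write(
            "# target_name query_model model_length seq_evalue dom_evalue "
            "bit_score hmm_from hmm_to ali_from ali_to\n"
        )
        for h in self.hits:
            out.write(
                f"{h.protein_id} {h.model_name} {h.model_length} "
                f"{h.seq_evalue:.3g} {h.dom_evalue:.3g} {h.bit_score:.1f} "
                f"{h.hmm_from} {h.hmm_to} {h.ali_from} {h.ali_to}\n"
            )
        return out.getvalue()

    def gff3(self) -> str:
        out = StringIO()
        write_gff3(self.genes, out)
        return out.getvalue()

    def fasta(self, sequences: dict[str, str]) -> str:
        out = StringIO()
        for name in sequences:
            out.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), 60):
                out.write(seq[i : i + 60] + "\n")
        return out.getvalue()

    def anchor_pairs(self) -> list[AnchorPair]:
        """Truth anchors as detector-ready objects."""
        return [
            AnchorPair(
                gene_a=a["gene_a"],
                gene_b=a["gene_b"],
                chrom_a=a["chrom_a"],
                chrom_b=a["chrom_b"],
                rank_a=a["rank_a"],
                rank_b=a["rank_b"],
            )
            for a in self.truth["anchors"]
        ]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gff3": outdir / "genome.gff3",
            "cds": outdir / "cds.fasta",
            "proteins": outdir / "proteins.fasta",
            "hits": outdir / "hits.tsv",
            "anchors": outdir / "anchors.tsv",
            "truth": outdir / "truth.json",
        }
        paths["gff3"].write_text(self.gff3())
        paths["cds"].write_text(self.fasta(self.cds))
        paths["proteins"].write_text(self.fasta(self.proteins))
        paths["hits"].write_text(self.hit_table())
        with paths["anchors"].open("w") as fh:
            fh.write("gene_a\tgene_b\tchrom_a\tchrom_b\trank_a\trank_b\n")
            for a in self.truth["anchors"]:
                fh.write(
                    f"{a['gene_a']}\t{a['gene_b']}\t{a['chrom_a']}\t"
                    f"{a['chrom_b']}\t{a['rank_a']}\t{a['rank_b']}\n"
                )
        paths["truth"].write_text(json.dumps(self.truth, indent=1, sort_keys=True))
        return paths


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_SORTED_SENSE), size=n_codons)
    return "".join(_SORTED_SENSE[i] for i in idx)


def _translate(cds: str) -> str:
    return "".join(CODON_TO_AA[cds[i : i + 3]] for i in range(0, len(cds), 3))


_SPACER = 6  # decoys between planted items: > 5 intervening, never tandem


def gen_genome(config: SynthGenomeConfig) -> GenomeSim:
    """Generate a synthetic annotated genome with planted duplications.

    Chromosomes are token streams of kinase and decoy genes.  Tandem
    arrays are runs of same-family kinases with 0-2 intervening decoys
    and small gaps; every other pair of planted genes is separated by at
    least six intervening decoys, so planted arrays are the only tandem
    signal.  Collinear blocks place order-preserved anchor partners on a
    chromosome pair.  Raises :class:`SizingError` when the plant does
    not fit the configured capacity.
    """
    rng = np.random.default_rng(config.seed)
    fam_names = [f"FamK{chr(ord('A') + i)}_{i + 1}" for i in range(config.n_families)]
    quota = dict(zip(fam_names, config.family_sizes))

    def take(family: str) -> str:
        if quota[family] <= 0:
            raise SizingError(f"family {family} quota exhausted")
        quota[family] -= 1
        return family

    # --- assemble per-chromosome token streams ----------------------------
    chroms = [f"chr{c + 1}" for c in range(config.n_chromosomes)]
    tokens: dict[str, list[dict]] = {c: [] for c in chroms}
    decoy_budget = config.n_decoys
    truth_arrays: list[list[int]] = []  # token refs resolved to ids later
    token_counter = 0

    def new_token(chrom: str, kind: str, **meta) -> dict:
        nonlocal token_counter
        tok = {"kind": kind, "idx": token_counter, **meta}
        token_counter += 1
        tokens[chrom].append(tok)
        return tok

    def add_decoys(chrom: str, n: int) -> None:
        nonlocal decoy_budget
        if n == 0:
            return
        if decoy_budget < n:
            raise SizingError(
                "not enough decoy genes to separate planted features; "
                "increase n_decoys"
            )
        decoy_budget -= n
        for _ in range(n):
            new_token(chrom, "decoy")

    # tandem arrays, round-robin over chromosomes and families
    for a in range(config.n_tandem_arrays):
        chrom = chroms[a % len(chroms)]
        family = fam_names[a % len(fam_names)]
        if tokens[chrom]:
            add_decoys(chrom, _SPACER)
        array_tokens = []
        for m in range(config.tandem_array_size):
            if m > 0:
                add_decoys(chrom, int(rng.integers(0, 3)))
            tok = new_token(chrom, "kinase", family=take(family), role="tandem")
            array_tokens.append(tok)
        truth_arrays.append([t["idx"] for t in array_tokens])

    # near-miss pair: same family, 1 intervening decoy, separated by a
    # gap beyond the tandem bp threshold
    near_miss_tokens: list[dict] = []
    if config.plant_near_miss and config.n_families and quota[fam_names[0]] >= 2:
        chrom = chroms[0]
        add_decoys(chrom, _SPACER)
        t1 = new_token(chrom, "kinase", family=take(fam_names[0]), role="near_miss")
        add_decoys(chrom, 1)
        tokens[chrom][-1]["big_gap_after"] = True
        t2 = new_token(chrom, "kinase", family=take(fam_names[0]), role="near_miss")
        near_miss_tokens = [t1, t2]

    # collinear blocks on chromosome pairs
    block_truth: list[dict] = []
    for b in range(config.n_collinear_blocks):
        ca = chroms[(2 * b) % len(chroms)]
        cb = chroms[(2 * b + 1) % len(chroms)]
        if ca == cb:
            raise SizingError("not enough chromosomes for the requested blocks")
        pair_tokens = []
        for side in (ca, cb):
            add_decoys(side, _SPACER)
        for k in range(config.block_length):
            family = fam_names[k % len(fam_names)]
            take(family)
            take(family)  # both anchor partners drawn from the family quota
            if k > 0:
                add_decoys(ca, _SPACER)
                add_decoys(cb, _SPACER)
            ta = new_token(ca, "kinase", family=family, role="anchor", block=b)
            tb = new_token(cb, "kinase", family=family, role="anchor", block=b)
            pair_tokens.append((ta, tb))
        block_truth.append({"pair_tokens": pair_tokens, "chrom_a": ca, "chrom_b": cb})

    # scattered kinases: remaining quota, spaced so no unplanned tandems
    scatter_specs = [f for f in fam_names for _ in range(quota[f])]
    rng.shuffle(scatter_specs)
    for i, family in enumerate(scatter_specs):
        chrom = chroms[i % len(chroms)]
        add_decoys(chrom, _SPACER)
        quota[family] -= 1
        new_token(chrom, "kinase", family=family, role="scattered")

    # remaining decoys distributed round-robin at chromosome ends
    i = 0
    while decoy_budget > 0:
        new_token(chroms[i % len(chroms)], "decoy")
        decoy_budget -= 1
        i += 1

    for chrom in chroms:
        if len(tokens[chrom]) > config.genes_per_chromosome:
            raise SizingError(
                f"{chrom} holds {len(tokens[chrom])} genes but capacity is "
                f"{config.genes_per_chromosome}; increase genes_per_chromosome"
            )

    # --- materialise genes, sequences and hits ----------------------------
    genes: list[Gene] = []
    cds: dict[str, str] = {}
    proteins: dict[str, str] = {}
    hits: list[DomainHit] = []
    truth_kinases: dict[str, dict] = {}
    truth_decoys: dict[str, dict] = {}
    id_of_token: dict[int, str] = {}
    gene_no = 0
    lo_gap, hi_gap = config.intergenic_gap_bp
    multidomain_left = config.n_multidomain
    decoy_modes = ("evalue", "coverage", "no_hit")

    # per-family ancestral CDS: family members are diverged copies, so
    # duplicate pairs are alignable and yield defined Ka/Ks
    family_ancestor = {
        f: _random_cds(rng, int(rng.integers(250, 321))) for f in fam_names
    }

    def _diverge(seq: str, per_codon_rate: float = 0.08) -> str:
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        for i, codon in enumerate(codons):
            if rng.random() < per_codon_rate:
                syn, nonsyn = _single_change_options(codon)
                options = syn + nonsyn
                if options:
                    codons[i] = options[int(rng.integers(0, len(options)))]
        return "".join(codons)

    for chrom in chroms:
        pos = 1
        for tok in tokens[chrom]:
            gene_no += 1
            gid = f"g{gene_no:05d}"
            id_of_token[tok["idx"]] = gid
            if tok["kind"] == "kinase":
                seq = _diverge(family_ancestor[tok["family"]])
                n_codons = len(seq) // 3
            else:
                n_codons = int(rng.integers(120, 320))
                seq = _random_cds(rng, n_codons)
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, 7))
            # split CDS length over exons, then lay out with small introns
            cuts = np.sort(rng.choice(np.arange(1, n_codons * 3), size=n_exons - 1, replace=False)) if n_exons > 1 else np.array([], dtype=int)
            exon_lens = np.diff(np.concatenate(([0], cuts, [n_codons * 3])))
            exons = []
            cursor = pos
            for el in exon_lens:
                exons.append((cursor, cursor + int(el) - 1))
                cursor += int(el) + int(rng.integers(60, 400))
            start, end = exons[0][0], exons[-1][1]
            tx = Transcript(
                transcript_id=f"{gid}.t1",
                gene_id=gid,
                strand=strand,
                exons=exons,
                cds_length=n_codons * 3,
            )
            genes.append(
                Gene(gene_id=gid, chrom=chrom, start=start, end=end, strand=strand, transcripts=[tx])
            )
            cds[gid] = seq
            proteins[gid] = _translate(seq)
            gap = int(rng.integers(lo_gap, hi_gap + 1))
            if tok.get("big_gap_after"):
                gap = config.near_miss_gap_bp
            pos = end + 1 + gap

            prot_len = n_codons
            if tok["kind"] == "kinase":
                n_dom = 1
                if tok["role"] == "scattered" and multidomain_left > 0 and prot_len >= 290:
                    n_dom = 2
                    multidomain_left -= 1
                for d in range(n_dom):
                    model = "Pkinase" if rng.random() < 0.8 else "Pkinase_Tyr"
                    if n_dom > 1:
                        # half-model alignments on disjoint protein spans so
                        # the domain merger keeps them distinct
                        hmm_from, hmm_to = 131, 260
                        ali_from = 1 + d * 150
                        ali_to = ali_from + 129
                    else:
                        hmm_from = int(rng.integers(1, 30))
                        hmm_to = int(rng.integers(200, 261))
                        ali_len = hmm_to - hmm_from + 1
                        ali_from = 1
                        ali_to = min(ali_from + ali_len - 1, prot_len)
                    hits.append(
                        DomainHit(
                            protein_id=gid,
                            model_name=model,
                            model_length=260,
                            seq_evalue=10.0 ** -float(rng.uniform(20, 60)),
                            dom_evalue=10.0 ** -float(rng.uniform(8, 40)),
                            bit_score=float(rng.uniform(150, 500)),
                            hmm_from=hmm_from,
                            hmm_to=hmm_to,
                            ali_from=ali_from,
                            ali_to=ali_to,
                        )
                    )
                family = tok["family"]
                own_score = float(rng.uniform(250, 450))
                hits.append(
                    DomainHit(
                        protein_id=gid,
                        model_name=family,
                        model_length=250,
                        seq_evalue=1e-40,
                        dom_evalue=10.0 ** -float(rng.uniform(15, 40)),
                        bit_score=own_score,
                        hmm_from=1,
                        hmm_to=250,
                        ali_from=1,
                        ali_to=min(250, prot_len),
                    )
                )
                other = fam_names[int(rng.integers(0, len(fam_names)))]
                if other != family:
                    hits.append(
                        DomainHit(
                            protein_id=gid,
                            model_name=other,
                            model_length=250,
                            seq_evalue=1e-20,
                            dom_evalue=1e-12,
                            bit_score=own_score - float(rng.uniform(30, 120)),
                            hmm_from=1,
                            hmm_to=250,
                            ali_from=1,
                            ali_to=min(250, prot_len),
                        )
                    )
                truth_kinases[gid] = {
                    "family": family,
                    "group": family.split("_", 1)[0],
                    "role": tok["role"],
                    "n_domains": n_dom,
                    "accepted": True,
                }
            else:
                mode = config.decoy_fail_mode or decoy_modes[int(rng.integers(0, 3))]
                if mode == "evalue":
                    hits.append(
                        DomainHit(
                            protein_id=gid,
                            model_name="Pkinase",
                            model_length=260,
                            seq_evalue=1e-2,
                            dom_evalue=1e-3,
                            bit_score=20.0,
                            hmm_from=1,
                            hmm_to=240,
                            ali_from=1,
                            ali_to=min(240, prot_len),
                        )
                    )
                elif mode == "coverage":
                    hits.append(
                        DomainHit(
                            protein_id=gid,
                            model_name="Pkinase",
                            model_length=260,
                            seq_evalue=1e-30,
                            dom_evalue=1e-20,
                            bit_score=80.0,
                            hmm_from=10,
                            hmm_to=109,  # 100/260 model coverage, below half
                            ali_from=1,
                            ali_to=min(100, prot_len),
                        )
                    )
                truth_decoys[gid] = {"fail_mode": mode}

    # ranks among all genes per chromosome, by start coordinate
    rank: dict[str, int] = {}
    for chrom in chroms:
        on_chrom = sorted(
            (g for g in genes if g.chrom == chrom), key=lambda g: g.start
        )
        for r, g in enumerate(on_chrom):
            rank[g.gene_id] = r

    anchors = []
    blocks_out = []
    for b, bt in enumerate(block_truth):
        pair_ids = [
            (id_of_token[ta["idx"]], id_of_token[tb["idx"]])
            for ta, tb in bt["pair_tokens"]
        ]
        for ga, gb in pair_ids:
            anchors.append(
                {
                    "gene_a": ga,
                    "gene_b": gb,
                    "chrom_a": bt["chrom_a"],
                    "chrom_b": bt["chrom_b"],
                    "rank_a": rank[ga],
                    "rank_b": rank[gb],
                }
            )
        blocks_out.append(
            {
                "block": b,
                "chrom_a": bt["chrom_a"],
                "chrom_b": bt["chrom_b"],
                "anchors": pair_ids,
            }
        )

    truth = {
        "kinases": truth_kinases,
        "decoys": truth_decoys,
        "tandem_arrays": [
            [id_of_token[i] for i in arr] for arr in truth_arrays
        ],
        "near_miss_pairs": (
            [[id_of_token[t["idx"]] for t in near_miss_tokens]]
            if near_miss_tokens
            else []
        ),
        "blocks": blocks_out,
        "anchors": anchors,
        "families": fam_names,
    }
    return GenomeSim(genes=genes, cds=cds, proteins=proteins, hits=hits, truth=truth)


def survey_scale_catalog(
    group_sizes: dict[str, int],
    n_scaffold: int = 0,
    domain_multiplicities: dict[int, int] | None = None,
    n_chromosomes: int = 25,
) -> list["KinaseRecord"]:
    """Synthetic catalog mirroring the headline counts of a kinome survey.

    Builds one :class:`KinaseRecord` per gene with the requested group
    sizes, scaffold tally and kinase-domain multiplicity histogram
    (genes not covered by ``domain_multiplicities`` carry one domain).
    Coordinates and intron counts are mechanical placeholders; the
    records exist so the catalog and duplication summarizers can be
    exercised at the scale of a published survey without its genome.
    """
    from .models import KinaseRecord

    total = sum(group_sizes.values())
    multi = []
    for k, count in sorted(domain_multiplicities.items()) if domain_multiplicities else []:
        multi.extend([k] * count)
    if len(multi) > total:
        raise ValueError("more multi-domain genes than genes")
    multi.extend([1] * (total - len(multi)))

    records = []
    i = 0
    for group in sorted(group_sizes):
        for _ in range(group_sizes[group]):
            if i < n_scaffold:
                chrom = f"scaffold_{i + 1}"
            else:
                chrom = f"chr{(i - n_scaffold) % n_chromosomes + 1}"
            family = group if group == "unclassified" else f"{group}_fam1"
            records.append(
                KinaseRecord(
                    gene_id=f"k{i + 1:05d}",
                    protein_id=f"k{i + 1:05d}",
                    family=family,
                    group=group,
                    n_kinase_domains=multi[i],
                    intron_count=0,
                    chrom=chrom,
                    start=1 + 10_000 * i,
                    end=5_000 + 10_000 * i,
                    strand="+",
                )
            )
            i += 1
    return records


# ---------------------------------------------------------------------------
# diverged CDS pairs
# ---------------------------------------------------------------------------

@dataclass
class CodonPairConfig:
    n_codons: int = 300
    target_ks: float = 0.3
    target_ka: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 30:
            raise ValueError("n_codons must be >= 30")
        if self.target_ks < 0 or self.target_ka < 0:
            raise ValueError("divergence targets must be non-negative")


@dataclass
class CdsPair:
    """A planted diverged CDS pair with its change bookkeeping."""

    cds_a: str
    cds_b: str
    n_syn_planted: int
    n_nonsyn_planted: int


def _inverse_jc(d: float) -> float:
    """Uncorrected proportion whose Jukes-Cantor distance equals d."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


@lru_cache(maxsize=None)
def _single_change_options(codon: str) -> tuple[list[str], list[str]]:
    """Sense single-base mutants of a codon, split syn/nonsyn."""
    aa = CODON_TO_AA[codon]
    syn, nonsyn = [], []
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in SENSE_CODONS:
                continue
            (syn if CODON_TO_AA[mutant] == aa else nonsyn).append(mutant)
    return syn, nonsyn


def gen_cds_pair(config: CodonPairConfig) -> CdsPair:
    """Derive a diverged partner CDS by placing codon changes.

    The number of synonymous (nonsynonymous) changes is chosen so the
    uncorrected NG86 proportions pS and pN match the Jukes-Cantor
    inverses of the Ks and Ka targets.  At most one change is placed per
    codon, each a single-base substitution, so planted changes map
    one-to-one onto NG86 difference counts; no stop codons are created.
    """
    rng = np.random.default_rng(config.seed)
    cds_a = _random_cds(rng, config.n_codons)
    codons = [cds_a[i : i + 3] for i in range(0, len(cds_a), 3)]
    s_total = sum(count_sites(c)[0] for c in codons)
    n_total = 3 * config.n_codons - s_total
    n_syn = int(round(_inverse_jc(config.target_ks) * s_total))
    n_nonsyn = int(round(_inverse_jc(config.target_ka) * n_total))

    syn_capable = [i for i, c in enumerate(codons) if _single_change_options(c)[0]]
    nonsyn_capable = [i for i, c in enumerate(codons) if _single_change_options(c)[1]]
    if n_syn > len(syn_capable):
        raise ValueError(
            f"target_ks={config.target_ks} needs {n_syn} synonymous changes "
            f"but only {len(syn_capable)} codons admit one"
        )
    rng.shuffle(syn_capable)
    syn_sites = set(syn_capable[:n_syn])
    nonsyn_pool = [i for i in nonsyn_capable if i not in syn_sites]
    if n_nonsyn > len(nonsyn_pool):
        raise ValueError(
            f"target_ka={config.target_ka} needs {n_nonsyn} nonsynonymous "
            f"changes but only {len(nonsyn_pool)} codons admit one"
        )
    rng.shuffle(nonsyn_pool)
    nonsyn_sites = set(nonsyn_pool[:n_nonsyn])

    out = list(codons)
    for i in sorted(syn_sites):
        options = _single_change_options(codons[i])[0]
        out[i] = options[int(rng.integers(0, len(options)))]
    for i in sorted(nonsyn_sites):
        options = _single_change_options(codons[i])[1]
        out[i] = options[int(rng.integers(0, len(options)))]
    return CdsPair(
        cds_a=cds_a,
        cds_b="".join(out),
        n_syn_planted=n_syn,
        n_nonsyn_planted=n_nonsyn,
    )


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSimConfig:
    n_genes: int = 200
    sample_labels: tuple[str, ...] = DEFAULT_TISSUES
    n_clusters: int = 5
    cluster_profiles: list[list[float]] | None = None
    noise_sd: float = 3.0
    frac_low_expressed: float = 0.2
    low_max_fpkm: float = 9.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_clusters <= 0:
            raise ValueError("n_genes and n_clusters must be positive")
        if not 0 <= self.frac_low_expressed <= 1:
            raise ValueError("frac_low_expressed must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.cluster_profiles is not None:
            if len(self.cluster_profiles) != self.n_clusters:
                raise ValueError("one profile per cluster required")
            for p in self.cluster_profiles:
                if len(p) != len(self.sample_labels):
                    raise ValueError("profiles need one value per sample")


@dataclass
class ExpressionSim:
    matrix: pd.DataFrame  # genes x samples, FPKM
    labels: dict[str, str]  # gene -> "low" or "cluster_<i>" (1-based)

    def write(self, path: str | Path) -> None:
        self.matrix.to_csv(path, sep="\t", index_label="gene")


def _default_profiles(n_clusters: int, n_samples: int) -> np.ndarray:
    """Well-separated block profiles: low baseline, high plateau."""
    profiles = np.full((n_clusters, n_samples), 4.0)
    width = max(1, n_samples // n_clusters)
    for c in range(n_clusters):
        lo = (c * width) % n_samples
        for w in range(width):
            profiles[c, (lo + w) % n_samples] = 90.0
    return profiles


def gen_expression(config: ExpressionSimConfig) -> ExpressionSim:
    """FPKM matrix with planted clusters and lowly-expressed genes.

    Lowly-expressed genes take uniform values below 10 in every sample;
    the remaining genes are split as evenly as possible over the
    clusters and drawn as profile + Gaussian noise, truncated at zero.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = len(config.sample_labels)
    profiles = (
        np.asarray(config.cluster_profiles, dtype=float)
        if config.cluster_profiles is not None
        else _default_profiles(config.n_clusters, n_samples)
    )
    n_low = int(round(config.frac_low_expressed * config.n_genes))
    n_expr = config.n_genes - n_low
    if n_expr and n_expr < config.n_clusters:
        raise ValueError("fewer expressed genes than clusters")

    rows = []
    labels: dict[str, str] = {}
    gene_ids = [f"gene{i + 1:05d}" for i in range(config.n_genes)]
    low_idx = set(rng.choice(config.n_genes, size=n_low, replace=False).tolist())
    expressed = [i for i in range(config.n_genes) if i not in low_idx]
    for j, i in enumerate(expressed):
        cluster = j % config.n_clusters
        labels[gene_ids[i]] = f"cluster_{cluster + 1}"
    for i in low_idx:
        labels[gene_ids[i]] = "low"

    matrix = np.zeros((config.n_genes, n_samples))
    for i in range(config.n_genes):
        if i in low_idx:
            matrix[i] = rng.uniform(0.0, config.low_max_fpkm, size=n_samples)
        else:
            cluster = int(labels[gene_ids[i]].split("_")[1]) - 1
            noise = rng.normal(0.0, config.noise_sd, size=n_samples) if config.noise_sd else 0.0
            matrix[i] = np.maximum(profiles[cluster] + noise, 0.0)
    frame = pd.DataFrame(matrix, index=gene_ids, columns=list(config.sample_labels))
    return ExpressionSim(matrix=frame, labels=labels)


# ---------------------------------------------------------------------------
# isoform fixtures
# ---------------------------------------------------------------------------

_BASE_EXONS = [(1, 100), (201, 300), (401, 500), (601, 700), (801, 900)]


def _alt_isoform(event: str, strand: str) -> list[tuple[int, int]]:
    exons = list(_BASE_EXONS)
    if event == "IR":
        return [(1, 300)] + exons[2:]
    if event == "ES":
        return [exons[0]] + exons[2:]
    if event == "AA":
        # differ at the intron's 3' (acceptor) end only
        if strand == "+":
            return [exons[0], (221, 300)] + exons[2:]
        return [(1, 80), (201, 300)] + exons[2:]
    if event == "AD":
        # differ at the intron's 5' (donor) end only
        if strand == "+":
            return [(1, 80), (201, 300)] + exons[2:]
        return [exons[0], (221, 300)] + exons[2:]
    if event == "complex":
        # intron differing at both boundaries
        return [(1, 80), (221, 300)] + exons[2:]
    raise ValueError(f"unknown AS event type: {event!r}")


def gen_isoforms(
    event_spec: Sequence[str],
    gene_id: str = "as_gene",
    strand: str = "+",
) -> Gene:
    """A gene whose isoforms exhibit exactly the requested AS events.

    ``event_spec`` draws from {IR, AA, AD, ES, complex}.  An empty spec
    yields two identical isoforms (no events); each requested event adds
    one alternative isoform relative to the shared base isoform, so two
    or more distinct event types aggregate to a gene-level "complex"
    call.
    """
    isoforms = [
        Transcript(
            transcript_id=f"{gene_id}.t0",
            gene_id=gene_id,
            strand=strand,
            exons=list(_BASE_EXONS),
            cds_length=500,
        )
    ]
    if not event_spec:
        isoforms.append(
            Transcript(
                transcript_id=f"{gene_id}.t1",
                gene_id=gene_id,
                strand=strand,
                exons=list(_BASE_EXONS),
                cds_length=500,
            )
        )
    for i, event in enumerate(event_spec, 1):
        isoforms.append(
            Transcript(
                transcript_id=f"{gene_id}.t{i}",
                gene_id=gene_id,
                strand=strand,
                exons=_alt_isoform(event, strand),
                cds_length=450,
            )
        )
    return Gene(
        gene_id=gene_id,
        chrom="chr1",
        start=1,
        end=900,
        strand=strand,
        transcripts=isoforms,
    )
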