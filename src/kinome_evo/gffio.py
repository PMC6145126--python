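"""GFF3 reading and writing for gene -> mRNA -> exon/CDS hierarchies.

Reading goes through :mod:`gffutils` (in-memory database); writing emits
plain 1-based inclusive GFF3 text.  Only the features the pipeline uses
(gene, mRNA, exon, CDS) are materialised.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, TextIO

import gffutils

from .models import Gene, Transcript

__all__ = ["read_gene_models", "write_gff3"]


def read_gene_models(source: str | Path) -> list[Gene]:
    """Load gene models from a GFF3 file into :class:`Gene` containers.

    Genes are returned sorted by (chrom, start).  Transcript CDS length
    is the summed length of CDS features; transcripts lacking CDS
    features fall back to summed exon length so a representative isoform
    is always defined.
    """
    db = gffutils.create_db(
        str(source),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[Gene] = []
    for gf in db.features_of_type("gene"):
        gene = Gene(
            gene_id=gf.id,
            chrom=gf.seqid,
            start=gf.start,
            end=gf.end,
            strand=gf.strand,
        )
        for tf in db.children(gf, featuretype="mRNA", order_by="start"):
            exons = [
                (ef.start, ef.end)
                for ef in db.children(tf, featuretype="exon", order_by="start")
            ]
            cds_len = sum(
                cf.end - cf.start + 1
                for cf in db.children(tf, featuretype="CDS")
            )
            if not exons:
                continue
            if cds_len == 0:
                cds_len = sum(e - s + 1 for s, e in exons)
            gene.transcripts.append(
                Transcript(
                    transcript_id=tf.id,
                    gene_id=gf.id,
                    strand=tf.strand,
                    exons=exons,
                    cds_length=cds_len,
                )
            )
        genes.append(gene)
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_gff3(genes: Iterable[Gene], handle: TextIO, source: str = "kinome_evo") -> None:
    """Write gene models as GFF3 (gene -> mRNA -> exon/CDS)."""
    handle.write("##gff-version 3\n")
    for gene in genes:
        handle.write(
            f"{gene.chrom}\t{source}\tgene\t{gene.start}\t{gene.end}\t.\t"
            f"{gene.strand}\t.\tID={gene.gene_id}\n"
        )
        for tx in gene.transcripts:
            ts, te = tx.span
            handle.write(
                f"{gene.chrom}\t{source}\tmRNA\t{ts}\t{te}\t.\t{tx.strand}\t.\t"
                f"ID={tx.transcript_id};Parent={gene.gene_id}\n"
            )
            for i, (es, ee) in enumerate(tx.exons, 1):
                handle.write(
                    f"{gene.chrom}\t{source}\texon\t{es}\t{ee}\t.\t{tx.strand}\t.\t"
                    f"ID={tx.transcript_id}.exon{i};Parent={tx.transcript_id}\n"
                )
                handle.write(
                    f"{gene.chrom}\t{source}\tCDS\t{es}\t{ee}\t.\t{tx.strand}\t0\t"
                    f"ID={tx.transcript_id}.cds{i};Parent={tx.transcript_id}\n"
                )
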