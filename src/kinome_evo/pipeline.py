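"""End-to-end orchestration: catalog -> duplication -> Ka/Ks, catalog ->
expression -> network, and splicing, from one config.

Each stage is a pure function of its inputs, the thresholds and the
seed; re-running an identical config over identical inputs reproduces
identical outputs.  All tabular outputs are TSV with header rows and the
run report is JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd
from Bio import SeqIO

from . import catalog as catalog_mod
from . import duplication as dup_mod
from . import expression as expr_mod
from . import kaks as kaks_mod
from . import network as net_mod
from . import splicing as splice_mod
from .gffio import read_gene_models

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run"]


@dataclass
class PipelineConfig:
    gff3: str | None = None
    hits: str | None = None
    cds_fasta: str | None = None
    anchors: str | None = None
    expression_matrix: str | None = None
    outdir: str = "kinome_out"

    run_catalog: bool = True
    run_duplication: bool = True
    run_kaks: bool = True
    run_splicing: bool = True
    run_expression: bool = True
    run_network: bool = True

    evalue_max: float = catalog_mod.DEFAULT_EVALUE_MAX
    min_model_coverage: float = catalog_mod.DEFAULT_MIN_COVERAGE
    max_intervening: int = dup_mod.DEFAULT_MAX_INTERVENING
    max_separation_bp: int = dup_mod.DEFAULT_MAX_SEPARATION_BP
    min_block: int = dup_mod.DEFAULT_MIN_BLOCK
    max_gap: int = dup_mod.DEFAULT_MAX_GAP
    ks_bin_width: float = 0.1
    fpkm_threshold: float = expr_mod.DEFAULT_FPKM_THRESHOLD
    k_clusters: int = expr_mod.DEFAULT_K
    n_restarts: int = 50
    cluster_on_log: bool = True
    min_abs_pcc: float = net_mod.DEFAULT_MIN_ABS_PCC
    alpha: float = net_mod.DEFAULT_ALPHA
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _read_anchor_table(path: str) -> list[dup_mod.AnchorPair]:
    frame = pd.read_csv(path, sep="\t")
    return [
        dup_mod.AnchorPair(
            gene_a=row.gene_a,
            gene_b=row.gene_b,
            chrom_a=row.chrom_a,
            chrom_b=row.chrom_b,
            rank_a=int(row.rank_a),
            rank_b=int(row.rank_b),
        )
        for row in frame.itertuples()
    ]


def run(config: PipelineConfig) -> dict[str, Any]:
    """Execute the enabled stages in dependency order; return the report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    genes = read_gene_models(config.gff3) if config.gff3 else []
    records: list = []

    if config.run_catalog:
        if not (config.gff3 and config.hits):
            raise ValueError("catalog stage requires --gff3 and --hits")
        with open(config.hits) as fh:
            hits = catalog_mod.parse_domain_hits(fh)
        records = catalog_mod.build_catalog(
            hits,
            genes,
            evalue_max=config.evalue_max,
            min_model_coverage=config.min_model_coverage,
        )
        frame = pd.DataFrame(
            [
                {
                    "gene": r.gene_id,
                    "family": r.family,
                    "group": r.group,
                    "n_kinase_domains": r.n_kinase_domains,
                    "introns": r.intron_count,
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "strand": r.strand,
                    "tie_flag": r.tie_flag,
                    "score_margin": r.score_margin,
                }
                for r in records
            ]
        )
        frame.to_csv(outdir / "catalog.tsv", sep="\t", index=False)
        summary = catalog_mod.summarize_catalog(records)
        pd.Series(summary.family_counts, name="n_genes").rename_axis("family").to_csv(
            outdir / "family_counts.tsv", sep="\t"
        )
        report["stages"]["catalog"] = {
            "n_kinases": summary.total,
            "n_families": len(
                [f for f in summary.family_counts if f != "unclassified"]
            ),
            "n_groups": len([g for g in summary.group_counts if g != "unclassified"]),
            "n_unclassified": summary.n_unclassified,
            "n_multidomain": summary.n_multidomain,
            "scaffold_genes": summary.scaffold_genes,
        }

    tandem_events: list = []
    blocks: list = []
    if config.run_duplication:
        if not records:
            raise ValueError("duplication stage requires the catalog stage")
        tandem_events, arrays = dup_mod.call_tandem(
            records,
            genes,
            max_intervening=config.max_intervening,
            max_separation_bp=config.max_separation_bp,
        )
        pd.DataFrame(
            [
                {
                    "gene_a": e.gene_a,
                    "gene_b": e.gene_b,
                    "chrom": e.chrom_a,
                    "intervening_genes": e.intervening_genes,
                    "separation_bp": e.separation_bp,
                }
                for e in tandem_events
            ]
        ).to_csv(outdir / "tandem_events.tsv", sep="\t", index=False)
        if config.anchors:
            anchors = _read_anchor_table(config.anchors)
            blocks = dup_mod.find_collinear_blocks(
                anchors, min_block=config.min_block, max_gap=config.max_gap
            )
            pd.DataFrame(
                [
                    {
                        "block_id": b.block_id,
                        "chrom_a": b.chrom_a,
                        "chrom_b": b.chrom_b,
                        "orientation": b.orientation,
                        "gene_a": a.gene_a,
                        "gene_b": a.gene_b,
                    }
                    for b in blocks
                    for a in b.anchors
                ]
            ).to_csv(outdir / "collinear_blocks.tsv", sep="\t", index=False)
        origins = dup_mod.classify_duplication(records, tandem_events, blocks)
        pd.Series(origins, name="origin").rename_axis("gene").to_csv(
            outdir / "duplication_origin.tsv", sep="\t"
        )
        report["stages"]["duplication"] = {
            "n_tandem_pairs": len(tandem_events),
            "n_tandem_arrays": len(arrays),
            "n_tandem_genes": len({g for e in tandem_events for g in (e.gene_a, e.gene_b)}),
            "n_blocks": len(blocks),
            "n_segmental_genes": sum(1 for v in origins.values() if v in ("segmental", "both")),
        }

    if config.run_kaks:
        if not config.cds_fasta:
            raise ValueError("kaks stage requires --cds-fasta")
        cds = {
            rec.id: str(rec.seq)
            for rec in SeqIO.parse(config.cds_fasta, "fasta")
        }
        pairs: list[tuple[str, str, str]] = [
            ("tandem", e.gene_a, e.gene_b) for e in tandem_events
        ] + [
            ("segmental", a.gene_a, a.gene_b)
            for b in blocks
            for a in b.anchors
        ]
        results = []
        rows = []
        for kind, ga, gb in pairs:
            if ga not in cds or gb not in cds:
                logger.warning("missing CDS for pair %s-%s; skipped", ga, gb)
                continue
            res = kaks_mod.kaks(cds[ga], cds[gb], gene_a=ga, gene_b=gb)
            results.append(res)
            rows.append(
                {
                    "kind": kind,
                    "gene_a": ga,
                    "gene_b": gb,
                    "Ka": res.ka,
                    "Ks": res.ks,
                    "Ka_Ks": res.ratio,
                    "selection": res.selection,
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "kaks.tsv", sep="\t", index=False)
        hist = kaks_mod.ks_histogram(results, bin_width=config.ks_bin_width)
        pd.DataFrame(
            [
                {"bin": hist.bin_label(idx), "count": count}
                for idx, count in hist.counts.items()
            ]
        ).to_csv(outdir / "ks_histogram.tsv", sep="\t", index=False)
        from collections import Counter

        report["stages"]["kaks"] = {
            "n_pairs": len(results),
            "selection": dict(Counter(r.selection for r in results)),
            "ks_peak_bins": [hist.bin_label(b) for b in hist.peak_bins],
        }

    if config.run_splicing:
        if not genes:
            raise ValueError("splicing stage requires --gff3")
        calls = [splice_mod.classify_gene(g) for g in genes if g.transcripts]
        pd.DataFrame(
            [{"gene": c.gene_id, "category": c.category} for c in calls]
        ).to_csv(outdir / "as_genes.tsv", sep="\t", index=False)
        summary = splice_mod.as_summary(calls)
        report["stages"]["splicing"] = {
            "n_genes": len(calls),
            "n_as_genes": sum(1 for c in calls if c.category != "none"),
            "proportions_pct": summary,
        }

    matrix = None
    if config.run_expression or config.run_network:
        if not config.expression_matrix:
            raise ValueError("expression stages require --matrix")
        matrix = pd.read_csv(config.expression_matrix, sep="\t", index_col=0)

    clustered_input = None
    if config.run_expression:
        retained, filtered = expr_mod.filter_low_expression(
            matrix, config.fpkm_threshold
        )
        logged = expr_mod.log_transform(retained)
        clustered_input = logged if config.cluster_on_log else retained
        assignment = expr_mod.kmeans_pearson(
            clustered_input,
            k=min(config.k_clusters, max(1, len(clustered_input))),
            n_restarts=config.n_restarts,
            seed=config.seed,
        )
        assignment.labels.rename_axis("gene").to_csv(
            outdir / "clusters.tsv", sep="\t"
        )
        sizes = assignment.labels.value_counts().sort_index()
        report["stages"]["expression"] = {
            "n_input_genes": int(len(matrix)),
            "n_filtered_low": len(filtered),
            "n_clustered": int(len(assignment.labels)),
            "cluster_sizes": {int(k): int(v) for k, v in sizes.items()},
            "objective": assignment.objective,
        }

    if config.run_network:
        net_input = expr_mod.log_transform(
            expr_mod.filter_low_expression(matrix, config.fpkm_threshold)[0]
        )
        edges = net_mod.build_network(
            net_input, min_abs_pcc=config.min_abs_pcc, alpha=config.alpha
        )
        pd.DataFrame(
            [
                {
                    "node_a": e.node_a,
                    "node_b": e.node_b,
                    "r": e.r,
                    "p": e.p,
                    "sign": e.sign,
                }
                for e in edges
            ]
        ).to_csv(outdir / "edges.tsv", sep="\t", index=False)
        degrees, components = net_mod.degree_and_components(edges)
        pd.Series(degrees, name="degree").rename_axis("node").to_csv(
            outdir / "degrees.tsv", sep="\t"
        )
        report["stages"]["network"] = {
            "n_nodes": len(degrees),
            "n_edges": len(edges),
            "n_components": len(components),
            "component_sizes": sorted((len(c) for c in components), reverse=True),
        }

    with (outdir / "report.json").open("w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
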