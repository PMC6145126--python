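"""Kinase identification and classification from profile-HMM hit tables.

A protein is called a kinase when at least one hit of a catalytic model
(Pkinase / Pkinase_Tyr by default) survives two filters: a per-domain
independent E-value strictly below 1e-5 and an alignment covering at
least half of the HMM model length.  Family assignment takes the
best-scoring accepted family-model hit; its group is the family-name
prefix (e.g. ``RLK-Pelle_DLSV`` -> ``RLK-Pelle``).  Proteins with no
accepted family hit are carried as "unclassified".

Structural summaries follow the catalog: per-family/group/chromosome
counts, kinase-domain multiplicity after merging split alignments, and
intron counts from the representative (longest-CDS) transcript.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

from .models import Gene, KinaseRecord

logger = logging.getLogger(__name__)

__all__ = [
    "DomainHit",
    "CatalogSummary",
    "CATALYTIC_MODELS",
    "DEFAULT_EVALUE_MAX",
    "DEFAULT_MIN_COVERAGE",
    "parse_domain_hits",
    "filter_kinase_hits",
    "assign_family",
    "count_kinase_domains",
    "count_introns",
    "build_catalog",
    "summarize_catalog",
]

#: catalytic (kinase-domain) model names; all other models are family models
CATALYTIC_MODELS = frozenset({"Pkinase", "Pkinase_Tyr"})
DEFAULT_EVALUE_MAX = 1e-5
DEFAULT_MIN_COVERAGE = 0.5

_COLUMNS = (
    "target_name",
    "query_model",
    "model_length",
    "seq_evalue",
    "dom_evalue",
    "bit_score",
    "hmm_from",
    "hmm_to",
    "ali_from",
    "ali_to",
)


@dataclass(frozen=True)
class DomainHit:
    """One domain alignment of a profile HMM to a protein."""

    protein_id: str
    model_name: str
    model_length: int
    seq_evalue: float
    dom_evalue: float
    bit_score: float
    hmm_from: int
    hmm_to: int
    ali_from: int
    ali_to: int

    def __post_init__(self) -> None:
        if not (1 <= self.hmm_from <= self.hmm_to <= self.model_length):
            raise ValueError(
                f"{self.protein_id}/{self.model_name}: hmm coordinates "
                f"{self.hmm_from}-{self.hmm_to} outside model length {self.model_length}"
            )
        if self.ali_from > self.ali_to:
            raise ValueError(f"{self.protein_id}: ali_from > ali_to")
        if self.seq_evalue < 0 or self.dom_evalue < 0:
            raise ValueError("E-values must be non-negative")

    @property
    def model_coverage(self) -> float:
        return (self.hmm_to - self.hmm_from + 1) / self.model_length


def parse_domain_hits(stream: TextIO) -> list[DomainHit]:
    """Parse a whitespace-delimited per-domain hit table.

    Expects the ten columns emitted by common profile-HMM search tools
    in domtblout style: target name, query model, model length,
    full-sequence E-value, per-domain independent E-value, bit score,
    hmm from/to, ali from/to.  ``#`` comment lines are skipped; rows
    violating coordinate invariants are dropped with a logged warning
    naming the line.
    """
    hits: list[DomainHit] = []
    for lineno, raw in enumerate(stream, 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < len(_COLUMNS):
            raise ValueError(
                f"line {lineno}: expected {len(_COLUMNS)} columns "
                f"({', '.join(_COLUMNS)}), got {len(fields)}"
            )
        try:
            hit = DomainHit(
                protein_id=fields[0],
                model_name=fields[1],
                model_length=int(fields[2]),
                seq_evalue=float(fields[3]),
                dom_evalue=float(fields[4]),
                bit_score=float(fields[5]),
                hmm_from=int(fields[6]),
                hmm_to=int(fields[7]),
                ali_from=int(fields[8]),
                ali_to=int(fields[9]),
            )
        except ValueError as exc:
            logger.warning("rejected hit table row at line %d: %s", lineno, exc)
            continue
        hits.append(hit)
    return hits


def filter_kinase_hits(
    hits: Iterable[DomainHit],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    min_model_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[DomainHit]:
    """Keep hits passing the E-value and model-coverage filters.

    Acceptance requires dom_evalue strictly below ``evalue_max`` and
    (hmm_to - hmm_from + 1) / model_length of at least
    ``min_model_coverage`` (inclusive: a hit covering exactly half the
    model passes the default filter; a hit at exactly the E-value cutoff
    does not).
    """
    if evalue_max <= 0:
        raise ValueError("evalue_max must be positive")
    if not (0 < min_model_coverage <= 1):
        raise ValueError("min_model_coverage must be in (0, 1]")
    return [
        h
        for h in hits
        if h.dom_evalue < evalue_max and h.model_coverage >= min_model_coverage
    ]


def assign_family(
    family_hits: Sequence[DomainHit],
) -> tuple[str, str, bool, float | None]:
    """Assign (family, group) from accepted family-model hits of one protein.

    Returns ``(family, group, tie_flag, score_margin)``.  The family is
    the model with the highest bit score; exact ties are broken by
    lexicographic model name and flagged so they can be re-examined.
    ``score_margin`` is the bit-score gap to the runner-up family (None
    with a single candidate).  No hits -> ("unclassified",
    "unclassified", False, None).
    """
    if not family_hits:
        return "unclassified", "unclassified", False, None
    best_by_family: dict[str, float] = {}
    for hit in family_hits:
        prev = best_by_family.get(hit.model_name)
        if prev is None or hit.bit_score > prev:
            best_by_family[hit.model_name] = hit.bit_score
    ranked = sorted(best_by_family.items(), key=lambda kv: (-kv[1], kv[0]))
    family, top = ranked[0]
    tie = len(ranked) > 1 and ranked[1][1] == top
    margin = top - ranked[1][1] if len(ranked) > 1 else None
    group = family.split("_", 1)[0]
    return family, group, tie, margin


def count_kinase_domains(accepted_catalytic_hits: Sequence[DomainHit]) -> int:
    """Number of distinct kinase domains among one protein's accepted hits.

    Hits are merged when their protein-coordinate overlap exceeds 50% of
    the shorter hit, so split alignments of one physical domain are not
    double-counted; the merged interval count is returned.
    """
    intervals = sorted(
        (h.ali_from, h.ali_to) for h in accepted_catalytic_hits
    )
    merged: list[list[int]] = []
    for start, end in intervals:
        if merged:
            ms, me = merged[-1]
            overlap = min(me, end) - max(ms, start) + 1
            shorter = min(me - ms + 1, end - start + 1)
            if overlap > 0.5 * shorter:
                merged[-1][1] = max(me, end)
                continue
        merged.append([start, end])
    return len(merged)


def count_introns(gene: Gene) -> int:
    """Intron count of the gene's representative (longest-CDS) transcript."""
    rep = gene.representative()
    if rep.n_exons == 0:
        raise ValueError(f"{gene.gene_id}: representative transcript has no exons")
    return rep.n_exons - 1


def build_catalog(
    hits: Sequence[DomainHit],
    genes: Sequence[Gene],
    *,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    min_model_coverage: float = DEFAULT_MIN_COVERAGE,
    catalytic_models: frozenset[str] = CATALYTIC_MODELS,
    protein_to_gene: Mapping[str, str] | None = None,
) -> list[KinaseRecord]:
    """Assemble the kinome catalog from a hit table and gene models.

    A gene enters the catalog iff its protein has >=1 accepted catalytic
    hit.  Protein ids default to gene ids unless ``protein_to_gene``
    maps them explicitly.
    """
    accepted = filter_kinase_hits(hits, evalue_max, min_model_coverage)
    by_protein: dict[str, list[DomainHit]] = defaultdict(list)
    for hit in accepted:
        by_protein[hit.protein_id].append(hit)
    gene_index = {g.gene_id: g for g in genes}
    records: list[KinaseRecord] = []
    for protein_id in sorted(by_protein):
        phits = by_protein[protein_id]
        catalytic = [h for h in phits if h.model_name in catalytic_models]
        if not catalytic:
            continue
        gene_id = (
            protein_to_gene[protein_id] if protein_to_gene else protein_id
        )
        gene = gene_index.get(gene_id)
        if gene is None:
            logger.warning("kinase protein %s has no gene model; skipped", protein_id)
            continue
        family, group, tie, margin = assign_family(
            [h for h in phits if h.model_name not in catalytic_models]
        )
        records.append(
            KinaseRecord(
                gene_id=gene_id,
                protein_id=protein_id,
                family=family,
                group=group,
                n_kinase_domains=count_kinase_domains(catalytic),
                intron_count=count_introns(gene),
                chrom=gene.chrom,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                tie_flag=tie,
                score_margin=margin,
            )
        )
    return records


def _is_scaffold(chrom: str) -> bool:
    return chrom.lower().startswith(("scaffold", "contig", "unplaced"))


@dataclass
class CatalogSummary:
    """Aggregate counts over a kinome catalog."""

    total: int
    family_counts: dict[str, int]
    group_counts: dict[str, int]
    chromosome_counts: dict[str, int]
    scaffold_genes: int
    domain_multiplicity: dict[int, int]
    n_unclassified: int = 0

    @property
    def n_chromosome_genes(self) -> int:
        return sum(self.chromosome_counts.values())

    @property
    def n_multidomain(self) -> int:
        return sum(v for k, v in self.domain_multiplicity.items() if k >= 2)

    def group_share_pct(self, group: str) -> float:
        """Percentage of catalog genes in ``group`` (of the full catalog)."""
        if self.total == 0:
            raise ValueError("empty catalog")
        return 100.0 * self.group_counts.get(group, 0) / self.total

    def share_of_genome_pct(self, n_genome_genes: int) -> float:
        """Catalog size as a percentage of the annotated gene count."""
        if n_genome_genes <= 0:
            raise ValueError("genome gene count must be positive")
        return 100.0 * self.total / n_genome_genes


def summarize_catalog(records: Sequence[KinaseRecord]) -> CatalogSummary:
    """Per-family/group/chromosome counts and domain-multiplicity histogram.

    Genes on scaffold/contig sequences are tallied separately from
    chromosome-anchored genes; family counts include the unclassified
    bucket so totals are conserved.
    """
    families = Counter(r.family for r in records)
    groups = Counter(r.group for r in records)
    chroms: Counter[str] = Counter()
    scaffold = 0
    for r in records:
        if _is_scaffold(r.chrom):
            scaffold += 1
        else:
            chroms[r.chrom] += 1
    multiplicity = Counter(r.n_kinase_domains for r in records)
    return CatalogSummary(
        total=len(records),
        family_counts=dict(sorted(families.items())),
        group_counts=dict(sorted(groups.items())),
        chromosome_counts=dict(sorted(chroms.items())),
        scaffold_genes=scaffold,
        domain_multiplicity=dict(sorted(multiplicity.items())),
        n_unclassified=families.get("unclassified", 0),
    )
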