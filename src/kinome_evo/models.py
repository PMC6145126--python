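"""Shared containers for gene/transcript models and catalog records.

Coordinates are 1-based inclusive genomic positions throughout, matching
GFF3 convention; exon lists are kept sorted by start and must not
overlap within a transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field

Interval = tuple[int, int]


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    strand: str
    exons: list[Interval] = field(default_factory=list)
    cds_length: int = 0

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons ({s1},{e1}) and ({s2},{e2})"
                )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> Interval:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    def representative(self) -> Transcript:
        """Longest-CDS transcript (ties by transcript id)."""
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: gene has no transcripts")
        return max(self.transcripts, key=lambda t: (t.cds_length, t.transcript_id))


@dataclass
class KinaseRecord:
    """One classified kinase gene, a row of the kinome catalog."""

    gene_id: str
    protein_id: str
    family: str
    group: str
    n_kinase_domains: int
    intron_count: int
    chrom: str
    start: int
    end: int
    strand: str
    tie_flag: bool = False
    score_margin: float | None = None

    def __post_init__(self) -> None:
        if self.family == "unclassified" and self.group != "unclassified":
            raise ValueError("unclassified family requires unclassified group")
        if self.n_kinase_domains < 1:
            raise ValueError("catalog records require >=1 accepted kinase domain")
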