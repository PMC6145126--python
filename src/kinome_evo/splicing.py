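"""Alternative-splicing event classification from transcript models.

Events are called between isoform pairs by comparing intron chains in
genomic coordinates (donor = 5' intron boundary, acceptor = 3', resolved
by strand):

* intron retention (IR): an intron of one isoform lies entirely within
  an exon of the other;
* alternative acceptor (AA): overlapping introns sharing the donor
  boundary but not the acceptor;
* alternative donor (AD): sharing the acceptor but not the donor;
* exon skipping (ES): an exon of one isoform falls strictly inside a
  single intron of the other while both flanking exon junctions are
  shared;
* anything else that changes the intron chain contributes to the
  "complex" category.

A gene showing exactly one elementary type is labelled with it; two or
more distinct types, or any unclassifiable difference, make the gene
"complex"; identical intron chains (UTR-only differences included) give
"none".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .models import Gene, Interval, Transcript

__all__ = [
    "ASEvent",
    "GeneASCall",
    "ELEMENTARY_TYPES",
    "GENE_CATEGORIES",
    "introns_of",
    "classify_pair_events",
    "classify_gene",
    "as_summary",
]

ELEMENTARY_TYPES = ("intron_retention", "alt_acceptor", "alt_donor", "exon_skipping")
#: elementary type -> gene-level category label
_CATEGORY_OF = {
    "intron_retention": "IR",
    "alt_acceptor": "AA",
    "alt_donor": "AD",
    "exon_skipping": "ES",
    "complex": "complex",
}
GENE_CATEGORIES = ("IR", "AA", "AD", "ES", "complex", "none")


@dataclass(frozen=True)
class ASEvent:
    gene_id: str
    isoform_a: str
    isoform_b: str
    type: str  # one of ELEMENTARY_TYPES, or "complex" for unclassifiable diffs
    coordinates: tuple[Interval, ...]
    strand: str

    @property
    def key(self) -> tuple[str, tuple[Interval, ...]]:
        """Identity of the event irrespective of isoform-pair direction."""
        return self.type, self.coordinates


@dataclass
class GeneASCall:
    gene_id: str
    events: list[ASEvent]
    category: str  # IR | AA | AD | ES | complex | none


def introns_of(transcript: Transcript) -> list[Interval]:
    """Intron intervals (gaps between consecutive exons), sorted by start."""
    exons = transcript.exons
    return [
        (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(exons, exons[1:])
    ]


def donor_acceptor(intron: Interval, strand: str) -> tuple[int, int]:
    """(donor, acceptor) genomic positions of an intron, strand-resolved."""
    start, end = intron
    return (start, end) if strand == "+" else (end, start)


def _overlaps(a: Interval, b: Interval) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _within(inner: Interval, outer: Interval) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def classify_pair_events(iso_a: Transcript, iso_b: Transcript) -> list[ASEvent]:
    """Elementary AS events between two isoforms of one gene.

    Events are detected on the introns unique to either isoform, in the
    order ES, IR, AA/AD; unique introns left unexplained yield a
    "complex" event.  The result is symmetric in argument order (the
    direction is only metadata).
    """
    if iso_a.gene_id != iso_b.gene_id:
        raise ValueError("isoforms belong to different genes")
    if iso_a.strand != iso_b.strand:
        raise ValueError("isoforms on different strands")
    strand = iso_a.strand
    gene_id = iso_a.gene_id
    # canonical orientation so (a, b) and (b, a) give identical events
    if iso_b.transcript_id < iso_a.transcript_id:
        iso_a, iso_b = iso_b, iso_a

    introns_a = introns_of(iso_a)
    introns_b = introns_of(iso_b)
    set_a, set_b = set(introns_a), set(introns_b)
    unique = {
        "a": [i for i in introns_a if i not in set_b],
        "b": [i for i in introns_b if i not in set_a],
    }
    explained = {"a": set(), "b": set()}
    events: list[ASEvent] = []

    def emit(ev_type: str, coords: Iterable[Interval]) -> None:
        events.append(
            ASEvent(
                gene_id=gene_id,
                isoform_a=iso_a.transcript_id,
                isoform_b=iso_b.transcript_id,
                type=ev_type,
                coordinates=tuple(sorted(coords)),
                strand=strand,
            )
        )

    isoforms = {"a": iso_a, "b": iso_b}
    intron_lists = {"a": introns_a, "b": introns_b}

    # exon skipping: exon of X strictly inside one intron of Y whose
    # boundaries coincide with X's flanking introns
    for x, y in (("a", "b"), ("b", "a")):
        iso_x = isoforms[x]
        introns_x = intron_lists[x]
        for k, exon in enumerate(iso_x.exons[1:-1], start=1):
            left = introns_x[k - 1]
            right = introns_x[k]
            for intron_y in intron_lists[y]:
                if (
                    _within(exon, (intron_y[0] + 1, intron_y[1] - 1))
                    and intron_y[0] == left[0]
                    and intron_y[1] == right[1]
                ):
                    emit("exon_skipping", [exon])
                    explained[x].update((left, right))
                    explained[y].add(intron_y)

    # intron retention: unique intron of X contained in an exon of Y
    for x, y in (("a", "b"), ("b", "a")):
        for intron in unique[x]:
            if intron in explained[x]:
                continue
            if any(_within(intron, exon) for exon in isoforms[y].exons):
                emit("intron_retention", [intron])
                explained[x].add(intron)

    # alternative donor / acceptor between overlapping unique introns
    for ia in unique["a"]:
        if ia in explained["a"]:
            continue
        for ib in unique["b"]:
            if ib in explained["b"] or not _overlaps(ia, ib):
                continue
            donor_a, acc_a = donor_acceptor(ia, strand)
            donor_b, acc_b = donor_acceptor(ib, strand)
            if donor_a == donor_b and acc_a != acc_b:
                emit("alt_acceptor", [ia, ib])
            elif acc_a == acc_b and donor_a != donor_b:
                emit("alt_donor", [ia, ib])
            else:
                # overlapping introns differing at both boundaries
                emit("complex", [ia, ib])
            explained["a"].add(ia)
            explained["b"].add(ib)
            break

    leftovers = [
        i for x in ("a", "b") for i in unique[x] if i not in explained[x]
    ]
    if leftovers:
        emit("complex", leftovers)
    return events


def classify_gene(gene: Gene) -> GeneASCall:
    """Gene-level AS category from all pairwise isoform comparisons.

    The event set is the union over isoform pairs (deduplicated by type
    and coordinates).  One elementary type -> that category; several, or
    any complex event -> "complex"; no events (including single-isoform
    genes) -> "none".
    """
    events: list[ASEvent] = []
    seen: set[tuple] = set()
    isoforms = sorted(gene.transcripts, key=lambda t: t.transcript_id)
    for i in range(len(isoforms)):
        for j in range(i + 1, len(isoforms)):
            for ev in classify_pair_events(isoforms[i], isoforms[j]):
                if ev.key not in seen:
                    seen.add(ev.key)
                    events.append(ev)
    types = {ev.type for ev in events}
    if not types:
        category = "none"
    elif "complex" in types or len(types) > 1:
        category = "complex"
    else:
        category = _CATEGORY_OF[types.pop()]
    return GeneASCall(gene_id=gene.gene_id, events=events, category=category)


def as_summary(calls: Sequence[GeneASCall]) -> dict[str, float]:
    """Category proportions (%) among genes with at least one AS event."""
    as_calls = [c for c in calls if c.category != "none"]
    if not as_calls:
        return {}
    counts = Counter(c.category for c in as_calls)
    total = len(as_calls)
    return {
        cat: 100.0 * counts[cat] / total
        for cat in GENE_CATEGORIES
        if cat != "none" and counts.get(cat)
    }
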