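"""Tandem and segmental duplication detection.

Tandem duplicates: two genes of the same family on one chromosome
separated by at most five intervening annotated genes (of any kind, not
only kinases) and by strictly less than 100 kb between their nearest
boundaries.  Arrays are connected components of the pairwise tandem
relation.

Segmental duplicates: members of collinear blocks — maximal chains of
homologous anchor pairs whose per-chromosome gene ranks are monotone on
both chromosomes (same or inverted orientation), allowing rank gaps up
to 25 and requiring at least 5 anchors, mirroring the documented
defaults of standard collinearity scanners.  Anchor homology is an
upstream input (a similarity table for real data, truth labels for
synthetic genomes).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .models import Gene, KinaseRecord

logger = logging.getLogger(__name__)

__all__ = [
    "DuplicationEvent",
    "CollinearBlock",
    "AnchorPair",
    "call_tandem",
    "find_collinear_blocks",
    "classify_duplication",
    "DEFAULT_MAX_INTERVENING",
    "DEFAULT_MAX_SEPARATION_BP",
    "DEFAULT_MIN_BLOCK",
    "DEFAULT_MAX_GAP",
]

DEFAULT_MAX_INTERVENING = 5
DEFAULT_MAX_SEPARATION_BP = 100_000
DEFAULT_MIN_BLOCK = 5
DEFAULT_MAX_GAP = 25


@dataclass(frozen=True)
class DuplicationEvent:
    kind: str  # tandem | segmental
    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    intervening_genes: int | None = None
    separation_bp: int | None = None
    block_id: str | None = None

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("self-pair is not a duplication event")
        if self.gene_a > self.gene_b:
            raise ValueError("pairs must be stored in sorted order")


@dataclass(frozen=True)
class AnchorPair:
    """A homologous gene pair with per-chromosome positional ranks."""

    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int


@dataclass
class CollinearBlock:
    block_id: str
    chrom_a: str
    chrom_b: str
    orientation: str  # same | inverted
    anchors: list[AnchorPair]


def call_tandem(
    kinases: Sequence[KinaseRecord],
    all_genes: Sequence[Gene],
    max_intervening: int = DEFAULT_MAX_INTERVENING,
    max_separation_bp: int = DEFAULT_MAX_SEPARATION_BP,
) -> tuple[list[DuplicationEvent], list[list[str]]]:
    """Call tandem duplicate pairs and arrays among catalogued kinases.

    ``all_genes`` must contain every annotated gene so intervening
    neighbours are counted over the whole annotation.  Returns the event
    list (canonically ordered pairs) and the arrays, i.e. connected
    components of the tandem relation, each sorted by position.

    Both thresholds follow their wording: *at most* ``max_intervening``
    genes between the pair (inclusive) and a boundary-to-boundary gap
    *strictly below* ``max_separation_bp``.
    """
    order: dict[str, list[Gene]] = defaultdict(list)
    for g in sorted(all_genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
        order[g.chrom].append(g)
    rank: dict[str, int] = {}
    gene_by_id: dict[str, Gene] = {}
    for chrom_genes in order.values():
        for i, g in enumerate(chrom_genes):
            rank[g.gene_id] = i
            gene_by_id[g.gene_id] = g

    by_family_chrom: dict[tuple[str, str], list[KinaseRecord]] = defaultdict(list)
    for rec in kinases:
        if rec.family == "unclassified":
            continue
        if rec.gene_id not in rank:
            logger.warning(
                "kinase %s missing from the gene annotation; excluded from "
                "tandem calling",
                rec.gene_id,
            )
            continue
        by_family_chrom[(rec.family, rec.chrom)].append(rec)

    events: list[DuplicationEvent] = []
    graph = nx.Graph()
    for (family, chrom), members in sorted(by_family_chrom.items()):
        members = sorted(members, key=lambda r: (r.start, r.gene_id))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                intervening = abs(rank[b.gene_id] - rank[a.gene_id]) - 1
                upstream, downstream = (a, b) if a.start <= b.start else (b, a)
                separation = max(0, downstream.start - upstream.end)
                if intervening <= max_intervening and separation < max_separation_bp:
                    ga, gb = sorted((a.gene_id, b.gene_id))
                    events.append(
                        DuplicationEvent(
                            kind="tandem",
                            gene_a=ga,
                            gene_b=gb,
                            chrom_a=chrom,
                            chrom_b=chrom,
                            intervening_genes=intervening,
                            separation_bp=separation,
                        )
                    )
                    graph.add_edge(ga, gb)
    arrays = [
        sorted(component, key=lambda gid: (rank[gid], gid))
        for component in nx.connected_components(graph)
    ]
    arrays.sort(key=lambda arr: (gene_by_id[arr[0]].chrom, rank[arr[0]]))
    events.sort(key=lambda e: (e.chrom_a, e.gene_a, e.gene_b))
    return events, arrays


def _best_chain(
    anchors: list[AnchorPair], direction: int, max_gap: int
) -> list[int]:
    """Longest monotone chain by DP; ``direction`` +1 rising, -1 falling rank_b.

    Chains must rise in rank_a and rise (or fall) in rank_b with both
    rank gaps at most ``max_gap``.  Ties in length prefer the chain with
    the smaller combined rank span.
    """
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i].rank_a, anchors[i].rank_b))
    best_len = [1] * len(order)
    best_span = [0] * len(order)
    parent = [-1] * len(order)
    for oi, i in enumerate(order):
        for oj in range(oi):
            j = order[oj]
            da = anchors[i].rank_a - anchors[j].rank_a
            db = direction * (anchors[i].rank_b - anchors[j].rank_b)
            if da <= 0 or db <= 0 or da > max_gap or db > max_gap:
                continue
            cand_len = best_len[oj] + 1
            cand_span = best_span[oj] + da + db
            if cand_len > best_len[oi] or (
                cand_len == best_len[oi]
                and parent[oi] != -1
                and cand_span < best_span[oi]
            ):
                best_len[oi] = cand_len
                best_span[oi] = cand_span
                parent[oi] = oj
    end = max(
        range(len(order)), key=lambda oi: (best_len[oi], -best_span[oi])
    )
    chain: list[int] = []
    oi = end
    while oi != -1:
        chain.append(order[oi])
        oi = parent[oi]
    chain.reverse()
    return chain


def find_collinear_blocks(
    anchors: Sequence[AnchorPair],
    min_block: int = DEFAULT_MIN_BLOCK,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[CollinearBlock]:
    """Chain anchors into collinear blocks, greedily by chain score.

    Within each chromosome pair, the longest monotone chain (same or
    inverted orientation; ties broken toward the smaller rank span) is
    extracted, its anchors retired, and the search repeated until no
    chain reaches ``min_block`` anchors.  Each anchor belongs to at most
    one block.
    """
    if min_block < 2:
        raise ValueError("min_block must be at least 2")
    by_chrom_pair: dict[tuple[str, str], list[AnchorPair]] = defaultdict(list)
    for a in anchors:
        by_chrom_pair[(a.chrom_a, a.chrom_b)].append(a)

    blocks: list[CollinearBlock] = []
    counter = 0
    for (ca, cb), pool in sorted(by_chrom_pair.items()):
        pool = sorted(pool, key=lambda a: (a.rank_a, a.rank_b))
        while len(pool) >= min_block:
            candidates = []
            for direction, orientation in ((1, "same"), (-1, "inverted")):
                chain_idx = _best_chain(pool, direction, max_gap)
                chain = [pool[i] for i in chain_idx]
                span = (
                    chain[-1].rank_a - chain[0].rank_a
                    + abs(chain[-1].rank_b - chain[0].rank_b)
                )
                candidates.append((len(chain), -span, orientation, chain_idx))
            candidates.sort(key=lambda c: (c[0], c[1]), reverse=True)
            length, _, orientation, chain_idx = candidates[0]
            if length < min_block:
                break
            counter += 1
            chain = [pool[i] for i in chain_idx]
            blocks.append(
                CollinearBlock(
                    block_id=f"block_{counter}",
                    chrom_a=ca,
                    chrom_b=cb,
                    orientation=orientation,
                    anchors=chain,
                )
            )
            used = set(chain_idx)
            pool = [a for i, a in enumerate(pool) if i not in used]
    return blocks


def classify_duplication(
    kinases: Sequence[KinaseRecord],
    tandem_events: Sequence[DuplicationEvent],
    blocks: Sequence[CollinearBlock],
) -> dict[str, str]:
    """Per-gene duplication origin: tandem, segmental, both or none."""
    tandem_genes = {g for e in tandem_events for g in (e.gene_a, e.gene_b)}
    segmental_genes = {
        g for b in blocks for a in b.anchors for g in (a.gene_a, a.gene_b)
    }
    labels: dict[str, str] = {}
    for rec in kinases:
        t = rec.gene_id in tandem_genes
        s = rec.gene_id in segmental_genes
        labels[rec.gene_id] = (
            "both" if t and s else "tandem" if t else "segmental" if s else "none"
        )
    return labels
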