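"""Independent reference implementations used only to cross-check the
package.  Coded directly from first principles (Biopython translation,
exhaustive enumeration) and kept free of any package internals.
"""

from __future__ import annotations

import itertools
import math

from Bio.Seq import Seq

BASES = "ACGT"


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


def is_stop(codon: str) -> bool:
    return translate(codon) == "*"


def ref_sites(codon: str) -> tuple[float, float]:
    """Fraction of single-base neighbours that are synonymous, per position."""
    aa = translate(codon)
    syn_total = 0.0
    for pos in range(3):
        neighbours = [
            codon[:pos] + b + codon[pos + 1 :]
            for b in BASES
            if b != codon[pos]
        ]
        usable = [m for m in neighbours if not is_stop(m)]
        if usable:
            syn_total += sum(translate(m) == aa for m in usable) / len(usable)
    return syn_total, 3.0 - syn_total


def ref_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average syn/nonsyn step counts over stop-free mutation pathways."""
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not positions:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(positions):
        current = codon_a
        steps = []
        ok = True
        for k, pos in enumerate(order):
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if is_stop(nxt) and k < len(order) - 1:
                ok = False
                break
            steps.append(translate(nxt) == translate(current))
            current = nxt
        if ok:
            pathways.append(steps)
    if not pathways:
        for order in itertools.permutations(positions):
            current = codon_a
            steps = []
            for pos in order:
                nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
                steps.append(
                    not is_stop(nxt)
                    and not is_stop(current)
                    and translate(nxt) == translate(current)
                )
                current = nxt
            pathways.append(steps)
    sd = sum(sum(p) for p in pathways) / len(pathways)
    nd = sum(len(p) - sum(p) for p in pathways) / len(pathways)
    return sd, nd


def ref_kaks(cds_a: str, cds_b: str) -> tuple[float | None, float | None]:
    """(Ks, Ka) from the reference counts and the Jukes-Cantor formula."""
    codons_a = [cds_a[i : i + 3] for i in range(0, len(cds_a), 3)]
    codons_b = [cds_b[i : i + 3] for i in range(0, len(cds_b), 3)]
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        sa, na = ref_sites(ca)
        sb, nb = ref_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = ref_diffs(ca, cb)
        Sd += sd
        Nd += nd

    def jc(p: float) -> float | None:
        if p >= 0.75:
            return None
        return -0.75 * math.log(1 - 4 * p / 3)

    return jc(Sd / S), jc(Nd / N)


def ref_tandem_pairs(
    kinases: list[dict], all_positions: list[dict], max_intervening: int, max_bp: int
) -> set[tuple[str, str]]:
    """Exhaustive per-chromosome scan over all same-family kinase pairs.

    ``kinases``: dicts with gene, family, chrom, start, end.
    ``all_positions``: dicts with gene, chrom, start for every annotated gene.
    """
    by_chrom: dict[str, list[dict]] = {}
    for g in all_positions:
        by_chrom.setdefault(g["chrom"], []).append(g)
    index = {}
    for chrom, genes in by_chrom.items():
        genes.sort(key=lambda g: (g["start"], g["gene"]))
        for i, g in enumerate(genes):
            index[g["gene"]] = i
    pairs = set()
    for a in kinases:
        for b in kinases:
            if a["gene"] >= b["gene"]:
                continue
            if a["family"] != b["family"] or a["chrom"] != b["chrom"]:
                continue
            if a["family"] == "unclassified":
                continue
            intervening = abs(index[a["gene"]] - index[b["gene"]]) - 1
            first, second = (a, b) if a["start"] <= b["start"] else (b, a)
            gap = max(0, second["start"] - first["end"])
            if intervening <= max_intervening and gap < max_bp:
                pairs.add((a["gene"], b["gene"]))
    return pairs


def ref_longest_chain(
    points: list[tuple[int, int]], max_gap: int
) -> int:
    """Length of the longest doubly-monotone chain, by exhaustive search.

    Considers both rising and falling second coordinates; feasible for
    up to ~15 points (subset enumeration).
    """
    n = len(points)
    best = 0
    for mask in range(1, 1 << n):
        chosen = sorted(
            (points[i] for i in range(n) if mask >> i & 1),
        )
        for direction in (1, -1):
            ok = True
            for (a1, b1), (a2, b2) in zip(chosen, chosen[1:]):
                da = a2 - a1
                db = direction * (b2 - b1)
                if da <= 0 or db <= 0 or da > max_gap or db > max_gap:
                    ok = False
                    break
            if ok:
                best = max(best, len(chosen))
    return best
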