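"""Nei-Gojobori (1986) Ka/Ks estimation with Jukes-Cantor correction.

Implements the classical counting method for synonymous (Ks) and
nonsynonymous (Ka) substitution rates between two aligned coding
sequences:

* per-codon synonymous/nonsynonymous *site* counts, where each codon
  position contributes the fraction of its single-base changes that are
  synonymous (changes to stop codons are excluded from the denominator);
* pathway-averaged *difference* counts for codon pairs differing at 2-3
  positions, excluding pathways that pass through a stop codon;
* proportions pS = Sd/S and pN = Nd/N with S, N averaged between the two
  sequences, corrected for multiple hits with the Jukes-Cantor distance
  d = -(3/4) ln(1 - 4p/3).

Ka/Ks < 1 indicates purifying (negative) selection, = 1 neutral
evolution and > 1 positive selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Iterable, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "KaKsResult",
    "KsHistogram",
    "codon_align",
    "count_sites",
    "count_differences",
    "kaks",
    "ks_histogram",
    "jukes_cantor",
    "NEUTRAL_TOL",
]

_TABLE = unambiguous_dna_by_id[1]  # standard nuclear code
CODON_TO_AA = dict(_TABLE.forward_table)
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = frozenset(CODON_TO_AA)
_BASES = "ACGT"

#: half-width of the Ka/Ks band classified as "neutral"
NEUTRAL_TOL = 1e-9


@dataclass(frozen=True)
class KaKsResult:
    """NG86 site/difference counts and corrected rates for one CDS pair.

    ``ks``, ``ka`` and ``ratio`` are ``None`` when undefined: a proportion
    at or beyond the Jukes-Cantor saturation point 3/4, or a ratio with
    Ks = 0 (distinct from saturation, see ``selection``).
    """

    gene_a: str
    gene_b: str
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ks: float | None
    ka: float | None
    ratio: float | None
    selection: str  # purifying | neutral | positive | undefined


@dataclass
class KsHistogram:
    """Ks frequency distribution in half-open bins [k*w, (k+1)*w)."""

    bin_width: float
    counts: dict[int, int]
    n_undefined: int
    peak_bins: list[int] = field(default_factory=list)

    def bin_label(self, index: int) -> str:
        lo = index * self.bin_width
        return f"{lo:g}-{lo + self.bin_width:g}"


def _validate_cds(seq: str, name: str) -> str:
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"{name}: CDS length {len(seq)} is not a multiple of 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for i, codon in enumerate(codons[:-1]):
        if codon in STOP_CODONS:
            raise ValueError(f"{name}: internal stop codon {codon} at codon {i + 1}")
    return seq


def codon_align(
    cds_a: str,
    cds_b: str,
    protein_alignment: tuple[str, str] | None = None,
) -> list[tuple[str, str]]:
    """Pair up codons of two CDS for NG86 counting.

    Without a protein alignment the sequences must be equal-length and
    gapless and are paired positionally.  With a protein alignment
    ``(aln_a, aln_b)`` (gaps as ``-``), codons are back-translated onto
    the alignment and gap-containing columns are dropped; the ungapped
    alignment rows must match the CDS translations.

    A terminal stop codon present in both sequences is dropped; internal
    stops are an error.
    """
    cds_a = _validate_cds(cds_a, "cds_a")
    cds_b = _validate_cds(cds_b, "cds_b")
    codons_a = [cds_a[i : i + 3] for i in range(0, len(cds_a), 3)]
    codons_b = [cds_b[i : i + 3] for i in range(0, len(cds_b), 3)]
    if codons_a and codons_a[-1] in STOP_CODONS:
        codons_a = codons_a[:-1]
    if codons_b and codons_b[-1] in STOP_CODONS:
        codons_b = codons_b[:-1]

    if protein_alignment is None:
        if len(codons_a) != len(codons_b):
            raise ValueError(
                "unequal CDS lengths require a protein alignment "
                f"({len(codons_a)} vs {len(codons_b)} codons)"
            )
        return list(zip(codons_a, codons_b))

    aln_a, aln_b = protein_alignment
    if len(aln_a) != len(aln_b):
        raise ValueError("protein alignment rows differ in length")
    for aln, codons, name in ((aln_a, codons_a, "cds_a"), (aln_b, codons_b, "cds_b")):
        residues = aln.replace("-", "")
        trans = "".join(CODON_TO_AA[c] for c in codons)
        if residues != trans:
            raise ValueError(f"protein alignment does not match translation of {name}")
    pairs: list[tuple[str, str]] = []
    ia = ib = 0
    for col_a, col_b in zip(aln_a, aln_b):
        ca = cb = None
        if col_a != "-":
            ca = codons_a[ia]
            ia += 1
        if col_b != "-":
            cb = codons_b[ib]
            ib += 1
        if ca is not None and cb is not None:
            pairs.append((ca, cb))
    return pairs


@lru_cache(maxsize=None)
def count_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts (s, n) of one sense codon.

    Each position contributes syn_neighbors / valid_neighbors, where
    neighbors that mutate the codon into a stop are excluded from the
    denominator; s + n = 3 always.
    """
    if codon not in SENSE_CODONS:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            valid += 1
            if CODON_TO_AA[mutant] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


@lru_cache(maxsize=None)
def count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous difference counts (sd, nd).

    Codon pairs differing at 2-3 positions are resolved by averaging over
    all orderings of single-base steps; pathways passing through a stop
    codon are excluded (if every pathway is blocked, all are used and
    steps touching a stop count as nonsynonymous).  sd + nd equals the
    number of differing positions.
    """
    for codon in (codon_a, codon_b):
        if codon not in SENSE_CODONS:
            raise ValueError(f"not a sense codon: {codon!r}")
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0

    def walk(order: Sequence[int]) -> tuple[float, float] | None:
        current = codon_a
        sd = nd = 0.0
        blocked = False
        for step, pos in enumerate(order):
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            intermediate = step < len(order) - 1
            if nxt in STOP_CODONS:
                if intermediate:
                    blocked = True
                nd += 1.0  # only used in the all-blocked fallback
            elif CODON_TO_AA.get(current) is not None and CODON_TO_AA.get(nxt) == CODON_TO_AA.get(current):
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        if blocked:
            return None
        return sd, nd

    orders = list(permutations(diff_positions))
    tallies = [walk(o) for o in orders]
    valid = [t for t in tallies if t is not None]
    if not valid:
        # every pathway crosses a stop: fall back to averaging them all
        valid = []
        for order in orders:
            current = codon_a
            sd = nd = 0.0
            for pos in order:
                nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
                if (
                    current in SENSE_CODONS
                    and nxt in SENSE_CODONS
                    and CODON_TO_AA[nxt] == CODON_TO_AA[current]
                ):
                    sd += 1.0
                else:
                    nd += 1.0
                current = nxt
            valid.append((sd, nd))
    sd = sum(t[0] for t in valid) / len(valid)
    nd = sum(t[1] for t in valid) / len(valid)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3).

    Returns ``None`` (saturation) for p >= 3/4 where the logarithm is
    undefined.
    """
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _classify(ratio: float | None) -> str:
    if ratio is None:
        return "undefined"
    if ratio < 1.0 - NEUTRAL_TOL:
        return "purifying"
    if ratio > 1.0 + NEUTRAL_TOL:
        return "positive"
    return "neutral"


def kaks(
    cds_a: str,
    cds_b: str,
    *,
    gene_a: str = "a",
    gene_b: str = "b",
    protein_alignment: tuple[str, str] | None = None,
) -> KaKsResult:
    """NG86 Ka, Ks and Ka/Ks for one aligned CDS pair.

    Site totals are averaged between the two sequences; symmetric in
    argument order.  Saturated proportions (p >= 3/4) flag the distance
    as undefined rather than raising; Ks = 0 flags the ratio undefined.
    """
    pairs = codon_align(cds_a, cds_b, protein_alignment)
    if not pairs:
        raise ValueError("no aligned codons")
    s_a = n_a = s_b = n_b = 0.0
    sd = nd = 0.0
    for ca, cb in pairs:
        sa, na = count_sites(ca)
        sb, nb = count_sites(cb)
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        d_s, d_n = count_differences(ca, cb)
        sd += d_s
        nd += d_n
    s_sites = (s_a + s_b) / 2.0
    n_sites = (n_a + n_b) / 2.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    if ks is None or ka is None or ks == 0.0:
        ratio = None
    else:
        ratio = ka / ks
    return KaKsResult(
        gene_a=gene_a,
        gene_b=gene_b,
        s_sites=s_sites,
        n_sites=n_sites,
        sd=sd,
        nd=nd,
        ps=ps,
        pn=pn,
        ks=ks,
        ka=ka,
        ratio=ratio,
        selection=_classify(ratio),
    )


def ks_histogram(results: Iterable[KaKsResult], bin_width: float = 0.1) -> KsHistogram:
    """Bin defined Ks values into half-open bins of ``bin_width``.

    Undefined (saturated) Ks values are excluded from the bins and
    tallied separately; the modal bin(s) are reported for dating the
    duplication cohort.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    counts: dict[int, int] = {}
    n_undef = 0
    for res in results:
        if res.ks is None:
            n_undef += 1
            continue
        idx = int(res.ks // bin_width)
        counts[idx] = counts.get(idx, 0) + 1
    peak = []
    if counts:
        top = max(counts.values())
        peak = sorted(k for k, v in counts.items() if v == top)
    return KsHistogram(bin_width=bin_width, counts=dict(sorted(counts.items())), n_undefined=n_undef, peak_bins=peak)
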