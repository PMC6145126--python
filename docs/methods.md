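# Methods

This note records the models implemented, the parameter choices that
matter, what the synthetic data does and does not emulate, and the
numerical decisions taken where the design was open.

## Kinase identification and classification

Input is a whitespace-delimited per-domain hit table (the dialect of
common profile-HMM search tools: target, model, model length,
full-sequence and per-domain independent E-values, bit score, HMM and
alignment coordinates). A hit is accepted when its **per-domain
independent E-value is strictly below 10⁻⁵** and its alignment covers
**at least 50% of the model length** (inclusive at the boundary,
computed on model coordinates). The per-domain E-value, rather than the
full-sequence one, is the conservative choice for a coverage-based
rule; a flag allows per-sequence filtering instead. A protein is a
kinase iff ≥ 1 accepted hit of a catalytic model (default
Pkinase/Pkinase_Tyr).

Family assignment takes the accepted family-model hit with the highest
bit score. Exact ties are broken lexicographically and **flagged**, and
the bit-score margin to the runner-up is reported, so borderline
assignments are visible without a phylogenetic confirmation step (tree
building is out of scope). The group is the family-name prefix before
the first underscore (`RLK-Pelle_DLSV` → `RLK-Pelle`). Proteins with no
accepted family hit are carried as `unclassified` (family and group).

Kinase-domain multiplicity merges accepted catalytic hits whose
protein-coordinate overlap exceeds 50% of the shorter hit, preventing a
split alignment of one physical domain from counting twice. Intron
counts use the representative transcript (longest CDS, ties by id);
gene coordinates are the GFF3 gene span, 1-based inclusive. Summaries
tally scaffold-located genes separately from chromosome-anchored ones.

## Duplication detection

**Tandem:** two catalogued genes of the same family on one chromosome
with at most **5 intervening annotated genes** (all genes, not just
kinases — "neighbouring" is read against the whole annotation) and a
boundary-to-boundary gap **strictly below 100 kb** (end of the upstream
gene to start of the downstream gene; the measurement point is a
package choice, as common usage does not pin it down). Arrays are
connected components of the pairwise relation; both pair-level and
array-level counts are reported because "event" is ambiguous between
the two.

**Segmental:** a deliberate simplification of full collinearity
scanners. Anchors (homologous gene pairs with per-chromosome gene
ranks) are chained into maximal runs monotone in both rank orders,
allowing rank gaps ≤ 25 and requiring ≥ 5 anchors — the documented
defaults of the standard tool this emulates. Chains are extracted
greedily (longest first, ties toward the smaller rank span; same
orientation preferred over inverted on exact ties), so no anchor joins
two blocks. Anchor homology is an upstream input: a similarity table
for real data, truth labels for synthetic genomes — similarity search
itself is out of scope.

## Ka/Ks (Nei–Gojobori 1986 with Jukes–Cantor correction)

The counting method is fully specified so it can be verified against a
brute-force oracle:

- **Sites.** For each codon position, the synonymous fraction is
  (synonymous single-base neighbours)/(neighbours that are not stop
  codons); s + n = 3 per codon. Site totals are averaged between the
  two sequences.
- **Differences.** Codon pairs differing at 2–3 positions average the
  synonymous/nonsynonymous step counts over all orderings of
  single-base steps, excluding pathways through stop codons (if every
  pathway is blocked — possible only for rare pairs — all pathways are
  used and steps touching a stop count as nonsynonymous).
- **Correction.** d = −(3/4)·ln(1 − 4p/3) applied to pS and pN;
  p ≥ 3/4 flags the rate as undefined (saturation) rather than raising.
  Ks = 0 flags the *ratio* undefined — distinct from saturation, since
  an infinite ratio would conflate "no synonymous signal" with
  "positive selection".
- **Selection.** purifying / neutral / positive by comparing Ka/Ks to 1
  with a 10⁻⁹ tolerance band for neutrality.

The standard nuclear genetic code is fixed. Codon alignment accepts
equal-length gapless CDS directly or back-translates a supplied protein
alignment, dropping gap columns; terminal stop codons present in the
CDS are trimmed. The likelihood-based alternatives (GY94-style) and
codon-usage-corrected estimators are out of scope; on real data a
different substitution model would shift values slightly.

Ks histograms use half-open bins [k·w, (k+1)·w) with w = 0.1 by
default; undefined Ks values are excluded from the bins and tallied
separately, and the modal bin(s) are reported for dating.

## Alternative splicing

The classifier operationalizes the standard pairwise-isoform event
definitions (the upstream databases used in survey papers do not
publish their internal rules): comparisons run on intron chains in
genomic coordinates, donor/acceptor resolved by strand. Intron
retention: an intron of one isoform inside an exon of the other.
Alternative acceptor/donor: overlapping introns sharing the donor
(resp. acceptor) boundary only. Exon skipping: an exon strictly inside
a single intron of the other isoform whose boundaries coincide with the
flanking introns' outer boundaries (i.e. the flanking junctions are
shared). Detection runs ES → IR → AA/AD, consuming introns as they are
explained; overlapping introns differing at both boundaries and any
leftover unique introns contribute a "complex" event. UTR-only
differences (identical intron chains) are not AS.

Gene level: the union of pairwise events, deduplicated by type and
coordinates. Exactly one elementary type labels the gene with it; two
or more types, or any complex event, label it "complex"; single-isoform
genes and identical isoforms are "none". Summary proportions are over
genes with at least one event.

## Expression

Genes whose FPKM is **strictly below 10 in every sample** are filtered
as lowly expressed (a single sample at exactly 10 retains the gene).
Clustering operates on log₂(FPKM+1) by default — survey papers show
log-scale heatmaps without stating the clustering input scale, so the
scale is a config flag. k-means uses Pearson distance
d(x, c) = 1 − r(x, c) with centroids as arithmetic means of member
profiles, k = 10 by default and the best of `n_restarts` (default 50)
initialisations by the summed within-cluster distance; deterministic
given the seed. Zero-variance profiles are removed first and reported;
a zero-variance centroid is assigned the maximal distance 2 to keep
iterations total; an emptied cluster is re-seeded from the point
farthest from its centroid. Family-level expression is the arithmetic
mean of member FPKM per sample.

## Coexpression network

Edges require |r| **strictly** above the threshold (0.8 default, 0.9
for the stricter variant) and a **two-sided t-test p-value strictly
below 0.01** — the t transform is the package's operationalization of
"significance level", cross-checked against a permutation null in the
tests. No multiple-testing correction is applied by default, matching
common practice for these survey networks; a Benjamini–Hochberg option
exists. Constant profiles have no defined correlation and are dropped
with a warning. Gene-level and family-mean matrices go through the same
code path. For diurnal two-tissue designs the two 12-point series are
concatenated into one 24-point profile per gene.

## Synthetic data: what it emulates, and what it does not

The generators produce the *statistical structure* the methods assume,
not biological realism:

- `gen_genome` lays out each chromosome as a stream of kinase and decoy
  genes. Tandem arrays are same-family runs with 0–2 intervening decoys
  and small gaps (guaranteed to satisfy the tandem rule); every other
  planted gene is separated by ≥ 6 intervening decoys, so planted
  arrays are the only tandem signal; a "near-miss" same-family pair
  with one intervening gene but a 150 kb gap exercises the bp bound.
  Intergenic gaps are uniform on 0.5–5 kb so both sides of the 100 kb
  threshold occur. Collinear blocks place order-preserved anchor
  partners on chromosome pairs. Same-family genes are diverged copies
  of a per-family ancestral CDS (8% of codons substituted per copy), so
  duplicate pairs are alignable and give defined Ka/Ks. Decoys carry no
  hit, an E-value-failing hit (10⁻³), or a coverage-failing hit (100 of
  260 model positions) in equal proportion. Defaults (6 chromosomes,
  ~120 genes each, 6 families) are a desk-scale stand-in for a 25-
  chromosome genome; there is no sequence-level homology realism beyond
  what the detectors read.
- `gen_cds_pair` plants at most one single-base change per codon —
  synonymous and nonsynonymous counts chosen as the Jukes–Cantor
  inverses of the Ks/Ka targets times the NG86 site counts — so planted
  changes map one-to-one onto NG86 differences and recovery error
  measures only the estimator, not pathway ambiguity.
- `gen_expression` draws lowly-expressed genes uniformly below 10 and
  expressed genes as cluster profile + Gaussian noise truncated at
  zero; default profiles are well-separated plateaus (baseline 4, peak
  90 FPKM). The 14-sample default panel mirrors a tissue survey; a
  24-point panel emulates diurnal series.
- `gen_isoforms` builds fixtures exhibiting exactly one requested event
  per alternative isoform against a shared 5-exon base isoform.
- `survey_scale_catalog` builds a synthetic catalog whose group sizes,
  scaffold tally and domain-multiplicity histogram mirror a published
  survey's printed counts, so the summarizers can be exercised at that
  scale; coordinates are placeholders.

Because the generators plant exactly the structure the detectors test
for, passing tests demonstrate correctness of the rules and estimators
— not robustness to annotation errors, fragmented assemblies, missing
isoforms or non-Gaussian expression noise, none of which are simulated.

All generators take explicit seeds and are byte-deterministic;
identical config + seed reproduces identical files.

## Problem sizes in tests and the acceptance script

The shipped checks use desk-scale sizes chosen to exercise every rule:
1000 random codon pairs for oracle equivalence; 100 pairs × 900 codons
per Ks target for recovery (mean relative error ≲ 1%, well inside the
15% budget); 50 (tests) / 20 (script) random genomes for tandem/block
recovery; 300 genes × 10 clusters × 50 restarts for clustering; 20
draws × 50 000 shuffles per (r, n) point for the permutation
cross-check of the t-based p-value (the permutation null is conditional
on the draw, so single-draw deviations of several Monte-Carlo sigmas
are expected and the comparison averages over draws).

## Known limitations

- NG86 is the implemented estimator; surveys built on other tools'
  default models will differ slightly on real data.
- Collinearity is simplified chaining, not the full scoring scheme of
  the standard tool; on clean anchors they agree, on noisy anchor sets
  the block boundaries may differ.
- AS calling is transcript-model-based; read-level quantification (PSI)
  and subtypes like mutually exclusive exons are out of scope.
- Whether survey clustering ran on raw or log FPKM (and with how many
  restarts) is typically unstated; both are supported, log is the
  default.
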