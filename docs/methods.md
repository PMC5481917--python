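# Methods

famexpand analyzes how a gene superfamily expands in a lineage that went
through a whole-genome triplication (WGT) followed by fractionation, with
tandem duplication (TD) acting both before and after the lineage split.
The motivating system is the plant UDP-glycosyltransferase (UGT)
superfamily in *Brassica rapa* and *B. oleracea* compared against
*A. thaliana*, but every stage is generic: inputs are gene-only GFF3
annotations, a per-gene family table, a homology anchor table, a
subgenome map, codon-aligned sequence pairs, and a gene x tissue
expression matrix.

## Rank-based adjacency

All positional rules use gene *ranks*: the 0-based ordinal of a gene
among all annotated genes on its chromosome ordered by start coordinate
(ties by end, then id). Ranks count intervening ORFs, so the rules are
invariant to coordinate rescaling. Two rules share this machinery:

* **Gene clusters** — two or more superfamily genes whose consecutive
  members lie within `max_gap` = 8 ranks (boundary inclusive), pooled
  across families by default. We read "within eight open reading frames"
  as a rank difference of at most 8 between consecutive members, computed
  against the full gene complement; whether the convention means 8
  intervening genes or a span of 8 is genuinely ambiguous, so the choice
  is exposed as a flag.
* **Tandem arrays** — maximal same-family runs with at most
  `max_intervening` = 1 non-family gene between consecutive members.
  A loader for externally curated tandem lists (PTGBase-style) can
  replace detection.

## Synteny and ortholog retention

Anchors are filtered at significance <= 1e-20 and, with the uniqueness
convention (u = 1), reduced to the best-scoring anchor per (reference
gene, target chromosome). Chaining is a dynamic program per chromosome
pair: the largest chain with strictly increasing reference ranks,
strictly monotone target ranks (same or inverted orientation) and rank
gaps <= `max_rank_gap` = 25 on both genomes is extracted, its anchors
removed, and the search repeated; chains shorter than `min_anchors` = 5
are discarded. This is a deliberately simple stand-in for MCScanX-style
collinearity chaining — equivalence with MCScanX is not claimed. What is
verified instead: the DP is exactly optimal (tested against subset
enumeration on small instances) and recovers planted block structure
perfectly on simulated genomes.

Blocks take the subgenome label (LF / MF1 / MF2: least, medium, most
fractionated) of the map interval holding the majority of their anchors;
ties are flagged. Ortholog records then give each reference gene its
best-scoring syntenic partner per subgenome; a descendant gene can serve
only one reference gene (score, then lexicographic id). The copy class
(0-3) counts filled subgenome slots.

## Dating tandem arrays

A descendant gene is *ancient* when it occupies an ortholog slot — it was
retained from the triplication, so it predates the reference/descendant
split. The WGT/TD Venn partition and its "ancient TD fraction"
(|WGT intersect TD| / |TD|) follow directly. Array-level calls:

* **ancient-complete** — at least two members are ancient and their
  reference partners sit in one reference-genome tandem array (the
  reference array "would exist", so the array predates the split);
* **ancient-incomplete** — ancient members without reference-side array
  support;
* **lineage-specific** — no ancient member;
* **mixed** — ancient and lineage-specific members together (an old
  array that kept duplicating after the split).

The packaged ancient-array table (reference genes x six subgenome slots)
is recounted in fixture mode. Complete arrays are regrouped per
(species, subgenome, family) by numeric gene-id adjacency with id gap
<= 2 — descendant database ids run sequentially along chromosomes, so an
id gap of 2 corresponds to at most one intervening gene, the same
tolerance as the tandem rule. This reproduces the printed counts
(31 and 24 ancient genes; 13 and 12 complete arrays).

## Selection pressure (NG86)

Ka/Ks uses Nei-Gojobori (1986) counting with Jukes-Cantor correction,
standing in for ML codon models: per codon position, each of the three
possible point mutations contributes 1/3 of a site to the synonymous or
nonsynonymous class; mutations creating stop codons are excluded from
both denominators. Differences at codons disagreeing in k positions are
averaged over all k! mutational pathways, dropping pathways through stop
codons and renormalizing (codons where every pathway hits a stop are
skipped and counted). With ps = Sd/S and pn = Nd/N,
`d = -(3/4) ln(1 - 4p/3)`; p >= 3/4 is reported as saturated/undefined,
as is Ks = 0. Selection modes: ratio < 1 - band negative, > 1 + band
positive, else neutral, with band = 0.05 (the "equal to 1 = neutral"
rule needs a tolerance; it is configurable). Undefined ratios are
excluded from lineage means, with counts reported. Because the upstream
study used PAML, its printed lineage means are method- and
data-dependent and are not reproduced; the accuracy claim here is
simulation recovery (below). An independent NG86 implementation
(Biopython's) is used as a cross-check in tests; it differs only in
stop-codon conventions.

Lineage comparisons use the two-sided Mann-Whitney U test (exact
enumeration when the combined n <= 12 without ties, else the normal
approximation with tie and continuity corrections; identical samples are
p = 1 by convention) and the Pearson 2x2 chi-square without continuity
correction (Yates optional), both via scipy with the exact paths verified
against full enumeration.

## Expression divergence

Genes expressed above `min_value` = 0 in at least `min_tissues` = 1
tissue are kept (the upstream filtering threshold is unstated; both are
flags). Distance is 1 - Spearman rho between tissue profiles (average
ranks for ties; constant rows get distance 1 with a warning), clustered
by complete linkage and cut at a user-chosen k; presets k = 9 and k = 5
mirror the nine- and five-cluster analyses (how those counts were chosen
upstream is unstated, so k is explicit here). Per-cluster tissue calls
compare the cluster mean of row-wise z-scores against +/-0.5
(configurable): up / down / flat.

## Synthetic genomes (the recovery harness)

The generator plants a fully recorded history so each stage can be
scored exactly:

* **Ancestor** — `n_chromosomes` x `genes_per_chromosome` genes
  (default 5 x 200; the genome-recovery study uses 10 x 500), families
  with gamma-weighted sizes under the constraint that same-family genes
  sit >= `family_spacing` = 4 ranks apart outside planted arrays (so
  planted arrays never merge); pre-split tandem arrays planted per seed
  gene at rate 0.05, sizes 2..`max_array_size` with geometric decay.
* **Triplication + fractionation** — each gene copied into LF/MF1/MF2 of
  each descendant and kept with gene-wise independent Bernoulli retention
  (defaults 0.70 / 0.45 / 0.30, ordered as the fractionation labels
  imply; the upstream study states no rates, so these are testing
  defaults, not estimates). Post-split tandem copies added per retained
  gene at rate 0.02. The anchor table holds one anchor per descendant
  gene to its true ancestral source (triplication copies score 80-100,
  tandem copies 50-70, so uniqueness filtering resolves them), plus ~1%
  decoy pairs above the e-value cutoff. Cross-hits between paralogs are
  not emulated — the table represents a curated best-hit set, which is
  the main simplification relative to raw BLAST output.
* **Codon pairs** — a random stop-free sequence accumulates
  Poisson(3 L ks_target) proposed point mutations (uniform site, uniform
  alternative base); synonymous changes are always accepted,
  nonsynonymous with probability omega, stop-creating never. This makes
  E[Ks] ~ ks_target and E[Ka/Ks] ~ omega without transition/transversion
  bias (omega recovery is the only goal). ks_target >= 2 is flagged as
  saturating.
* **Expression** — each cluster receives a lognormal tissue profile,
  redrawn until every pairwise profile Spearman distance is >=
  `profile_separation` = 0.5 (merely distinct rank orders can differ by
  one adjacent swap, which rank-based clustering cannot resolve through
  noise); gene rows are the profile times entry-wise exp(N(0, noise_sd)).

All randomness flows from one integer seed through named
`numpy.random.Generator` streams (one per operation); identical configs
give identical outputs.

### What recovery on this simulator does and does not show

Recovery tests demonstrate that the inference chain is exact when
homology is unambiguous: member-level ancient/lineage-specific precision
and recall are 1.0 and recovered copy classes match planted retention
on genomes of >= 5000 ancestral genes. Planted arrays reduced to fewer
than two members in a subgenome (whole-array loss) make the age call
undecidable; such members are counted and excluded, never guessed.
Real genomes add what the simulator omits: paralogous cross-hits,
rearrangements and inversions beyond block orientation, unequal gene
spacing, annotation errors, and expression matrices whose cluster
structure is not block-shaped. Passing these tests therefore validates
the bookkeeping and the algorithms, not robustness to noisy homology.

## Numerical conventions

Percentages round half-up (not banker's) at 2 decimals by default; the
upstream tables mix truncation and rounding, so single-digit
discrepancies in the last decimal against printed values are expected
and documented rather than matched. Conflicts everywhere resolve by
highest score, then lexicographic gene id, for determinism. Coordinates
are 1-based inclusive (GFF3); strand is carried but ignored by adjacency
rules.

## Problem sizes used by the recovery studies

The shipped studies use 200 pairs x 300 codons for omega recovery,
10 x 500-gene ancestors (two descendants, three subgenomes) for
duplication-age recovery, and 120 genes x 6 tissues x 5 clusters for
expression recovery — sizes chosen so every study runs in seconds while
keeping binomial sampling error well inside the asserted tolerances.
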