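# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `telinc`. It describes what the code computes and why;
every empirical number quoted here is produced by the test suite or by
`scripts/acceptance.py`, nothing else.

## Coordinates and interval algebra

All internal coordinates are 0-based half-open. RepeatMasker `.out`
(1-based inclusive) and GTF (1-based inclusive) are converted on read;
BED and bedGraph pass through unchanged. A single convention everywhere
removes the most common class of off-by-one bugs in this kind of
pipeline; the round-trip tests (parse → export → parse) pin it down.

Interval sets are per-chromosome sorted lists. Normalisation (merging
overlapping/book-ended records) is always an explicit call, never a side
effect, so record multiplicity survives I/O round trips. All set
operations (union/projection, subtraction, intersection, pair
enumeration with a minimum-overlap floor) are validated against a
per-base bitmap oracle in the tests, including the accounting identity
`covered(A) = covered(A−B) + covered(A∩B)`.

TEs are strandless throughout: a TE may supply features to transcripts
on either strand. Transcript strand is used only to orient first/last
exons, TSS/polyA, and upstream/downstream flanks.

## TE annotation

RepeatMasker rows of class Low_complexity, Satellite, Simple_repeat or
any structural-RNA class are discarded, as are families on a
caller-supplied blacklist (species-specific artefact families such as
MutSatRep1 in mouse; there is no general rule behind such lists, so it
is configuration, not code). Consecutive same-family fragments on one
chromosome separated by fewer than 10 bp are merged into one fragment —
old TE copies are artificially split by the annotator and would
otherwise be multiply counted. "Fewer than 10" means a 9-bp gap merges
and a 10-bp gap does not. Merging keys on (chromosome, family) adjacency
only: fragment-ID linkage in the annotator output is not relied on.

LTR-class elements are subdivided into LTR proper and internal portions
(family names ending in `-int`/`_I`), because the two parts have very
different lengths and regulatory content; coverage tables report
LTR/LTR and LTR/int separately alongside LINE, SINE and DNA.

## TE content and compartment coverage

Per-transcript TE content is the fraction of the *genomic projection* of
the transcript's exons covered by qualifying TE overlaps. The ≥ 10 bp
overlap floor applies per fragment-exon pair: a fragment grazing one
exon by 3 bp contributes nothing even if it solidly overlaps another. A
TE spanning two exons is counted once via the projection.

Compartment coverage uses: whole ungapped genome; lncRNA exon
projection; protein-coding exon projection (only genes with both UTRs
annotated); introns minus every annotated exon of any set; upstream and
downstream flanks at 1 kb and 10 kb (nested by default — the 1-kb flank
is a subset of the 10-kb flank; a disjoint-annulus mode exists);
UTR5/UTR3/CDS. Flanks are per-transcript "longest clear run" intervals:
from the TSS (or polyA) away from the gene body until the first
annotated exon, the length cap, or the chromosome edge; per-gene
aggregation takes the union of per-transcript flanks to avoid double
counting bases.

lncRNAs are split into intergenic vs genic by whether their span
overlaps any protein-coding transcript span; the two subsets partition
the lncRNA set.

## Feature classification

Each TE×exon overlap of ≥ 10 bp receives exactly one category. Because a
TE fragment is a contiguous interval, it can cover both terminal bases
of an exon only by covering the whole exon, so the precedence (full exon
≻ single boundary ≻ interior) is never ambiguous:

| exon role | full coverage | 5′ boundary base | 3′ boundary base | interior |
|-----------|---------------|------------------|------------------|----------|
| first     | TSS_SPL       | TSS              | SPL              | EXONIZED |
| internal  | BOTH_SPL      | SPL              | SPL              | EXONIZED |
| last      | POLYA_SPL     | SPL              | POLYA            | EXONIZED |
| single    | FULL_SINGLE   | TSS              | POLYA            | EXONIZED |

Single-exon transcripts fully covered get the composite FULL_SINGLE
label, since the multi-exon categories do not apply. The TSS category
requires only coverage of the TSS base, not extension upstream of it.
The classifier is verified against an independent per-base brute-force
implementation over every placement of several TE lengths on toy
transcripts of both strands. Two symmetries hold and are tested:
relabelling the strand at fixed coordinates swaps TSS↔polyA categories,
and mirroring coordinates *and* flipping strand (a reverse complement of
the locus) preserves every category.

The site inventory deduplicates TSS/polyA/splice sites across
transcripts by (kind, chromosome, base, strand). A site counts as
TE-derived only when a TE both passes the 10-bp overlap filter with the
owning exon and covers the site's base — a 1-bp grazing contact cannot
claim a site.

## Shuffle null and empirical p-values

The null re-places every TE uniformly at random within its own
chromosome, avoiding assembly gaps and mutual overlap, preserving
length, family and class. Placement is rejection sampling of uniform
starts against an occupancy structure, TEs in input order; a chromosome
is restarted after a bounded number of consecutive rejections and
declared infeasible after bounded restarts. For a single TE this is
exactly uniform over feasible starts (verified by chi-square over 10,000
draws).

The empirical p of a category is the fraction of K replicates with a
*strictly lower* count than observed (ties contribute nothing), matching
the convention that a small p flags depletion of the observed count
relative to random placement. K defaults to 5,000 for real analyses; the
desk-scale `telinc all` uses K = 200, which resolves p to 0.005 and is
where the replicate-count standard error has long plateaued at this
problem size. A conservative `(lower + 1)/(K + 1)` variant is available
by flag.

Two properties of the strict-lower rule are worth knowing and are pinned
by the calibration test. For categories whose count distribution is wide
(many attainable values), the p-values are approximately uniform under a
uniform-placement truth. For sparse categories (counts concentrated on a
few values) the rule is *not* a valid p-value at the low tail —
P(p = 0) equals the probability of drawing the distribution's minimum,
which can exceed 0.05 — while the mean stays near ½. At real-genome
scales category counts are in the thousands and the distortion is
immaterial; on toy data, use the conservative variant if the low tail
matters.

The Jaccard statistic |A∩B|/|A∪B| (base pairs, projections) is tested by
the same TE shuffle, reporting both tails. The permutation mean matches
an exact enumeration over all placements on a small fixture.

## Conservation comparison

Per-base scores (phyloP-like) are compared between sets of regions —
exonised TE bases, non-TE exonic bases, a neutral intronic TE set, and a
count- and length-matched random set placed uniformly in ungapped
sequence — by label permutation on the pooled per-base scores, with a
mean-difference statistic by default and a variance-difference statistic
for the "fewer fast-evolving sites" comparison. The permutation p
includes the observed labelling (`(hits+1)/(n_perm+1)`), giving a valid
test with resolution 1/(n_perm+1). Aggregation is per base, not per
element (per-element means are available by flag in the statistic
choice); boxplot-style summaries of real data are per-base
distributions.

The neutral intronic TE set is intronic TE bases minus a 10-bp pad
inside each splice boundary (pad width is not dictated by anything
principled; 10 bp covers the core splice signals) and minus all supplied
chromatin-mark intervals.

## Family enrichment

With M exon-overlapping fragments in total and family genome-wide
fragment share f, the family's observed count k is tested against
Binomial(M, f), exact upper tail, no normal approximation. A fragment
overlapping several exons counts once (deduplicated by fragment id). The
flag additionally requires ratio k/(Mf) > 2 and k ≥ 5 fragments. No
multiple-testing correction is applied by default, matching the
per-family convention this analysis style uses; a Benjamini–Hochberg
option exists and is recommended when scanning hundreds of families.
The universe can be passed as a family → count mapping instead of a
fragment list, which is the sensible representation for multi-million
fragment genomes.

One statistical subtlety: because M includes k, the binomial test is
slightly conservative when a large share of all fragments overlaps the
target (variance deflation by 1−q, q the overlap rate). At realistic
rates — of order 1% of genome-wide fragments touching lncRNA exons — the
effect vanishes; the type-I calibration in the acceptance tests runs at
such a rate and attains ≈ 0.05.

A base-pair analogue (f by bp share, observed bp vs expected bp) is
reported alongside for effect-size context; significance always comes
from counts. Age partitioning splits fragment bp by a user-supplied
family → {lineage_specific, ancient} table; age is library metadata, not
something computable from coordinates.

## Cis-regulation

A TE overlapping a DNase cluster by *strictly more than* 10 bp (this
threshold is deliberately exclusive, unlike the ≥ 10 bp rule elsewhere;
both are config-visible) is a TE-DHS. Accessibility is summed per-base
tag count over the TE span per million library reads. A lncRNA is
specific to a cell type when its expression there is ≥ 10× the mean of
the other cell types plus a pseudocount ε = 0.1 normalised units (the
pseudocount guards all-but-silent genes; configurable). For each lncRNA
and cell, the single most active TE-DHS within 10 kb upstream of the TSS
(strand-aware; a symmetric ±10 kb mode exists since proximity need not
be directional) is retained, ties broken by proximity then id. The
coupling test is a one-sided Wilcoxon rank-sum comparing matched-cell vs
other-cell signals over the specific lncRNAs.

## Compensatory mutations in stems

For a Watson–Crick pair where both bases substitute independently with
transition weight κ and transversion weight 1, the probability the new
pair is again Watson–Crick is p(κ) = (κ²+2)/(κ+2)²: of the nine joint
outcomes, transition–transition always restores pairing (weight κ²) and
two of the transversion–transversion combinations do (weight 2). κ = 1
gives 1/3; the default κ = 1.2 (a vertebrate SNP-derived value) gives
0.3359375. The stem tail probability composes hypergeometric
co-placement of the two arms' substitution counts with a Binomial(j, p)
compensation count per co-mutated pair:

    P(C ≥ c) = Σ_j Hypergeom(j; N, m, n) · P(Bin(j, p) ≥ c)

Both formulas are contract-tested against exhaustive enumeration (all
placements × all substitution outcomes) for every (N ≤ 6, m ≤ 2, n ≤ 2,
c ≤ min(m,n)) to 12 decimals. "Compensatory" means restored Watson–Crick
pairing only; G:U wobble does not count unless the wobble flag is set
(the stricter definition is the default because wobble pairs are
thermodynamically marginal). Bonferroni adjustment multiplies by the
number of stems tested in the run. Structures are consumed as dot-bracket
strings from an external folding tool; folding itself is out of scope.

Editing density is simply sites per base within each exonic segment
class (Alu-like, other TE, non-TE), with classes partitioning the exonic
bases.

## Synthetic data

The generator emulates the *statistical structure* of the real analysis,
with no sequence realism (the only sequences are the short synthetic
stems):

* **Genome**: 2 × 1 Mb chromosomes, 2% assembly gaps (desk default).
* **TEs**: 8 families, two per class, with lognormal lengths and
  genomic fractions summing to ~0.33 — the TE load of a vertebrate
  genome at desk scale (~2,000 fragments).
* **Transcripts**: ~200 lncRNAs (15% genic, placed inside protein-coding
  spans) and ~100 protein-coding genes with both UTRs, 1–10 exons,
  lognormal exon/intron lengths, both strands.
* **Exonic targeting**: each fragment is exon-assigned with probability
  `rate × weight(family)` (desk rate 0.12, yielding ~72% TE-containing
  lncRNAs and ~24% exonic coverage — the regime real human lncRNA sets
  occupy); otherwise it is placed in the background *rejecting exon
  overlap*. Enrichment factors are target observed/expected ratios: the
  family shares among exon-assigned fragments are fraction × factor with
  unplanted families rescaled to close the mixture, so a family planted
  at 3× is recovered at ratio ≈ 3 by the enrichment module rather than
  3/mixture-mean. Because background placement avoids exons (and
  protein-coding exons are never targeted), shuffled TE sets overlap
  features far more than the observed set — the depletion signature the
  feature null is designed to detect.
* **Conservation**: per-base Normal(−0.1, 1) truncated to [−20, 10] over
  exons and TE bases, with +1 SD planted on exonised TE bases;
  background bases are written as ~25-bp constant runs, mimicking the
  local autocorrelation of real conservation tracks while keeping the
  bedGraph small.
* **DHS/expression**: ~70% of lncRNAs get a DHS peak over an upstream TE
  within 10 kb; per-cell signal is Gamma(2, 5) per peak, tripled in the
  matched cell for the ~25% of lncRNAs planted as cell-specific (whose
  expression is set ≥ 10× the other cells); plus background peaks.
* **Editing**: Bernoulli per base at 10⁻³ in Alu-like exonic segments
  and 10⁻⁵ elsewhere — the order-of-magnitude contrast characteristic of
  A-to-I editing. At desk scale this yields only a handful of sites, so
  density estimates are noisy by design.
* **Stems**: 40-pair hairpins with an 8-nt loop; element sequences
  substitute at 2% per site under the κ model; a third of stems get 3
  forced compensatory pairs (both bases substituted, Watson–Crick
  restored).

Everything is a deterministic function of the spec seed (byte-identical
bundles for equal seeds). The truth table records every planted quantity.

What passing tests on this generator do **not** show: robustness to
annotation noise (isoform inflation, fragmented assemblies), sequence
composition effects (GC, CpG), realistic TE age structure, or the
correlated placement of real TEs (clustering, insertion preferences).
Results on real genomes depend on annotation quality in ways the
synthetic bundle cannot probe.

## Problem sizes

The default test-suite and acceptance-script runs use: the desk bundle
(2 Mb, ~2,000 TEs) for end-to-end stages; K = 200 shuffle replicates for
the desk null; 100 trials × K = 200 for null calibration on a 60-kb toy;
a 4-Mb dense genome (~14,000 fragments, M ≈ 2,400) for enrichment
recovery; 200 fragment-level universes (250,000 fragments each, as
counts) for type-I calibration; 1,000 permutations for conservation
tests. These sizes put every Monte-Carlo standard error well inside the
asserted tolerances while keeping the full suite around half a minute.

## Known limitations

* No liftover, no TE age dating from divergence, no RNA folding, no
  peak calling, no read alignment: the pipeline consumes annotations and
  tracks, it does not produce them.
* The GTF reader handles the exon/CDS/UTR + gene_id/transcript_id/biotype
  subset of the format, not the full attribute zoo of every annotation
  source.
* The shuffle places TEs independently and uniformly; real TE insertion
  is clustered and biased, so empirical p-values against this null test
  "different from uniform random", nothing subtler.
* Bases, not elements, are the unit of the conservation comparison;
  per-base scores within an element are correlated in real data, which
  makes permutation p-values on real tracks anti-conservative. Treat
  them as descriptive there, or aggregate per element first.
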