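# Methods

## Problem and scope

Deep-intronic variants (intronic positions ≥ 50 bp from the nearest annotated
splice site; the boundary is inclusive) can activate cryptic splice sites and
create pseudoexons or exon extensions. The package classifies such variants
as pathogenic-splice-altering vs. benign and embeds the classifier in a
diagnostic prioritization workflow. The neural splice predictors used in
production settings are not bundled: per-position splice-site scoring is a
pluggable contract (`SiteScorer`), with a PWM scanner and a
precomputed-score table loader shipped as implementations. This keeps every
computation reproducible at desk scale while allowing production scores to
be ingested from TSV.

## Feature definitions and numerical choices

**Masked splice-gain features.** Scores are searched within *d* = 300 bp of
the variant. Alleles are VCF left-anchored; positions right of an insertion
map ref→alt by +len(insertion), deleted reference bases have no alternate
counterpart and contribute no gain, and inserted bases subtract a reference
score of 0. Deltas are masked to zero at every annotated splice site of the
gene, matched by exact position *and* site kind; raw gains are by definition
unmasked. Deltas are floored at 0 — only gain (splice-site creation) feeds
the classifier; loss scores are out of scope. Strand handling: all window
logic runs in transcript orientation; minus-strand windows are
reverse-complemented, which maps a genomically left-anchored allele onto the
same left-anchored offset contract (the anchor offset `L − o − len(ref)` is
shared between oriented frames). Within-allele position correspondence is
approximate on the minus strand for indels (the shared-anchor end differs);
this affects at most `min(len(ref), len(alt)) − 1` delta positions inside
the allele itself.

**Motif feature.** First-order (independent-position) donor 9×4 and acceptor
23×4 probability models against a uniform background; window log-odds in
bits. The variant feature takes the best reference (*r*) and alternate (*a*)
window overlapping the variant per kind: 0 unless *a* > *r* and *a* > 0
(with a 1e-9-bit tie tolerance so equal-scoring windows reached by different
float summation orders never count as gains), else `min(a, C)/C`. The cap
*C* = 12 bits and the clamp-divide transform are this package's explicit
stand-in for an unpublished normalization; *C* is configurable. The same
clamp maps PWM log-odds onto the [0, 1] per-position scores of the shipped
`PWMSiteScorer`.

**Constraint feature.** Direct interval lookup (0-based half-open BED
convention); overlapping intervals are rejected at load. A position covered
by no interval yields a missing value, and any missing feature makes the
variant unscorable — it is excluded from scoring and ranking rather than
given a default.

**Rarity filters.** Allele frequency < 1% in *every* listed source defines
rare (missing AF counts as 0: a variant absent from population databases is
treated as novel, the convention of diagnostic filtering); ≥ 5% in every
source defines common/benign. The two can never both hold.

**Distance convention.** Distances count intronic bases including the
variant's own base (first intronic base = 1). For deletions the most
splice-proximal deleted base anchors the distance, so an indel is
deep-intronic only when wholly deep — a deliberately conservative choice,
since the alternative (anchor base only) would admit indels that touch the
near-splice zone.

## Classifier

Bagged forest of T = 500 decision trees (scikit-learn backend). The reported
score is the fraction of trees whose leaf majority is pathogenic; leaf ties
break toward benign. Scores are therefore multiples of 1/T and bit-stable
under a fixed seed. Tuning: stratified 5-fold CV over a grid of tree count
{100, 300, 500}, depth {4, 8, 16, ∞}, per-tree sample fraction
{0.5, 0.8, 1.0} and features per split {1, 2, 3, all}, maximizing mean
average precision; ties break toward the smaller model (fewer trees, then
shallower). No class reweighting is applied despite the heavy imbalance:
average precision is the tuning metric precisely because it is stable under
imbalance. The 70/30 split is stratified with floor rounding on the training
side (forced by the worked-example counts 374 → 261/113) and the CV folds
are stratified as well; stratification is this package's choice where the
original procedure is unstated.

## Evaluation

Average precision is the interpolation-free step-sum (delegated to
scikit-learn, which implements exactly that sum; an independent hand-written
oracle checks it in the tests). Max MCC sweeps thresholds 0, 0.001, …, 1
with prediction positive iff score ≥ t; an MCC with any zero denominator
factor is defined as 0 (a widely used convention; the choice is invisible at
the maximum unless the score is constant). Comparator scores on other scales
enter through min-max normalization, which preserves ranks and hence max MCC
up to grid discretization. Sensitivity thresholds use the
nearest-rank-from-top rule — the threshold for level L% over n pathogenic
scores is the ⌈L/100·n⌉-th score from the top — so the realized sensitivity
is never below the requested level; higher levels give lower-or-equal
thresholds.

## Prioritization and the spike-in benchmark

The per-sample funnel: deep-intronic in a protein-coding transcript →
restrict to the Mendelian-disease gene list → rare in every AF source →
scorable (all five features) → score ≥ threshold, sorted by descending
score, with non-increasing stage counts reported. The spike-in benchmark
plants one known pathogenic SAV into one background individual (full cross
product of SAVs × samples) and ranks the spike among all scored candidates
threshold-free; whether thresholded or threshold-free ranking was intended
upstream is unstated, and threshold-free is the choice here since it is the
harder, assumption-free variant. Ties take the pessimistic (largest) rank.
An unscorable or filtered-out spike counts as undetected, i.e. beyond every
top-k cutoff of the undiagnosed rate.

## Synthetic world

`gen_reference` builds ~20 multi-exon genes (defaults: 3 exons of 90 bp,
introns 260–400 bp, genes alternating between strands across two
chromosomes) with consensus donor/acceptor junctions planted at every
exon–intron boundary. Half the genes form the Mendelian gene list; their
introns carry *cryptic* splice motifs — consensus donors/acceptors broken at
a near-invariant position — planted ≥ 50 bp from the real splice sites. The
activating variant (an SNV restoring the invariant base, or a 1-bp deletion
removing an inserted base, ~30% of sites) is the pathogenic SAV; its delta
gain under the PWM scorer is ~0.5 on the 12-bit normalized scale (a single
substitution can restore at most ~5.8 bits), well separated from the ~0
deltas of random substitutions. Constraint scores are drawn U(0.6, 0.95) on
disease genes and U(0.02, 0.18) elsewhere. Benign cohort variants are random
deep-intronic substitutions, either common (AF ~ U(0.05, 0.5) in both
sources) or novel (absent AF) so that the rarity filter retains realistic
background candidates. One global seed fans out to independent per-stage
child seeds.

`gen_feature_table` draws class-conditional feature rows directly: typical
pathogenic rows have high delta gains (70% pseudoexon-like with both sites
gained from Beta(6, 1.5), 30% extension-like with one), a 10% hard stratum
has delta ≤ 0.2 but a strong motif score (Beta(8, 2)), and benign rows have
low deltas (Beta(1.2, 12), with a 5% SAV-like minority at Beta(3, 3)),
mostly-zero motif scores, and constraint mass concentrated below 0.2
(Beta(1.6, 9)). These shapes were fixed once as a plausible qualitative
match to curated pathogenic/benign separations; they are a stated world,
not a fit to any dataset.

What the generator does *not* emulate: realistic human allele-frequency
spectra, linkage, sequencing error, multi-variant haplotypes, genes without
usable transcripts, and — because the PWM scorer sees only local motifs —
the long-range sequence context a neural splice predictor uses. In this
world the raw-gain feature saturates near 1 for sequence-level variants
(the annotated junctions always lie within d = 300 bp of a deep-intronic
position in 260–400 bp introns), so a green end-to-end test establishes the
plumbing and the delta/motif/constraint signal path, not the discriminative
value of the raw-gain feature itself; that value is exercised in the
feature-table world, where raw gain is drawn with class-conditional signal.

## Known limitations

- The raw-gain aggregation defaults to the mean of acceptor/donor raw gains,
  with a `raw_gain_agg="max"` switch; upstream descriptions disagree and the
  mean is the documented default here.
- The motif normalization (cap 12 bits) and the PWM parameters are stand-ins;
  absolute motif-feature values are not comparable to any published scale.
- The transcript picker (one per gene, longest total exonic span,
  transcript-id tie-break) is a deterministic stand-in for a consequence
  picker's single-transcript choice.
- `TableSiteScorer` requires plus-strand genomic context; minus-strand genes
  need the PWM scorer or pre-oriented tables.
- Reference headline numbers from the literature (average precision 0.92,
  max MCC 0.88, 95%-sensitivity threshold 0.082, ~27 candidates per genome,
  81.7% top-5 diagnosis) depend on licensed variant databases and full
  cohort genomes; they are documented for orientation only and are neither
  computed nor asserted anywhere in this package.
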