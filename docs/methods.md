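# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `lnck`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Study design assumed throughout

A biparental maize population: drought-tolerant parent AC7643,
drought-sensitive parent AC7729/TZSRW, and 14 RILs (7 tolerant, 7
sensitive), each grown under well-watered (WW) and water-stressed (WS)
conditions with two replicates — 64 samples. Sample metadata carries line,
generation (P/RIL), tolerance (D/S), condition and replicate; the triple
(line, condition, replicate) is unique.

Coordinates are 1-based inclusive internally (GTF convention); BED and
bedGraph are converted at the I/O boundary. Strand is mandatory everywhere
because positional classification is strand-defined; records with unknown
strand are rejected rather than guessed.

## Identification cascade

Four filters in fixed order, each parameterized in `CascadeConfig` with the
published defaults:

1. **Noncoding consensus** — both predictors must call the transcript
   noncoding. The published text does not state union vs intersection; the
   intersection is the conservative reading and the default
   (`consensus="either"` switches to union).
2. **No successful protein hit** — a hit succeeds iff identity ≥ 65 %,
   aligned length > 30 aa and E-value ≤ 10⁻⁹, all simultaneously. The
   "alignment rate" of the source protocol is interpreted as percent
   identity — the only per-HSP rate a BLAST report carries. Only the best
   (lowest-E) hit is consulted; a transcript with no hit passes.
3. **Not translated** — RNC-seq abundance ≤ 0.1; ribosome-bound RNA above
   that level is treated as translated and removed.
4. **Length and abundance** — spliced length strictly > 200 nt and RNA-seq
   abundance above 0.1. The protocol text uses a strict inequality for the
   abundance and the results text an inclusive one; both readings are
   implemented (`rna_cmp`), strict by default.

Per-stage surviving counts are recorded; a transcript's
`stage_of_elimination` is the first stage it fails, which is what the
planted-decoy tests check (each synthetic decoy violates exactly one
stage). Tightening any threshold can only shrink the retained set; this
monotonicity is tested over a parameter grid.

## Positional classification

Classes are assigned against the coding annotation with precedence
antisense > intronic > sense-overlapping > divergent > intergenic, since a
locus may satisfy several definitions:

- **antisense** — any gene-span overlap with a coding gene on the opposite
  strand;
- **intronic** — same-strand overlap with the lncRNA fully inside a gap of
  the partner's merged exons;
- **sense_overlapping** — any other same-strand overlap;
- **divergent** — no overlap, but TSS-to-TSS distance ≤ 2000 bp
  (inclusive) to an opposite-strand coding gene with the lncRNA positioned
  upstream and transcribed away (head-to-head geometry);
- **intergenic** — everything else. A lncRNA on a chromosome absent from
  the coding annotation is classified intergenic with a warning, not an
  error.

The partner gene reported is the largest-overlap (overlap classes) or
nearest-TSS (divergent) candidate, ties broken lexicographically so the
result is deterministic. The rules are mirror-symmetric: flipping all
strands and reflecting coordinates preserves every class (tested).

## Differential expression

With two replicates per condition, a transparent conditional exact
negative-binomial test replaces the black-box GLM machinery:

- **Normalization.** Replicates within a condition share one expression
  profile, so they are equalized by library size (composition-free). The
  between-condition factor is the 35 %-trimmed mean of condition-level
  M-values (log ratio of condition means across genes). At this
  aggregation level differentially expressed genes sit several null
  standard deviations away from the unchanged block, so trimming removes
  them entirely and the offset is anchored on the unchanged majority.
  A plain median (or a per-gene four-sample reference) is biased here: with
  asymmetric DE the median slides inside the wide null ratio distribution,
  which at two replicates shrinks every estimated fold change by up to
  ~0.3 log₂ units. The trimmed construction is valid while each DE
  direction covers < 35 % of the matrix — one reason DE always runs on the
  full coding + lncRNA matrix, never on the lncRNA subset alone (where
  the published down-fraction of 50.5 % would make depth and regulation
  unidentifiable for any normalization).
- **Dispersion.** A single common dispersion φ per line from the pooled
  method of moments, φ̂ = Σ(v−m)/Σm² over genes with mean ≥ 5 and both
  conditions (v, m = within-condition replicate variance and mean),
  floored at 0.01. The pooled form is unbiased and dominated by
  well-measured genes; per-gene estimates at two replicates are far too
  noisy to use individually.
- **Test.** Counts are summed within condition; conditional on the pooled
  total T, the two-sided p-value sums the probabilities of all splits at
  most as likely as the observed one, under sums distributed
  NB(size = n/φ, mean = T/2). Above T = 2000 the enumeration switches to
  the asymptotically equivalent z-test on log(s₂/s₁) with variance
  1/s₁ + 1/s₂ + 2φ/n (the two agree to ~3 decimal places at the
  boundary).
- **Calls.** Genes with normalized mean count below 10 are reported
  untested (independent filtering) and excluded from the per-line BH
  adjustment. Status: up iff p_adj < 0.05 and log₂FC ≥ 1; down for ≤ −1;
  otherwise equal. log₂FC uses normalized means with pseudo-count 0.5;
  all-zero genes get p = 1, log₂FC = 0, equal.

Measured operating characteristics (recomputed by the acceptance script):
type-I error ≈ 0.006–0.009 at nominal 0.05 on 10⁴ Poisson nulls
(conservative, as expected for an exact test with a dispersion floor);
power ≈ 0.93 at log₂FC = 2, mean 200, φ = 0.1; called lncRNA down-fraction
≈ 0.47–0.49 for a planted 0.505 at |log₂FC| = 2. With the generator's
realistic effect-size distribution (|log₂FC| = 1 + Gamma(2, 0.75), see
below) the two-replicate design has ≈ 0.87 down-sensitivity, so called
fractions on fully realistic data sit ~0.07 below the planted
probabilities — an inherent property of two-replicate designs, reported
as-is by the pipeline summary.

## Specificity statistics

Shannon entropy of a gene's relative expression across N samples,
H = −Σ p log₂ p with 0·log₂0 ≡ 0, bounded by [0, log₂N]; all-zero genes
are excluded with a reason rather than assigned H = 0 (H = 0 means
*maximally specific*, the opposite of *absent*). A gene is *specific to
group G* iff expressed (FPKM ≥ 0.1, inclusive) in at least one sample of G
and in zero samples of the complement; an `all`-replicates rule is
available by flag. Housekeeping genes are those expressed in every sample
with a coefficient of variation ≤ 0.3.

Contingency tests are Pearson χ² without continuity correction by default:
the published tables have 10³–10⁵ counts per margin, where the correction
is immaterial. For small tables the `correction=True` mode applies Yates'
correction, which is the variant that tracks the conditional (fixed
margin, hypergeometric) permutation null within 0.02 at n = 40 — the
uncorrected statistic cannot, since its continuous reference distribution
ignores the discreteness that dominates small tables. The up-vs-down
contrast within one gene class is a χ² goodness of fit of (n_up, n_down)
against equal proportions.

Percentages are printed with half-up rounding, one decimal generally and
two decimals below 10 %, matching the published precision.

## Recombination and association

Gene–fragment overlap requires ≥ 1 shared base (configurable); fragments
are unstranded. Multiplicity is *single* iff fragments of exactly one RIL
hit the gene — replicates of one line never count as multiple. Enrichment
reports, per biotype, both the proportion of fragment-overlapping genes
that are offspring-specific and the single/multiple proportions, each with
its χ²; tiny inputs are flagged underpowered instead of silently tested.

Expression matching for SNP-density controls is greedy nearest-neighbour
on mean log(FPKM+1) without replacement, targets processed in decreasing
expression order; match quality (mean |Δ|) is reported. SNP-in-gene uses
the gene span, not exons. Genotype–trait comparisons drop missing
genotypes, require ≥ 2 classes with ≥ 2 lines, and use Welch's t-test for
two classes (no variance-homogeneity assumption) or one-way ANOVA for
three, with significance stars at 0.05/0.01/0.001.

## Metagene profiles

Layout: 1 kb flanks in 20 fixed 50-bp bins each, gene body
length-normalized into 40 bins (defaults; all exposed). The published
analysis states only the 1-kb flanks; bin counts are this package's
explicit configuration, not a reproduction target. Coverage is held as a
step function with an exact continuous cumulative integral, so body bins
of genes shorter than the bin count are fractional averages, not errors,
and bin means are exact (no per-base materialization). Minus-strand genes
are reversed so profiles read 5′→3′; profiles are linear in gene sets
(the union profile is the count-weighted mean, tested exactly).
Transcript-space m⁶A profiles concatenate exons 5′→3′ before binning, so
intronic signal cannot leak into the profile.

## Co-expression and ceRNA networks

The weighted co-expression workflow is deliberately simplified to its
load-bearing parts: signed adjacency a = ((1+r)/2)^β with β = 6,
dissimilarity 1−a, average-linkage hierarchical clustering cut at a fixed
height (0.9), clusters below the minimum size pooled as grey. The
soft-threshold scan, topological overlap and dynamic tree cutting are
intentionally out of scope; the validated surface is planted-structure
recovery (two planted blocks are recovered with Rand index 1), not
reproduction of any particular module count. Genes are canonicalized by id
before clustering, making the partition invariant to input row order.

The module eigengene is the first principal component of the standardized
member expression (unit variance, sign fixed so mean gene–eigengene
correlation ≥ 0). Module–trait and MM–GS statistics are Pearson
correlations with t-test p-values. **Caveat:** the MM–GS p-value treats
member genes as independent observations; inside a coherent module they
are not, so under a null trait the |cor(MM, GS)| > 0.3 flag fires far more
often than its nominal level — a well-known property of this statistic.
The tests therefore calibrate sign symmetry and magnitude under the null
rather than the flag's rate, and downstream interpretation should lean on
the module–trait correlation, not MM–GS alone.

ceRNA assembly validates interaction types against
{cleavage, translation_inhibition, mimic}, deduplicates typed edges, and
emits a bridge triple (ncRNA, miRNA, mRNA) iff both the ncRNA–miRNA and
miRNA–mRNA edges exist — equivalent to the brute-force join, against which
it is tested exactly. Plain pandas joins implement this; a graph library
would add nothing.

## Synthetic-data generator

The generator's defaults are the study conditions, fixed once:

- **Annotation** — 1200 coding genes and 250 lncRNA genes on 2
  chromosomes (auto-sized; a fixed genome that cannot hold the request is
  an error). Coding genes: length log-normal (median 2.5 kb, capped
  0.4–15 kb), 1+Poisson(3) exons. lncRNAs: median 700 bp (250–2000),
  single-exon with probability 0.823, and exon layouts constructed so the
  spliced length always exceeds 200 nt (a true lncRNA must be able to pass
  its own length filter). Positional classes planted at
  90.1 % intergenic, 4.6 % antisense, 3.7 % divergent, and the remaining
  1.6 % split intronic / sense-overlapping; placement geometry guarantees
  each planted class is recovered by the classifier's definitions, so
  classification is graded against an exact truth.
- **Expression** — baseline FPKM log-normal with lncRNA location e^0.5 ≈
  1.6 an order of magnitude below coding e^2 ≈ 7.4 (σ_log = 1); counts
  negative-binomial with dispersion 0.1 (housekeeping 0.01) around
  FPKM × length(kb) × depth × size-factor means, depth 150 (a median
  lncRNA receives ~150 counts, deep sequencing), size factors fixed per
  sample in U(0.7, 1.3); FPKM is derived back from counts. Per gene × line
  DE labels follow the published class proportions (lncRNA up/down/equal
  0.389/0.505/0.106, coding 0.214/0.298/0.488); planted
  |log₂FC| = 1 + Gamma(2, 0.75) (mean 2.5, zero density at the calling
  threshold, matching the broader lncRNA fold-change spread). 19.2 % of
  lncRNAs and 8.1 % of coding genes are line-specific, planted on RILs
  only (the study observed almost no parent-specific lncRNAs); 50
  housekeeping genes are uniform everywhere. Three planted co-expression
  modules of 60 genes share a per-line drought response (σ = 0.25 jitter)
  plus a latent per-sample factor; the survival trait is driven by the
  first module's realized profile (loading 0.7).
- **Tracks** — per mark and condition, signal near each gene = body level
  + strand-aware Gaussian peak (σ = 150 bp) at the TSS, or inside the
  3′-most exon for m⁶A on mRNAs (lncRNA m⁶A peak 0), scaled by
  (1 + ws_shift) under WS; activating marks (H3K4me3, H3K9ac, H3K27ac)
  peak higher on coding than lncRNA genes and shift down under drought,
  H3K9me3/H3K4me1/H3K36me3/m⁶A shift up, DNA methylation is higher on
  lncRNA bodies. 50-bp bins, Gaussian noise σ = 0.05, emitted as bedGraph.
- **Population data** — 1320 recombination fragments (log-normal length,
  median 20 kb) over the RILs, 30 % anchored on genes specifically
  expressed in the fragment's line (lncRNA-weighted 3:1), planting the
  offspring-specific excess at recombination sites. 2000 SNPs over a
  120-line association panel (HWE genotypes, 2 % missing), 10 planted
  inside lncRNA loci with additive effects on survival and association
  p = 10^−U(6,12); all other SNPs null U(0,1) for both survival and the
  kernel-oil negative-control trait.
- **miRNA tables** — planted lncRNA–miRNA–mRNA bridges (occasionally with
  a circRNA sharing the miRNA) plus distractor edges whose miRNAs are
  private to one RNA class and therefore can never bridge.

Everything is deterministic under the seed; each generator stage draws
from an independently derived RNG stream, so toggling one stage never
perturbs another. Planted truth is returned (and written as sidecar
tables) for tests only; the pipeline never reads it.

**What the generator does not emulate:** read-level noise and mapping
artifacts (no FASTQ), sequence content, linkage disequilibrium and
population structure in the SNP panel, inter-gene correlation beyond the
planted modules, batch effects, and length biases in FPKM estimation.
Passing tests therefore demonstrate correctness of the statistical
machinery on data satisfying its assumptions, not robustness to every
artifact of real sequencing data.

## Problem sizes

The default demo (1200 coding + 250 lncRNA genes, 64 samples, all stages)
runs in well under a minute on one CPU; the DE null calibration uses 10⁴
genes, power and recovery checks 2.5×10³–2×10⁴ genes, and the permutation
oracle 10⁵ draws — sizes chosen so every recomputed statistic has a
standard error small relative to the band it is checked against.

## Known limitations

- Two replicates bound DE sensitivity (~0.87 for the realistic effect-size
  mixture); absolute DE counts from the source study are not reproduction
  targets.
- The trimmed-M normalization assumes < 35 % of genes DE per direction in
  the analyzed matrix.
- The exact NB test uses a single common dispersion; no empirical-Bayes
  moderation.
- Module detection has no topological-overlap smoothing; very diffuse
  modules fragment into grey.
- MM–GS significance is anticonservative under the null (above).
- Greedy expression matching is order-dependent by construction; the
  decreasing-expression processing order makes it deterministic and keeps
  mean |Δ| small, but it is not globally optimal matching.
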