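# lnck — drought-responsive lncRNA analysis for maize RIL populations

`lnck` re-implements, as a tested and reusable pipeline, the computational
analysis used to characterize drought-responsive long noncoding RNAs
(lncRNAs) in the roots of a maize biparental population: a drought-tolerant
parent, a drought-sensitive parent, and their recombinant inbred lines
(RILs), each profiled under well-watered (WW) and water-stressed (WS)
conditions with two replicates. It is written for computational biologists
who want each stage of such a study — identification, classification,
expression statistics, enrichment tests, epigenetic profiling, network
assembly — as a documented, unit-tested library function rather than a
collection of one-off scripts.

## What it computes

**Identification cascade.** Transcripts are retained as high-confidence
lncRNAs only if they pass, in order: (1) a noncoding consensus of two
coding-potential predictors; (2) no successful protein-database hit, where a
hit succeeds iff identity ≥ 65 %, aligned length > 30 aa and E ≤ 10⁻⁹;
(3) no evidence of translation (RNC-seq abundance ≤ 0.1); (4) spliced length
> 200 nt with RNA-seq abundance above 0.1.

**Positional classification.** Each lncRNA gene is assigned exactly one
class relative to the coding annotation, with precedence
antisense > intronic > sense-overlapping > divergent > intergenic; divergent
means a head-to-head TSS within 2 kb of a coding gene.

**Expression statistics.** WS-vs-WW differential expression per line uses a
conditional exact negative-binomial test (two replicates per condition;
dispersion by pooled method of moments, floored at 0.01), with
Benjamini–Hochberg correction; a gene is *up* iff p_adj < 0.05 and
log₂FC ≥ 1, *down* for ≤ −1. Expression specificity is Shannon entropy over
a gene's relative expression across samples,

    H(X) = − Σₓ P(x) log₂ P(x),   0 ≤ H ≤ log₂ N,

so a uniformly expressed (housekeeping) gene across 16 lines sits at
H = log₂ 16 = 4 bits, and a line-specific gene at H = 0. Contingency
comparisons are Pearson χ² (Yates correction optional), proportions are
printed at the published precision.

**Recombination & association.** Gene loci are intersected with
GBS-derived recombination fragments per RIL (1-bp minimum overlap,
single/multiple-line multiplicity), and the proportion of
offspring-specific genes among fragment-overlapping loci is compared
between lncRNAs and coding genes by χ². Trait-associated SNP density
(significant SNPs per kb of gene span) in lncRNA loci is compared against
coding controls matched on mean log(FPKM+1) by greedy nearest-neighbour
matching; per-SNP genotype–trait differences use Welch's t (2 genotype
classes) or one-way ANOVA (3).

**Epigenome profiles.** Strand-aware metagene profiles (1 kb flanks in
fixed bins, length-normalized gene body) of histone marks, DNA methylation
and m⁶A coverage, plus spliced-transcript profiles that recover
stop-codon-proximal m⁶A peaks without intron contamination.

**Networks.** A transparent simplification of weighted co-expression
analysis: signed adjacency ((1+r)/2)^β, average-linkage clustering at a
fixed cut height, module eigengene = first principal component, and the
module-trait / module-membership (MM) / gene-significance (GS)
correlations. The ceRNA network joins lncRNA/circRNA–miRNA and miRNA–mRNA
edge tables on their shared miRNA bridge.

**Synthetic data.** `lnck.simulate` generates every input the pipeline
reads (GTF, count/FPKM matrices, BED fragments, bedGraph tracks, SNP and
miRNA-target tables) with planted ground truth — positional classes, DE
labels, decoy transcripts that each violate one cascade stage, TSS peaks,
trait-associated SNPs, miRNA bridges — so every stage is validated by
truth recovery, without any external download.

## Worked example

Run the full demo pipeline (simulate + every stage) and inspect the
summary:

```
$ lnck all --seed 1 --out demo
summary written to demo/summary.json
```

With the default configuration (1200 coding genes, 250 lncRNAs, 16 lines ×
2 conditions × 2 replicates) the summary reports, among other things:

```
identify.per_stage_counts      [["noncoding_consensus", 325], ["no_protein_hit", 300],
                                ["not_translated", 275], ["length_and_abundance", 250]]
identify.cascade_stage_accuracy        1.0
identify.positional_class_recovery     1.0
expression.offspring_specific          {"lnc_pct": 19.2, "coding_pct": 7.75}
recombination.specific_proportion_pct  {"lncRNA": 19.5, "coding": 8.6}
recombination.specific_p               4.8e-07
cerna.planted_bridges_recovered        13 of 13, 0 spurious
```

Reading: the cascade eliminated each planted decoy at exactly its planted
stage and kept all 250 true lncRNAs; every planted positional class label
was recovered; offspring-specific expression is about 2.5× more frequent
among lncRNAs than coding genes, and that excess concentrates at
recombination sites (χ² p ≈ 5·10⁻⁷) — the qualitative structure the
generator plants, recovered end to end. The run is fully deterministic
under `--seed`; rerunning writes a byte-identical summary.

Individual stages are also exposed as subcommands (`lnck identify`,
`lnck de`, `lnck entropy`, `lnck specific`, `lnck recomb`,
`lnck profiles`, `lnck assoc`, `lnck network coexpr`, `lnck network
cerna`, `lnck io validate`) operating on the plain-text formats above.

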