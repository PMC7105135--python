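# Methods

This note documents the models, the synthetic study the package
simulates, the numerical choices, and the limits of what the test suite
demonstrates.

## Study design being emulated

Two insect lines share a nuclear genome after repeated backcrossing: the
paternal (introgressed) background with either the maternal cytoplasm's
*Wolbachia* infection retained or removed by antibiotics. Three infected
and three cured clonal replicate lines are profiled with WGBS and
RNA-seq. All inputs to this package are post-alignment tables: genotype
calls at parental diagnostic SNPs, per-strand CpG cytosine counts with a
lambda spike-in, a GFF3 annotation, and gene/exon count matrices.
Alignment, trimming, genotype calling and GO annotation are upstream
tools' work and out of scope.

## Introgression mapping

Genotype calls are kept when homozygous with depth ≥ 10 and quality
≥ 30 (defaults exposed in `PipelineConfig`). A call equal to the
maternal (resp. paternal) panel allele is maternal (paternal); anything
else, including positions off the panel, is unclassified. Maternal
blocks are maximal chains of maternal SNPs in which consecutive SNPs are
at most `threshold` apart (default 10 000 bp; 2 000 bp is the reported
alternative) with no paternal SNP strictly between them. Design
choices, made because the source procedure leaves them open:

- block ends sit exactly on the outermost maternal SNPs (no padding);
- an intervening paternal SNP always terminates a chain, even within the
  threshold distance;
- unclassified positions neither extend nor break chains;
- coordinates are 1-based inclusive internally, BED output is 0-based
  half-open;
- the mask applied by the pipeline is the union of all samples' blocks.

Singleton chains yield 1-bp blocks. The chaining is checked against an
exhaustive per-pair oracle on all random inputs of ≤ 20 SNPs and is
order-independent and monotone in the threshold (more threshold, never
more blocks, never less maternal bp).

## Methylation calls

A CpG unit is the plus-strand C at p paired with the minus-strand C at
p+1; counts are summed onto p, conserving totals exactly; a minus-strand
C without partner is kept as its own unit at p−1 and logged. The
conversion error e is the pooled methylated fraction of the unmethylated
lambda spike-in (warning below 99.8% efficiency), estimated per sample.
Site status is a one-sided binomial tail test at rate e with BH at 0.05
per sample — a reimplementation of the methylated/unmethylated dichotomy
consumed downstream; whether the original classifier pooled error rates
across samples is unknown, so per-sample rates are the default.
Gene-body methylation is the unweighted mean CpG fraction over the full
annotated gene span (introns included, strand ignored); the
condition-level value is the unweighted mean of replicate fractions.
Genes are labeled methylated strictly above 0.004.

## Differential methylation

Sites methylated in ≥ 1 of the six samples are testable. Counts follow
a beta-binomial with logit mean β₀ + β₁·infected and one per-site
overdispersion ρ ∈ (10⁻⁸, 1−10⁻⁸) shared between conditions and models.
Because the only predictor is two-level, the mean structure is saturated
per condition; the likelihood is therefore maximized by profiling: a
coarse grid then golden-section search over s = logit(ρ) (φ = e^{−s}),
with the per-group logit means maximized at every s by safeguarded
Newton ascent, clamped to ±15 to handle quasi-separation (an all-0
vs all-n site yields LRT = −12·log 0.5 ≈ 8.32, not a divergent
statistic: the bounded-ρ null can place its mass on {0, n}). This
replaces the original plan of a 3-start quasi-Newton on the joint
parameter vector; it is the same maximum-likelihood problem solved more
robustly and ~10× faster, and it agrees with an independent Nelder–Mead
/ `scipy.stats.betabinom` oracle to ~10⁻⁴ in the LRT.

The infection effect is a 1-df LRT against chi-squared. Untestable sites
(< 2 covered samples in a condition) are excluded from the BH
denominator. DMPs are sites with Q strictly below 0.05; the hyper/hypo
split is tested against 50:50 by a 1-df χ² without continuity
correction. DMPs inside any gene span are genic (credited to every
overlapping gene); intergenic DMPs go to the gene with the nearest span
boundary, ties to the lower-coordinate gene (logged).

Calibration, measured by simulation (`wolbmeth.calibration`): with three
replicates per condition the chi-squared reference is imperfect — under
a binomial-given-fraction null the test is conservative (≈ 0.039 at
nominal 0.05, flat in depth from 30 to 2000), and downstream of the
data-dependent testable-site selection it is mildly anti-conservative
(≈ 0.06). Both behaviors were confirmed with an independent
implementation of the same model; they are properties of the estimator
at n = 6, not of this code. BH discovery control on null data and power
(≥ 0.9 at a 2-logit shift, depth 30) are unaffected.

## Differential expression and exon usage

Size factors are median-of-ratios against the geometric-mean reference
over genes with no zero count. Each gene is an NB GLM with log link and
log size-factor offsets; the condition mean structure is again saturated
and fit by Fisher-scoring Newton. Dispersion: per-gene Cox–Reid adjusted
profile ML (grid + golden section on log r), then pooled across genes by
fitting α(μ) = a₀/μ + a₁ with relative-error (gamma-family style) IRLS
and 15-fold outlier trimming; the LRT is evaluated at the trended
dispersion. The pooling is the deliberate deviation from a fully
per-gene fit: with 6 observations the per-gene ML dispersion is noisy
enough to make the plain LRT badly liberal (type-I ≈ 0.13), and absolute-
error trend fitting is unstable under the heavy right tail of dispersion
estimates; the trended test is calibrated (0.045–0.056 across seeds at
2 000 genes) with log2-fold-change bias ≈ 0.01 at truth 2. No Cook's
outlier handling or fold-change shrinkage.

Fold-change summaries average on the linear scale (the down set reported
as mean fold lower); log2 values are emitted alongside.

Exon usage conditions on per-sample gene totals: the exon count is NB
with offset log(gene total) and a condition coefficient, the 1-df LRT
of which tests a condition-dependent exon share; this absorbs the
"sample" main effect of the usual exon-usage formula. The interaction
coefficient is reported in log2. Exons of single-exon genes, all-zero
exons, and exons whose gene total is positive in fewer than two samples
of a condition are untestable and excluded from the BH denominator; a
sample with zero gene total contributes nothing to the likelihood.
Library size cancels by construction, so the size-factor argument is
accepted but unused there.

## Transcriptional noise

Noise is 100·SD/mean (SD with n−1) of size-factor-normalized counts over
a condition's replicates, one observation per gene × condition — the
infection status must vary within gene for the model to estimate its
coefficient. Records with zero mean or zero SD are excluded from the
log-scale model with counts reported. The model is OLS of log10(CV) on
gene-body methylation (condition-matched), log2(mean normalized count),
log10(gene length) and an infected indicator; per-condition simple
regressions of log10(CV) on log2(expression) and a two-sample t-test on
log10(CV) accompany it. Rank deficiency raises an error naming the most
collinear column pair. Gene-class expression comparisons use a one-way
ANOVA on log2 means with Tukey HSD post-hocs; classes with < 2 members
are dropped with a warning.

## Synthetic data generator

One global seed expands into named substreams (CRC-keyed
`SeedSequence`s), so each stage regenerates independently and re-runs
are byte-identical. Defaults are the study conditions: 3+3 replicates;
2 chromosomes × 1 Mb with 300 genes and 6 000 CpGs; maternal truth
blocks covering ~5% of the genome (95–99% replaced); conversion error
0.002 with a lambda spike-in; WGBS depth mean 60 per CpG (the study
reports 100–200 M read pairs per sample — "exceptional depth" — scaled
to a desk-size genome), split binomially between strands; a bimodal
methylation landscape (30% of genes methylated, high mode Beta(8, 2);
unmethylated mode Beta(0.2, 150), i.e. near zero so that observed
fractions of unmethylated genes are dominated by conversion error and
fall below the 0.004 threshold); 1% of CpGs carry a ±2-logit infection
effect, 70% hyper; 5% of genes DE with |log2FC| ~ N(1.5, 0.5²) and 76%
up; NB expression with dispersion law 2/μ + 0.05 and cured-condition
dispersion inflated 1.5× (the noise phenotype); 5% of multi-exon genes
have one exon's share doubled in infected samples, exon counts drawn
multinomially so they sum exactly to gene counts.

Features of real data deliberately not emulated: read-level error,
PCR duplicates, genotype misclassification (available but defaulted to
0), correlation between methylation and expression levels, and any
mechanistic coupling of gene-body methylation to expression noise — so a
passing noise-model test demonstrates coefficient recovery and
directionality, not the biological effect itself. Because hyper effects
on the high-methylation mode push fractions toward 1 (boundary
compression), called DMPs can under-represent the configured 70% hyper
bias even though the truth matches it; the direction-split arithmetic is
therefore checked on the printed tallies, not on the generator.

## Benchmark problem sizes

The simulation benchmarks in `wolbmeth.calibration` (used by the test
suite and `scripts/acceptance.py`) run at sizes chosen to keep the whole
suite in a few minutes: 50 masking genomes of 1 Mb (blocks 80–150 kb,
diagnostic SNPs every ~1 kb — above the 1-per-2-kb density the mapper is
specified for); type-I error at 10 000 null sites; FDR over 12 null
replicates of 2 000 sites; power at 2 000 sites (~500 effect sites);
2 000 null genes and 200 recovery genes for expression; 100–200 noise
simulations of 5 000 records; 2 000 chaining-oracle cases and 1 000
Fisher tables. Monte-Carlo error bands are computed at the sizes
actually run.

## Known limitations

- The beta-binomial and NB LRTs rely on chi-squared asymptotics that a
  3-vs-3 design does not fully deliver (see calibration notes above);
  the expression side is repaired by dispersion pooling, the methylation
  side retains a known ±20% distortion of nominal type-I error.
- No spatial combination of neighboring CpG p-values and no
  differentially-methylated-region calling: the testing unit is the
  single CpG.
- The exon-usage reduction tests each exon against the rest of its gene
  independently; a gene-wide share reallocation spreads signal across
  its exons (compositional coupling).
- Fisher odds ratios are sample odds ratios with a labeled Haldane 0.5
  correction on zero cells, not conditional MLEs.
- GO-style enrichment operates on generic term maps; no ontology
  parsing or graph propagation.
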