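# Methods

## Scope and data model

The package selects hepatic biomarker genes for interindividual variability
in the omega-3 (DHA/EPA) response from four inputs: a treated
primary-hepatocyte count matrix (vehicle/DHA/EPA/OA), two population
expression cohorts (a general liver cohort and a fatty-liver disease
cohort), a donor panel of treatment/vehicle fold changes, and exosomal
alignments from a liver-humanized mouse against a combined human+mouse
reference. Gene-level counts are the entry point throughout: read QC,
alignment and feature counting are out of scope, as are live pathway
databases (enrichment runs against user-supplied GMT collections) and any
wet-lab processing.

## Differential expression

Each contrast is tested with a per-gene negative-binomial GLM
(variance = μ + φμ², log link, log library-size offset, group indicator),
fitted by vectorised Newton scoring across all genes simultaneously.
Dispersion is a method-of-moments estimate on counts rescaled to the mean
library size, `(s² − m)/m²` per group, clipped at zero, averaged across the
two groups and floored at 10⁻⁸. There is no dispersion shrinkage, Cook's
filtering or independent filtering: the downstream selection logic needs a
*calibrated* test, not a DESeq2 reproduction.

The Wald statistic is referred to a **t distribution with residual degrees
of freedom** (n_samples − n_coefficients). With a handful of replicates the
plug-in dispersion makes the usual normal reference anticonservative
(≈0.08 empirical type-I error at nominal 0.05 with n = 5 + 5 in our null
simulations); the t reference restores calibration (0.04–0.06 across
seeds), which the test suite asserts. A normal reference remains available
(`reference="normal"`).

Genes with zero counts in both groups get p = 1 and log2FC = 0 (flagged
degenerate). Genes with zero counts in exactly one group keep the
model-based test but report a log2FC from 0.5-pseudo-counted group totals,
avoiding infinite point estimates. Technical replicates are summed before
testing (sums preserve the NB model); a mean mode exists for comparison.
Categorical covariates enter as indicator columns; continuous covariates
are out of scope.

Calls are strict: `up` iff log2FC > threshold *and* padj < α. A coding gene
at exactly log2FC = 0.2 is not called. BH adjustment wraps
statsmodels' `multipletests`; the tests pin it against a literal step-up
implementation.

## Filtering conventions

"Fewer than half the samples" is read inclusively on the retention side: a
gene is kept when CPM ≥ threshold in at least ⌈frac·n⌉ samples, so exactly
half retains, and a CPM exactly at the threshold passes. `other` biotypes
use the coding threshold (conservative). Samples under 10⁶ aligned reads
can be dropped before CPM (`remove_shallow_samples`). The variance
flattening before PCA is log2(CPM+1): PCA here is a visual sample overview,
for which any monotone flattening transform serves.

## Variability and validation

CV is computed on the CPM scale (not log — that is a different statistic)
with the n−1 sd. Strata are the top/bottom quantile of the CV distribution
among expressed genes; the quantile width defaults to 0.25 (the analysis
speaks of top/bottom quantiles without fixing the width; quartiles are the
configurable default). Stratum sizes are exactly ⌊q·n⌋ with boundary ties
broken by ascending gene id. Cross-cohort stratum membership requires the
same stratum in *both* cohorts (single-cohort use is just passing one
table). The validation uses a two-sided Welch t-test by default
(`equal_var=True` recovers the classical Student test) and a Pearson
correlation with t-distribution p (df = n−2).

OA subtraction is any-direction: an OA call in either direction disqualifies
a gene from the signature classes (the stricter reading). DHA/EPA
direction-discordant genes stay in `DHA_and_EPA` with a `discordant` flag —
the class algebra is set-membership only. Representative pathways rank by
nominal p < 0.05 support (adjusted-p mode by flag; both values are always
emitted), ties by ascending median p, then name.

Exosome origin assignment operationalises "human-specific" as
best-score-exclusively-human; equal best scores on both genomes are
ambiguous and dropped. Reads hitting several genes at their best score are
split fractionally (1/n per gene), preserving read-count conservation.
Detectability uses raw read counts (the stated ranking basis), keeping the
top ⌈0.2·n⌉ genes, ties by gene id.

## The synthetic cohorts

All generators share a per-seed *gene universe* (ids, biotypes, baseline
means, dispersions, planted fold changes, planted CVs, module structure),
drawn from independent, order-stable RNG streams, so every cohort is
mutually consistent and every output is a pure function of
(SimSpec, rng_seed).

Defaults (the study conditions):

* 2000 genes, 20% lncRNA, 15% silent (baseline far below the CPM
  threshold, so the expression filter is genuinely exercised), 5
  replicates per condition, library sizes log-normal around 10⁶.
* Baseline means log-normal (ln-scale mean 4.5, sd 1.2) at 10⁶ depth;
  dispersion trend φ = 0.02 + 2/μ.
* Planted response classes by explicit quota so every region of the
  DHA/EPA/OA Venn diagram is non-empty (60/60/40 singles, 80 DHA∩EPA,
  30/30 pairwise with OA, 40 triple). Fold-change magnitudes are
  |N(1.0, 0.4)| truncated at 0.25, sign shared across a gene's conditions.
  These defaults are chosen so the DE stage, at five replicates, yields a
  well-populated signature set — emulating a strong fatty-acid treatment;
  smaller placeholder effects (e.g. mean 0.5) leave essentially nothing
  after BH at this design size and are reachable through `SimSpec`.
* Population CVs span 0.05–1.5 log-uniformly. Individual expression is
  log-normal around the gene's baseline with σ = √ln(1+CV²), plus Poisson
  sampling at the individual's depth, so the planted CV is the biological
  CV and the observed CV carries a 1/√mean sampling floor. Signature genes
  are planted into known strata: per-class most/least quotas at extreme
  CVs (most 1.1–1.5; least 0.05–0.065 with boosted depth so the sampling
  floor cannot lift them out), all other responsive genes mid-band
  (0.25–0.5). The default quotas encode most:least ratios of 12× / 7× / 4×
  for DHA∩EPA / DHA-only / EPA-only. The disease cohort jitters the CVs
  (log-sd 0.08) and shifts 30% of gene means.
* Donor panel: ratio = 2^lfc · exp(ε), ε ~ N(0, base + κ·CV²) per donor,
  base = 0.01, κ = 0.15. κ couples population CV to response CV on the log
  scale (ratios stay positive, CVs analytically controllable); κ = 0 is
  the null in which the validation must find nothing.
* Co-expression modules: 6 modules of 2 hub lncRNAs (taken from the
  most-variable signature plants) plus 20 coding genes sharing a latent
  factor with loading √ρ (ρ = 0.85; ~30% of members negatively loaded).
  The √ρ/√(1−ρ) mixture preserves each gene's marginal CV. The gene-set
  generator emits one pathway per module (members plus random padding)
  alongside random sets, so network enrichment has planted positives.
* Exosome mix: 50 000 human reads (10% with a lower-scoring mouse
  secondary alignment), 20 000 mouse reads, 1000 ambiguous reads with
  equal-score alignments on both genomes. Per-gene human abundance weights
  place a known top-quintile set (weights 5–10 vs 0.05–1) whose rank
  separation is far above multinomial noise, so the planted detectable set
  is recovered exactly; the pipeline boosts the most-variable signature
  genes into this set so the final biomarker intersection has known
  content.

What the generator does **not** emulate: GC/length biases, batch effects,
isoform structure, correlated library-size/composition effects,
sequence-level reads (alignment tables are simulated post-mapping), or any
real biological pathway structure. Passing tests therefore demonstrate
correctness of the selection logic and calibration of the statistics under
the stated model — not performance on real cohorts.

## Problem sizes and numerics

The default problem sizes (2000 genes, 4×5 hepatocyte samples, 100+60
population individuals, 10 donors, 71 000 exosomal reads) keep a full
roadmap run around five seconds and the entire test suite under a minute,
while being large enough for stable calibration estimates. Newton scoring
runs at most 60 iterations to step tolerance 10⁻¹⁰ with a 10⁻¹⁰ ridge on
the information matrix and coefficients clipped at ±15 on the natural-log
scale; dispersions are floored at 10⁻⁸; NB sampling falls back to Poisson
below that floor. All TSV output uses a fixed float format so reruns under
one seed are byte-identical.

## Known limitations

* The MoM dispersion is noisy at n = 5; calibration is rescued by the t
  reference rather than shrinkage, so per-gene power is below what a
  shrinkage estimator would give.
* Wald tests are unreliable for genes with zeros throughout one group
  (Hauck–Donner); the reported fold change is pseudo-counted but the p
  value for such genes should not be over-read.
* CV estimates carry a sampling floor of roughly 1/√(mean count); very low
  planted CVs are not distinguishable below it.
* The hypergeometric enrichment treats genes as exchangeable (no
  expression-level or gene-length bias correction).
* Cross-cohort stratum intersection requires membership in every supplied
  cohort; with many cohorts this becomes conservative quickly.
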