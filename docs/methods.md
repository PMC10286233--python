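# Methods

## Scope and data model

The package implements a two-layer screen over SNP data from closely
related diploid cohorts: (1) pairwise genetic differentiation aggregated to
genes and standardized, with QTL colocalization of the candidates, and
(2) population-level allele-specific expression (ASE) per strain × age
group from unphased per-SNP allele read counts, with an intersection layer
connecting the two. Genotypes are held as an alt-dosage matrix
(0/1/2/missing) over biallelic SNPs; gene intervals are 1-based inclusive,
QTL intervals 0-based half-open (BED), and the single conversion pair
`vcf_to_bed_pos`/`bed_to_vcf_pos` owns the coordinate mapping.

## Weir–Cockerham estimator

Per SNP and population pair, the method-of-moments components a (among
populations), b (among individuals within populations) and c (within
individuals) are computed from non-missing sample sizes, alt frequencies
and heterozygote proportions; θ̂ = a/(a+b+c). Choices:

- θ̂ is **undefined** (NaN) when a+b+c = 0 — typically a SNP monomorphic in
  the pooled pair — and such SNPs never enter gene aggregates. SNPs where a
  population has no call, or the mean sample size n̄ ≤ 1, are likewise
  undefined (the scalar entry point raises instead, since calling it on
  such input is a logic error upstream).
- **Negative θ̂ is retained.** Truncating at zero would inflate every gene
  mean and bias the screen's null moments.
- The multi-locus ratio-of-sums estimate Σa/Σ(a+b+c) is exposed both
  genome-wide (run summaries) and as an optional gene-aggregation mode
  (`mode="ratio"`); the default gene aggregate is the arithmetic mean of
  per-SNP θ̂, the conventional gene-based reading.

## SNP retention

Order: call-rate → autosome → pooled-MAF. Call rate is the fraction of
non-missing calls across **all** individuals (boundary inclusive at 0.80).
MAF is computed per comparison pair, pooled over the two populations: a
shared SNP set then yields different monomorphic/low-MAF counts per
comparison, which is the behaviour the ledger is designed to account for.
MAF exactly at the threshold is kept; comparisons use a half-count margin
so integer allele counts at the boundary are not lost to float division.
SNPs with zero non-missing calls in the pair are removed in the MAF stage.
The `FilterLedger` enforces exact integer conservation at construction.

## Gene screen

SNP→gene assignment is interval containment (inclusive ends) via an
interval tree; SNPs under overlapping genes count in each gene. Genes need
≥ 3 defined-θ̂ SNPs. Z-standardization uses the sample (n−1) standard
deviation; a degenerate screen (all gene means equal) raises rather than
emitting zeros. Candidates are Z ≥ 4 (inclusive); the top-1% set takes
exactly ceil(0.01·n) genes ranked by Z descending with ties broken by
gene id, so reruns are reproducible. Colocalization is SNP-level: a
candidate gene is colocalized with a trait category if ≥ 1 of its
contributing SNPs lies inside a region of that category; genes with no
overlap anywhere are emitted once under the pseudo-category "none".

## ASE detection

Per (strain, week, gene): counts pass the per-SNP-per-sample rule (minor
≥ 3 reads, depth ≥ 30, minor ratio ≥ 1%), then fold to (m, d) with
m = max(ref, alt). Individual j's pooled folded fraction is
p̂_j = Σ_s m_s / Σ_s d_s ≥ ½, and its deviance against the balanced null is
2[Σ m ln p̂_j + Σ(d−m) ln(1−p̂_j) + Σ d ln 2] (0·ln 0 := 0, handled by
`xlogy`); the gene statistic T sums individuals and is nonnegative because
p̂_j is the maximizer. The null distribution is obtained by redrawing each
accepted cell as Binomial(d, ½), folding identically, and recomputing T;
p = (1+k)/(1+R) with k the exceedances among R resamples, a valid p-value
by construction. The adaptive rule processes batches (default 1,000) and
stops once 50 exceedances accumulate (relative SE of p̂ ≈ 14%) or R_max
(default 10,000) is spent; calls at the 0.05/0.01 thresholds are
unaffected by the cap because the smallest attainable p, 1/(R_max+1), is
far below both. Each gene × group owns an RNG substream keyed by (seed,
strain, week, gene), and cells are put in canonical (individual, position)
order first, so p-values are independent of evaluation order and row
order. Benjamini–Hochberg q-values (via `statsmodels`) are computed within
each (strain, week) group; `significant_05` means p < 0.05 (the reporting
convention of the intersection layer) and `significant_01` means p < 0.01
with q < 0.05.

The statistic is a deliberate surrogate for mixed-model ASE detectors: it
shares their inputs, filters, unphased treatment and decision thresholds,
and is exactly calibrated under the balanced-binomial null. With true
per-individual random effects centred at ½ (τ > 0, π = ½) it rejects more
often than the nominal level — the composite null is not its null — which
is a documented limitation, not a bug; the generator's τ parameter exists
to exercise exactly that case.

## Intersection layer

Strain-specific at week w means significant in that strain and not the
other at the same week. Per-strain "specific totals" are row sums of the
five per-week counts (a gene recurring across weeks counts each time),
matching the accounting convention of per-week summary tables; the
distinct-gene count is emitted alongside. "Common across weeks" requires
significance at all five weeks; "common both strains" intersects the two.
Overlaps with the top-1% Z(F_ST) set are reported per cell as k/n.

## Synthetic data

- **Genotypes (Balding–Nichols).** Per SNP, ancestral frequency
  ~ U[0.05, 0.95]; each population's frequency ~ Beta(p(1−F)/F,
  (1−p)(1−F)/F); dosages Binomial(2, ·). F is the expectation of
  Weir–Cockerham θ, giving the estimator a closed-form recovery target.
  Defaults emulate the target study design: three cohorts of 90/89/21
  diploids (LB/LSL/BR), baseline F = 0.05 (adjacent commercial lines),
  planted genes at F = 0.5, 5% missingness, 2.65% of SNPs relocated to
  Z/W contigs. Genes are tiled round-robin over ten autosomes, 8 SNPs per
  gene by default: strongly diverged SNPs frequently drift near fixation in
  *both* populations and are then removed by the pooled-MAF rule, so genes
  need enough SNPs that ≥ 3 survive; real RNA-seq-derived screens carry
  ~30 SNPs per gene, and 8 is the desk-scale compromise that keeps planted
  genes detectable without inflating runtimes.
- **QTL regions.** Contigs chosen proportional to length, uniform starts,
  Exponential lengths (mean 200 kb) clipped to the contig, categories
  uniform over the six trait labels.
- **ASE counts.** Per gene/group/individual: allelic fraction
  logistic(logit(π) + N(0, τ²)); per SNP: depth ~ Poisson(mean 50, floored
  at 1), alt ~ Binomial(depth, fraction). Poisson (not negative-binomial)
  depth keeps the null calibration test exact; overdispersion enters only
  through τ. Unphased data are emulated by swapping each (SNP, individual)
  cell's ref/alt labels with probability ½ — per cell rather than per SNP,
  because the phase of a regulatory allele relative to the reference
  differs between individuals; folding is invariant to the swaps either
  way (property-tested).
- **Randomness.** One master seed feeds named substreams
  (cohort/qtl/ase/ase_test) via `SeedSequence`, so stages are reproducible
  independently and in any order.

What the generator does **not** model: linkage disequilibrium within
genes, read-level error or mapping bias, reference bias in ASE counts
(assumed removed upstream, as by N-masked realignment), shared eQTL
structure between strains, or correlated ages within individuals. Passing
tests therefore demonstrate correctness of the estimators and accounting
under the stated generative models, not robustness to those real-data
effects.

## Problem sizes and numerical choices

The test suite and acceptance script run desk-scale configurations chosen
by the package: cohorts of 2×50 for estimator recovery (5,000 SNPs, 20
seeds, target band 0.17–0.23 around F = 0.2), 1,000 null genes and 200
imbalanced genes for ASE calibration/power at R_max = 2,000, and small
(≈25-gene) end-to-end runs for byte-level determinism checks. Exceedance
comparisons use an absolute tie tolerance of 1e−9 on T to absorb float
noise between the scalar and batched code paths; Z-transform identities
are asserted at 1e−12. Degenerate inputs fail loudly: F ∉ (0,1) in the
generator, σ = 0 in the Z-transform, empty gene maps, R_max below one
batch, p-values outside (0, 1] in the BH step.
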