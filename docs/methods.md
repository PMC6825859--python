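# Methods

## Problem and model

`exoprev` analyses a jointly genotyped exome cohort in three steps.

**Variant spectrum.** Variants are tabulated by functional impact
(HIGH/MODERATE/LOW/MODIFIER, as assigned by an effect annotator upstream)
and by novelty (presence of an rsID). Excess novelty among high-impact
sites is tested with a chi-square on the 2×2 table (high-impact vs rest) ×
(novel vs known), without continuity correction — the counts this test is
meant for are in the tens of thousands, where Yates' correction only
biases the statistic. Call quality is regressed (OLS) on a novelty
indicator and the observed alternative allele frequency to check that
novel calls are not systematically lower-quality artifacts. Concordance
with a reference panel is the R² of cohort AF on panel AF over sites with
panel mean coverage ≥ 15×; population relationships are summarised by PCA
of the populations × variants AF matrix and by the per-population RMSD of
allele frequencies.

**Allele enrichment.** A candidate pathogenic allele is one annotated
pathogenic, with autosomal-recessive inheritance, rare in the whole
reference panel (AF < 0.5% by default), observed at least once, and
strictly heterozygous in the curated cohort (a homozygote would indicate
an affected individual or an annotation problem, and would also break the
carrier-count identity used later). Over-representation relative to a
comparison population is scored with the one-sided upper-tail binomial
test

    p = P(X ≥ n),  X ~ Binomial(N, q_ref)

where n is the observed alternate allele count, N the number of called
chromosomes at the site (2 × non-missing genotypes, not 2 × samples), and
q_ref the comparison population's AF. The tail is evaluated through the
binomial survival function; no normal approximation is used, so the test
is exact and conservative for discrete counts. No multiple-testing
correction is applied to the reported p-values (they are descriptive
rankings, not a discovery screen); a Benjamini–Hochberg column is emitted
alongside for users who want one.

**Carrier frequency and disease incidence.** Pathogenic allele counts are
summed per gene over the curated set; genes with fewer than 4
observations are dropped (too unstable to report). Because every
contributing variant is strictly heterozygous, the gene's allele count
n_g equals its carrier count, so the carrier frequency is c = n_g/N_ind
over individuals while the cumulative pathogenic allele frequency is
q = n_g/(2·N_ind) over chromosomes. Under Hardy–Weinberg equilibrium and
full penetrance the autosomal-recessive disease incidence is q². Interval
estimates use the Wilson score interval for the carrier proportion; the
incidence CI is obtained by halving and squaring the carrier bounds,
which keeps the three printed quantities (c, q, q²) mutually consistent.
A parametric-bootstrap incidence CI (resampling carrier counts
binomially, seeded) is available as an alternative.

## Confidence-interval choices

The Wilson score interval (no continuity correction) is the default
everywhere a binomial proportion is reported. It behaves well at the
small counts this analysis lives on (n of 2–13) and, unlike the Wald
interval, cannot produce negative bounds. Clopper–Pearson ("exact") is
available behind `ci_method="clopper-pearson"`; it is wider in the
interior of the count range. The RMSD confidence interval is a t-interval
for the mean of squared per-site AF differences with square-rooted
endpoints (lower clamped at 0); a seeded site-resampling bootstrap is the
alternative. Whether uncertainty should be propagated over sites or over
samples is genuinely ambiguous for an AF-level RMSD; over sites is the
choice here because the cohort AFs enter as fixed per-site summaries.

## Sample curation

Filters run in a fixed order — phenotype eligibility, declared-relative
pruning, heterozygosity QC — because the result can differ under
reordering (a relative removed first never enters the heterozygosity
median). Relatedness is declared metadata: one sample per non-empty
relatedness group is kept, preferring the highest genotype call rate,
then the lexicographically smallest id. The heterozygosity screen is
one-sided: samples with het fraction h > median(h) + k·MAD(h) are
flagged, k = 4 by default. MAD is the raw (unscaled) median absolute
deviation; with k = 4 this sits at roughly 2.7 normal SDs, a deliberately
permissive cut that in the simulated conditions flags inflated samples
(het probability ×1.5 or more) while keeping the false-positive rate
under 1%. Samples with zero called genotypes are flagged under a distinct
reason rather than silently dropped.

## Synthetic cohort generator

The generator exists so that every downstream estimate has a
parameter-recovery test against known truth. Its model:

- **Reference panel.** Each variant's ancestral AF p is Beta(0.2, 1.8)
  (rare-skewed, as exome site-frequency spectra are), clipped away from
  {0, 1}. Population AFs follow the Balding–Nichols parameterisation:
  Beta with mean p and variance F·p(1−p), one divergence parameter F per
  population (defaults 0.01, 0.05, 0.08, 0.12, 0.2). F = 0 collapses to
  the ancestral AF exactly. Per-variant panel mean coverage is bimodal so
  that a configurable fraction (default 10%) fails the 15× filter.
- **Cohort.** 372 diploid samples by default (the curated-set size of the
  emulated study design), drawn from the least-diverged population.
  Genotypes are two Bernoulli draws at the (possibly enriched, capped at
  1) target AF — Hardy–Weinberg by construction. Missingness (default 2%)
  is independent per genotype.
- **Planted violations.** Enrichment multiplies chosen variants' cohort
  AF; enriched variants are always annotated pathogenic/AR so planted
  signals are recoverable. Relative pairs are genotype copies with ≤ 10%
  per-site re-draw (declared via a shared relatedness group — no kinship
  inference exists downstream, matching the declared-metadata contract).
  Heterozygosity outliers are re-drawn from a genotype law whose het
  probability is multiplied by `het_inflation` and renormalised.
- **Annotations.** ~9.3% of sites are novel (no rsID) by default;
  pathogenic variants (5% of sites, preferring sites under 0.5% AF) are
  grouped three-per-gene so per-gene cumulative frequencies aggregate
  over several variants; site quality is Gaussian with optional AF and
  novelty effects (zero by default, i.e. the null of the quality
  regression holds).

All randomness flows from one integer seed; identical configurations
write byte-identical VCF/TSV outputs.

What the generator does **not** emulate: sequencing error and read-level
artifacts, multiallelic and indel sites, admixed or structured cohorts
(one homogeneous target population only), X-linked or dominant disease
models, linkage disequilibrium between sites, and cryptic (undeclared)
relatedness. Tests passing on this generator therefore validate the
statistical machinery and bookkeeping, not robustness to calling
artifacts or to ancestry mixture in real cohorts.

## Numerical and degenerate-input conventions

- Allele numbers count only called genotypes; sites with N = 0 carry an
  undefined-AF flag and are excluded from panel comparisons.
- Half-called genotypes ("./1") are treated as fully missing and counted
  in the read log.
- A reference AF of exactly 0 with n ≥ 1 observed alleles makes the
  binomial p-value 0; the result is flagged as a degenerate null rather
  than suppressed.
- Wilson bounds are clamped to [0, 1]; at n = 0 the lower bound is
  exactly 0 and at n = N the upper bound exactly 1.
- PCA mean-centres variants but does not scale them to unit variance (all
  entries share the AF unit); component signs are fixed by making the
  first population's coordinate non-negative, so results are reproducible
  and invariant to variant order at 1e-9.
- Enrichment ranking sorts by descending estimated AF, ties by ascending
  p-value, then variant key, with a stable sort throughout.

## Problem sizes used in the test suite

Property and calibration tests run at sizes chosen to make their
acceptance bands statistically meaningful: null calibration on 10⁴ rare
variants × 372 samples; enrichment power over 200 replicate cohorts of 30
candidate sites; incidence CI coverage over 1,500 independent simulated
genes (three variants of AF 0.005 each, so q_true = 0.015, where the
discrete Wilson coverage is ~0.95); population-structure recovery over 60
replicate panels of 5 populations × 1,500 variants. The whole suite runs
in well under a minute on one CPU.

## Known limitations

- Incidence assumes full penetrance and independence of alleles within a
  gene (no compound-heterozygote phasing, no cis double-counting guard
  beyond the strictly-heterozygous filter).
- The per-gene denominator is the count of curated individuals with at
  least one called genotype among the gene's candidate variants; genes
  whose variants sit in poorly called regions therefore get smaller,
  honest denominators rather than the cohort size.
- The binomial test treats the reference AF as known; uncertainty in the
  reference panel's own AF estimates is ignored, which anticonservatively
  narrows the null for very small panels (gnomAD-scale panels make this
  negligible).
- Chi-square on the impact × novelty table is unreliable for cohorts
  small enough to produce expected cell counts below ~5; the statistic is
  still reported, with no small-sample fallback.
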