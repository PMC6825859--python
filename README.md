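# exoprev

Cohort-exome analysis of recessive disease-allele prevalence: variant
spectrum characterisation against reference allele-frequency panels,
detection of over-represented ClinVar-pathogenic autosomal-recessive
alleles, and Hardy–Weinberg estimates of recessive disease incidence —
with a fully seeded synthetic-cohort simulator so that every estimate has
a parameter-recovery test.

## Who this is for

Groups holding a jointly genotyped exome cohort from a population that is
under-represented in the large aggregation databases, who want to ask:
which known pathogenic alleles are more common here than in a reference
population such as gnomAD NFE, and what recessive disease burden does
that imply?

## The statistics at the core

For a variant with alternate allele count *n* among *N* called
chromosomes in the curated cohort, over-representation relative to a
reference population with allele frequency *q*<sub>ref</sub> is scored
with the one-sided binomial tail

> *p* = P(X ≥ *n*), X ~ Binomial(*N*, *q*<sub>ref</sub>)

and the cohort frequency *n*/*N* is reported with a 95% Wilson score
interval. Candidate variants are ClinVar-pathogenic, autosomal-recessive,
rare in the panel (< 0.5%) and strictly heterozygous in the curated set.

Per gene, the pathogenic allele count *n*<sub>g</sub> over *N*<sub>ind</sub>
curated individuals gives the carrier frequency
*c* = *n*<sub>g</sub>/*N*<sub>ind</sub>, the cumulative pathogenic allele
frequency *q* = *n*<sub>g</sub>/(2·*N*<sub>ind</sub>), and — under
Hardy–Weinberg equilibrium — the expected disease incidence *q*².
Incidence bounds are the halved, squared Wilson bounds of *c*.

Cohort/panel relationships are summarised by allele-frequency
concordance (R² over sites with panel coverage ≥ 15×), PCA of the
populations × variants AF matrix, and per-population RMSD of allele
frequencies with confidence intervals.

See `docs/methods.md` for the model assumptions, curation rules, the
simulator's design, and known limitations.

## Worked example

Build the bundled deterministic fixture — a 372-sample cohort with fully
called genotypes encoding a set of known heterozygous carrier counts —
and run the whole pipeline:

```
exoprev fixture table_arithmetic --out demo/in
cat > demo/config.yaml <<EOF
vcf: demo/in/cohort.vcf
annotations: demo/in/annotations.tsv
metadata: demo/in/metadata.tsv
output_dir: demo/out
comparison_population: NFE
EOF
exoprev all demo/config.yaml
```

`demo/out/enrichment.tsv` then starts (selected columns):

```
rsid        gene   ac  an   estimated_af  ci_lower  ci_upper  p_value
rs5030858   PAH    6   744  0.0081        0.0037    0.0175    0.0010
rs36209567  F7     5   744  0.0067        0.0029    0.0156    0.0010
```

Reading the first row: 6 heterozygous carriers among 372 individuals
(744 chromosomes) give a cohort allele frequency of 0.0081 with Wilson
95% interval (0.0037, 0.0175); the chance of seeing ≥ 6 carriers if the
true frequency matched the comparison population's 0.0015 is about
1 × 10⁻³, i.e. the allele is over-represented.

`demo/out/incidence.tsv` aggregates alleles per gene:

```
gene   allele_count  carrier_frequency  incidence
ABCA4  13            0.0349             3.1e-04
PAH    11            0.0296             2.2e-04
F7      5            0.0134             4.5e-05
ATP7B   4            0.0108             2.9e-05
```

So 11 *PAH* carrier alleles among 372 individuals imply a carrier
frequency of about 1 in 34 and, under Hardy–Weinberg, a phenylketonuria
incidence of 2.2 × 10⁻⁴ ≈ 1 in 4,600 births.

For simulation studies, `exoprev simulate --out dir --seed 1` writes a
cohort with known ground truth (`truth_*.tsv`), and
`exoprev fixture enriched_cohort` plants enrichment at known variants.

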