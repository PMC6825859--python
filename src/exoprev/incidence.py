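"""Per-gene carrier frequency and Hardy–Weinberg disease incidence.

Pathogenic allele counts are summed per gene over the curated cohort.
Because every contributing variant is strictly heterozygous, the allele
count equals the carrier count, so the carrier frequency is c = n_g /
N_ind (individuals) while the cumulative pathogenic allele frequency is
q = n_g / (2 N_ind) (chromosomes). Under Hardy–Weinberg equilibrium the
expected autosomal-recessive disease incidence is q², with its
confidence interval obtained by halving and squaring the Wilson bounds
of the carrier proportion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prevalence import wilson_ci

logger = logging.getLogger(__name__)

__all__ = ["GeneIncidenceEstimate", "aggregate_gene_alleles", "estimate_incidence",
           "gene_incidence_table"]

MIN_GENE_ALLELES = 4  # "more than 3 observations" in the curated set


@dataclass(frozen=True)
class GeneIncidenceEstimate:
    gene: str
    disease: str
    n_alleles: int
    n_alleles_full: int | None
    n_individuals: int
    carrier_frequency: float
    carrier_ci: tuple[float, float]
    q: float
    incidence: float
    incidence_ci: tuple[float, float]


def aggregate_gene_alleles(
    candidates: pd.DataFrame,
    site_stats: pd.DataFrame,
    min_alleles: int = MIN_GENE_ALLELES,
) -> pd.Series:
    """Sum curated allele counts per gene over candidate pathogenic variants.

    Genes with fewer than ``min_alleles`` observations are dropped.
    Candidates lacking a gene annotation are excluded with a warning.
    Each variant contributes to exactly its one annotated gene.
    """
    has_gene = candidates["gene"].notna() & (candidates["gene"].astype(str) != "")
    n_dropped = int((~has_gene).sum())
    if n_dropped:
        logger.warning("excluded %d candidate variants lacking a gene annotation",
                       n_dropped)
    usable = candidates.loc[has_gene]
    ac = site_stats.loc[usable.index, "ac"]
    per_gene = ac.groupby(usable["gene"].to_numpy()).sum().astype(int)
    return per_gene[per_gene >= min_alleles].sort_values(ascending=False)


def estimate_incidence(
    n_g: int,
    n_individuals: int,
    confidence: float = 0.95,
    gene: str = "",
    disease: str = "",
    n_g_full: int | None = None,
    carrier_ci_fn=wilson_ci,
) -> GeneIncidenceEstimate:
    """Carrier frequency and Hardy–Weinberg incidence for one gene.

    ``n_g`` is the curated pathogenic allele count; with the
    all-heterozygous guarantee it equals the carrier count, so n_g cannot
    exceed the number of individuals.
    """
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    if n_g < 0:
        raise ValueError("allele count cannot be negative")
    if n_g > n_individuals:
        raise ValueError(
            "allele count exceeds individuals — impossible when all carriers "
            "are heterozygous"
        )
    c = n_g / n_individuals
    if n_g == 0:
        lo = hi = 0.0
    else:
        lo, hi = carrier_ci_fn(n_g, n_individuals, confidence)
    q = n_g / (2 * n_individuals)
    return GeneIncidenceEstimate(
        gene=gene,
        disease=disease,
        n_alleles=int(n_g),
        n_alleles_full=n_g_full,
        n_individuals=int(n_individuals),
        carrier_frequency=c,
        carrier_ci=(lo, hi),
        q=q,
        incidence=q * q,
        incidence_ci=((lo / 2) ** 2, (hi / 2) ** 2),
    )


def bootstrap_incidence_ci(
    n_g: int,
    n_individuals: int,
    confidence: float = 0.95,
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Parametric-bootstrap CI for q²: resample carrier counts binomially."""
    rng = np.random.default_rng(seed)
    c_hat = n_g / n_individuals
    counts = rng.binomial(n_individuals, c_hat, size=n_boot)
    q2 = (counts / (2 * n_individuals)) ** 2
    alpha = 1 - confidence
    lo, hi = np.quantile(q2, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def gene_incidence_table(
    candidates: pd.DataFrame,
    site_stats: pd.DataFrame,
    genotypes=None,
    n_individuals: int | None = None,
    min_alleles: int = MIN_GENE_ALLELES,
    confidence: float = 0.95,
    full_site_stats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene incidence estimates as a tidy frame.

    The per-gene denominator is the number of curated individuals with at
    least one called genotype among the gene's candidate variants when
    ``genotypes`` is supplied; otherwise ``n_individuals`` is used for
    every gene.
    """
    if genotypes is None and n_individuals is None:
        raise ValueError("provide genotypes or n_individuals")
    per_gene = aggregate_gene_alleles(candidates, site_stats, min_alleles=min_alleles)
    rows = []
    for gene, n_g in per_gene.items():
        keys = candidates.index[candidates["gene"] == gene]
        if genotypes is not None:
            order = {k: i for i, k in enumerate(genotypes.variant_keys)}
            rows_idx = [order[k] for k in keys if k in order]
            called = (genotypes.dosages[rows_idx] >= 0).any(axis=0)
            denom = int(called.sum())
        else:
            denom = int(n_individuals)
        n_full = None
        if full_site_stats is not None:
            n_full = int(full_site_stats.loc[keys, "ac"].sum())
        disease = ""
        if "disease" in candidates.columns:
            labels = candidates.loc[keys, "disease"].dropna().unique()
            disease = labels[0] if len(labels) else ""
        est = estimate_incidence(
            int(n_g), denom, confidence=confidence, gene=str(gene),
            disease=str(disease), n_g_full=n_full,
        )
        rows.append({
            "gene": est.gene,
            "disease": est.disease,
            "allele_count": est.n_alleles,
            "allele_count_full": est.n_alleles_full,
            "n_individuals": est.n_individuals,
            "carrier_frequency": est.carrier_frequency,
            "carrier_ci_lower": est.carrier_ci[0],
            "carrier_ci_upper": est.carrier_ci[1],
            "q": est.q,
            "incidence": est.incidence,
            "incidence_ci_lower": est.incidence_ci[0],
            "incidence_ci_upper": est.incidence_ci[1],
        })
    columns = ["gene", "disease", "allele_count", "allele_count_full",
               "n_individuals", "carrier_frequency", "carrier_ci_lower",
               "carrier_ci_upper", "q", "incidence", "incidence_ci_lower",
               "incidence_ci_upper"]
    frame = pd.DataFrame(rows, columns=columns if not rows else None)
    if not frame.empty:
        frame = frame.sort_values(
            ["allele_count", "gene"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    return frame
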