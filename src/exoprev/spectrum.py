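"""Variant-spectrum characterisation against reference panels.

Covers novelty and functional-impact tabulation (with a chi-square test
for excess novelty among high-impact sites), a site-quality regression on
novelty and allele frequency, allele-frequency concordance with a panel
population, principal-component analysis of population AFs, and per-
population RMSD of allele frequencies with a confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .io import CohortGenotypes
from .simulate import ReferencePanel

__all__ = [
    "SpectrumSummary",
    "QualityModel",
    "PopulationDistance",
    "summarize_spectrum",
    "fit_quality_model",
    "af_concordance",
    "pca_populations",
    "af_rmsd",
]

IMPACT_LEVELS = ("HIGH", "MODERATE", "LOW", "MODIFIER")


@dataclass(frozen=True)
class SpectrumSummary:
    impact_counts: pd.Series
    impact_fractions: pd.Series
    novelty_counts: pd.Series          # index: known / novel
    novelty_fractions: pd.Series
    impact_by_novelty: pd.DataFrame    # impact x {known, novel}
    mean_high_impact_per_sample: float | None
    chi2_statistic: float
    chi2_pvalue: float


@dataclass(frozen=True)
class QualityModel:
    """OLS fit of site quality on a novelty indicator and the observed AF."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    nobs: int


@dataclass(frozen=True)
class PopulationDistance:
    population: str
    rmsd: float
    ci_lower: float
    ci_upper: float
    n_sites: int


def _novel_mask(variants: pd.DataFrame) -> np.ndarray:
    return variants["rsid"].isna().to_numpy()


def summarize_spectrum(
    variants: pd.DataFrame,
    site_stats: pd.DataFrame | None = None,
    genotypes: CohortGenotypes | None = None,
) -> SpectrumSummary:
    """Tabulate impacts and novelty; test novelty excess among high-impact.

    The chi-square statistic is computed on the 2x2 table of
    (high-impact vs rest) x (novel vs known), without continuity
    correction. When ``genotypes`` are given the mean number of
    high-impact variants carried per sample is reported.
    """
    novel = _novel_mask(variants)
    impact = variants["impact"]
    impact_counts = impact.value_counts().reindex(IMPACT_LEVELS, fill_value=0)
    novelty_counts = pd.Series(
        {"known": int((~novel).sum()), "novel": int(novel.sum())}
    )
    cross = pd.crosstab(impact, np.where(novel, "novel", "known"))
    cross = cross.reindex(index=IMPACT_LEVELS, columns=["known", "novel"], fill_value=0)

    high = (impact == "HIGH").to_numpy()
    table = np.array(
        [
            [int((high & ~novel).sum()), int((high & novel).sum())],
            [int((~high & ~novel).sum()), int((~high & novel).sum())],
        ]
    )
    if table.sum() == 0 or np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        chi2, pval = 0.0, 1.0
    else:
        chi2, pval, _, _ = sps.chi2_contingency(table, correction=False)

    mean_high = None
    if genotypes is not None:
        order = {k: i for i, k in enumerate(genotypes.variant_keys)}
        rows = [order[k] for k, is_high in zip(variants.index, high) if is_high and k in order]
        carried = (genotypes.dosages[rows] >= 1).sum(axis=0)
        mean_high = float(carried.mean())

    n = len(variants)
    return SpectrumSummary(
        impact_counts=impact_counts,
        impact_fractions=impact_counts / max(n, 1),
        novelty_counts=novelty_counts,
        novelty_fractions=novelty_counts / max(n, 1),
        impact_by_novelty=cross,
        mean_high_impact_per_sample=mean_high,
        chi2_statistic=float(chi2),
        chi2_pvalue=float(pval),
    )


def fit_quality_model(variants: pd.DataFrame, site_stats: pd.DataFrame) -> QualityModel:
    """OLS of site quality on a novelty indicator (1 = novel) and cohort AF.

    Used to check that novel calls are not systematically lower-quality
    than known ones; significance is read from the coefficient t-tests.
    """
    if len(variants) < 3:
        raise ValueError("quality regression needs at least 3 variants")
    novel = _novel_mask(variants).astype(float)
    if novel.min() == novel.max():
        raise ValueError("both known and novel variants are required")
    af = site_stats.loc[variants.index, "af"].to_numpy(dtype=float)
    y = variants["site_quality"].to_numpy(dtype=float)
    ok = ~np.isnan(af) & ~np.isnan(y)
    X = sm.add_constant(
        pd.DataFrame({"novel": novel[ok], "af": af[ok]}), has_constant="add"
    )
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("singular design matrix in quality regression")
    fit = sm.OLS(y[ok], X).fit()
    return QualityModel(
        params=fit.params, bse=fit.bse, tvalues=fit.tvalues,
        pvalues=fit.pvalues, nobs=int(fit.nobs),
    )


def af_concordance(
    site_stats: pd.DataFrame,
    panel: ReferencePanel,
    population: str,
    min_coverage: float = 15.0,
) -> dict:
    """Regress cohort AF on one panel population's AF over well-covered sites.

    Sites below the coverage threshold, sites absent from the panel and
    sites with no called alleles are excluded first. Returns R², the
    regression slope and intercept, the number of sites used and the count
    excluded because they were absent from the panel.
    """
    if population not in panel.afs.columns:
        raise ValueError(f"population {population!r} not in panel")
    in_panel = site_stats.index.isin(panel.afs.index)
    n_absent = int((~in_panel).sum())
    present = site_stats.loc[in_panel]
    cov = panel.mean_coverage.loc[present.index]
    ok = (cov >= min_coverage).to_numpy() & ~present["af_undefined"].to_numpy()
    used = present.loc[ok]
    if len(used) < 2:
        raise ValueError("fewer than 2 qualifying sites for AF concordance")
    x = panel.afs.loc[used.index, population].to_numpy()
    y = used["af"].to_numpy(dtype=float)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "r_squared": float(fit.rsquared),
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "n_sites": int(len(used)),
        "n_absent_from_panel": n_absent,
    }


def pca_populations(
    panel: ReferencePanel,
    cohort_af: pd.Series,
    n_components: int = 2,
    cohort_label: str = "cohort",
) -> pd.DataFrame:
    """PCA of population allele frequencies with the cohort as an extra row.

    Only variants with a defined AF in every population and in the cohort
    enter the decomposition. Rows are populations (plus the cohort),
    columns are variants; variants are mean-centred but not variance-
    scaled, since all entries share the AF unit. Component signs are fixed
    by making the first population's coordinate non-negative on each axis.
    """
    if panel.afs.shape[1] < 3:
        raise ValueError("PCA needs at least 3 populations")
    joint = panel.afs.index.intersection(cohort_af.dropna().index)
    if len(joint) < 2:
        raise ValueError("fewer than 2 variants shared by all populations and cohort")
    mat = np.vstack([
        panel.afs.loc[joint].to_numpy().T,
        cohort_af.loc[joint].to_numpy()[None, :],
    ])
    centered = mat - mat.mean(axis=0, keepdims=True)
    # rows (populations) are few; SVD of the centred matrix is exact PCA
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    k = min(n_components, len(s))
    coords = u[:, :k] * s[:k]
    sign = np.where(coords[0, :] < 0, -1.0, 1.0)
    coords = coords * sign
    labels = panel.populations + [cohort_label]
    return pd.DataFrame(coords, index=labels,
                        columns=[f"PC{i + 1}" for i in range(k)])


def af_rmsd(
    cohort_af: pd.Series,
    panel: ReferencePanel,
    confidence: float = 0.95,
    method: str = "t",
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> list[PopulationDistance]:
    """Root-mean-square AF deviation between the cohort and each population.

    The default confidence interval is a t-interval for the mean of the
    squared per-site differences, with its endpoints square-rooted (lower
    clamped at 0). ``method="bootstrap"`` resamples sites instead (seeded).
    """
    joint = panel.afs.index.intersection(cohort_af.dropna().index)
    if len(joint) == 0:
        raise ValueError("no variants shared between cohort and panel")
    x = cohort_af.loc[joint].to_numpy()
    out: list[PopulationDistance] = []
    rng = np.random.default_rng(seed)
    for pop in panel.populations:
        sq = (x - panel.afs.loc[joint, pop].to_numpy()) ** 2
        rmsd = float(np.sqrt(sq.mean()))
        n = sq.size
        if method == "t":
            if n > 1 and sq.std(ddof=1) > 0:
                lo, hi = sps.t.interval(confidence, df=n - 1, loc=sq.mean(),
                                        scale=sps.sem(sq))
            else:
                lo = hi = sq.mean()
        elif method == "bootstrap":
            idx = rng.integers(0, n, size=(n_bootstrap, n))
            means = sq[idx].mean(axis=1)
            alpha = 1 - confidence
            lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
        else:
            raise ValueError(f"unknown CI method {method!r}")
        out.append(PopulationDistance(
            population=pop,
            rmsd=rmsd,
            ci_lower=float(np.sqrt(max(lo, 0.0))),
            ci_upper=float(np.sqrt(max(hi, 0.0))),
            n_sites=n,
        ))
    return out
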