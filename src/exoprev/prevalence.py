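"""Detection of over-represented recessive pathogenic alleles.

Candidate variants are ClinVar-pathogenic, autosomal-recessive, rare in
the reference panel (< 0.5% by default) and strictly heterozygous in the
curated cohort. Over-representation relative to a named comparison
population is scored with a one-sided upper-tail binomial test: the
p-value of observing at least n alternate alleles when sampling N
chromosomes at the reference allele frequency. Interval estimates of the
cohort AF use the Wilson score interval (Clopper–Pearson available).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "filter_candidates",
    "binomial_enrichment",
    "wilson_ci",
    "clopper_pearson_ci",
    "rank_enrichment",
]

DEFAULT_AF_MAX = 0.005
PANEL_AF_COLUMN = "af_ALL"


def filter_candidates(
    variants: pd.DataFrame,
    site_stats: pd.DataFrame,
    af_max: float = DEFAULT_AF_MAX,
    panel_af_column: str = PANEL_AF_COLUMN,
) -> pd.DataFrame:
    """Select rare pathogenic AR variants strictly heterozygous in the cohort.

    A variant is retained iff it is annotated pathogenic, inherited AR,
    its whole-panel reference AF is below ``af_max``, it is observed
    (ac >= 1) and no curated sample is homozygous-alternate. Variants with
    no panel AF entry are treated as AF 0 (retained) and flagged
    ``absent_from_panel``.
    """
    stats = site_stats.loc[variants.index]
    if panel_af_column in variants.columns:
        panel_af = variants[panel_af_column].astype(float)
        absent = panel_af.isna()
        panel_af = panel_af.fillna(0.0)
    else:
        panel_af = pd.Series(0.0, index=variants.index)
        absent = pd.Series(True, index=variants.index)

    keep = (
        (variants["clinical_significance"] == "pathogenic")
        & (variants["inheritance"] == "AR")
        & (panel_af < af_max)
        & (stats["ac"] >= 1)
        & (stats["n_hom_alt"] == 0)
    )
    out = variants.loc[keep].copy()
    out["panel_af"] = panel_af.loc[keep]
    out["absent_from_panel"] = absent.loc[keep]
    return out


def binomial_enrichment(n: int, N: int, af_ref: float) -> float:
    """One-sided upper-tail binomial p-value P(X >= n), X ~ Binomial(N, af_ref).

    Evaluated through the stable survival function (no normal
    approximation). With a degenerate null (af_ref = 0) and n >= 1 the
    p-value is 0 and a warning is emitted.
    """
    if not 0 <= n <= N:
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not 0.0 <= af_ref <= 1.0:
        raise ValueError(f"af_ref must lie in [0, 1], got {af_ref}")
    if n == 0:
        return 1.0
    if af_ref == 0.0:
        warnings.warn("degenerate null: af_ref = 0 with n >= 1 gives p = 0",
                      stacklevel=2)
        return 0.0
    return float(sps.binom.sf(n - 1, N, af_ref))


def wilson_ci(n: int, N: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, no continuity correction."""
    if N <= 0:
        raise ValueError("N must be positive")
    if not 0 <= n <= N:
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    lo, hi = proportion_confint(n, N, alpha=1 - confidence, method="wilson")
    # the Wilson lower bound is exactly 0 at n=0 (and upper 1 at n=N);
    # clear the float noise the generic formula leaves there
    lo = 0.0 if n == 0 else float(min(max(lo, 0.0), 1.0))
    hi = 1.0 if n == N else float(min(max(hi, 0.0), 1.0))
    return lo, hi


def clopper_pearson_ci(n: int, N: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper–Pearson) binomial interval; wider than Wilson."""
    if N <= 0:
        raise ValueError("N must be positive")
    lo, hi = proportion_confint(n, N, alpha=1 - confidence, method="beta")
    return float(np.nan_to_num(lo)), float(np.nan_to_num(hi))


_CI_METHODS = {"wilson": wilson_ci, "clopper-pearson": clopper_pearson_ci}


def rank_enrichment(
    candidates: pd.DataFrame,
    site_stats: pd.DataFrame,
    comparison_population: str,
    confidence: float = 0.95,
    full_site_stats: pd.DataFrame | None = None,
    ci_method: str = "wilson",
) -> pd.DataFrame:
    """Score and rank candidate variants against a comparison population.

    For each candidate: estimated AF = ac/an with a score CI, and the
    one-sided binomial p-value of the observed allele count against the
    comparison population's AF. Rows are sorted by descending estimated
    AF, ties broken by ascending p-value then variant key. When
    ``full_site_stats`` is given the uncurated allele counts are reported
    alongside (the bracketed counts of the source-style report). A raw
    Benjamini–Hochberg column is appended for convenience.
    """
    ci_fn = _CI_METHODS[ci_method]
    af_col = f"af_{comparison_population}"
    if af_col not in candidates.columns:
        raise ValueError(f"candidates lack column {af_col!r}")
    rows = []
    for key, var in candidates.iterrows():
        st = site_stats.loc[key]
        n, N = int(st["ac"]), int(st["an"])
        af_ref = float(var[af_col]) if pd.notna(var[af_col]) else 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pval = binomial_enrichment(n, N, af_ref)
        lo, hi = ci_fn(n, N, confidence) if N > 0 else (np.nan, np.nan)
        row = {
            "variant_key": key,
            "rsid": var.get("rsid"),
            "gene": var.get("gene"),
            "panel_af": var.get("panel_af", np.nan),
            "comparison_af": af_ref,
            "ac": n,
            "an": N,
            "estimated_af": n / N if N else np.nan,
            "ci_lower": lo,
            "ci_upper": hi,
            "p_value": pval,
            "degenerate_null": af_ref == 0.0 and n >= 1,
            "absent_from_panel": bool(var.get("absent_from_panel", False)),
            "disease": var.get("disease", ""),
        }
        if full_site_stats is not None and key in full_site_stats.index:
            row["ac_full"] = int(full_site_stats.loc[key, "ac"])
            row["an_full"] = int(full_site_stats.loc[key, "an"])
        rows.append(row)
    columns = ["variant_key", "rsid", "gene", "panel_af", "comparison_af", "ac",
               "an", "estimated_af", "ci_lower", "ci_upper", "p_value",
               "degenerate_null", "absent_from_panel", "disease"]
    if not rows:
        return pd.DataFrame(columns=columns + ["p_bh"])
    result = pd.DataFrame(rows)
    result = result.sort_values(
        ["estimated_af", "p_value", "variant_key"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    m = len(result)
    order = result["p_value"].rank(method="first").to_numpy()
    bh = result["p_value"].to_numpy() * m / order
    # enforce monotonicity of the step-up adjustment
    by_rank = np.argsort(order)
    adj = np.minimum.accumulate(bh[by_rank][::-1])[::-1]
    out = np.empty_like(adj)
    out[by_rank] = np.minimum(adj, 1.0)
    result["p_bh"] = out
    return result
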