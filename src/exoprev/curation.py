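"""Sample curation: phenotype eligibility, relatedness, heterozygosity QC.

Filters are applied in a fixed order — phenotype eligibility, then
declared-relative pruning, then heterozygosity-outlier removal — because
the retained set can differ under reordering. Relatedness is taken from
declared metadata groups, not estimated from genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CohortGenotypes, sample_call_stats, site_stats

__all__ = ["CurationReport", "remove_related", "flag_het_outliers", "curate",
           "retained_variant_fraction"]


def retained_variant_fraction(n_retained: int, n_total: int) -> float:
    """Share of polymorphic sites surviving curation (0 when none existed)."""
    if n_retained < 0 or n_total < n_retained:
        raise ValueError("need 0 <= n_retained <= n_total")
    return n_retained / n_total if n_total else 0.0

REASON_KEPT = "kept"
REASON_RELATED = "related"
REASON_HET_OUTLIER = "het_outlier"
REASON_PHENOTYPE = "phenotype_excluded"
REASON_NO_CALLS = "no_called_genotypes"


@dataclass(frozen=True)
class CurationReport:
    """Per-sample keep/remove decisions with reasons and summary counts.

    ``retained_variant_fraction`` is the share of variant sites still
    polymorphic (ac > 0) in the curated subset, relative to the sites
    polymorphic in the full cohort.
    """

    decisions: pd.DataFrame
    reason_counts: dict[str, int]
    retained_variant_fraction: float

    @property
    def kept(self) -> list[str]:
        d = self.decisions
        return list(d.index[d["decision"] == REASON_KEPT])


def remove_related(metadata: pd.DataFrame, genotypes: CohortGenotypes | None = None) -> set[str]:
    """Keep at most one sample per declared relatedness group.

    An empty ``relatedness_group`` means unrelated (always kept). Within a
    group the sample with the highest genotype call rate wins; ties break
    lexicographically on sample id. Without genotypes all call rates are
    treated as equal.
    """
    if "relatedness_group" not in metadata.columns:
        raise ValueError("metadata lacks a relatedness_group column")
    ids = metadata["sample_id"].astype(str)
    groups = metadata["relatedness_group"].fillna("").astype(str)
    if genotypes is not None:
        call_rate = sample_call_stats(genotypes)["call_rate"]
    else:
        call_rate = pd.Series(1.0, index=ids.to_numpy())

    kept: set[str] = set(ids[groups == ""])
    for _, members in ids[groups != ""].groupby(groups[groups != ""]):
        ranked = sorted(members, key=lambda s: (-float(call_rate.get(s, 0.0)), s))
        kept.add(ranked[0])
    return kept


def flag_het_outliers(genotypes: CohortGenotypes, k: float = 4.0) -> dict[str, str]:
    """Flag samples with unusually high heterozygosity.

    The per-sample heterozygous-call fraction h = n_het / n_called is
    screened one-sidedly: samples with h > median(h) + k * MAD(h) are
    flagged (MAD = raw median absolute deviation). Samples with no called
    genotypes at all are flagged under a distinct reason. Returns
    {sample_id: reason} for flagged samples only.
    """
    if genotypes.n_samples < 10:
        raise ValueError("heterozygosity screening needs at least 10 samples")
    stats = sample_call_stats(genotypes)
    h = stats["het_fraction"]
    flags: dict[str, str] = {s: REASON_NO_CALLS for s in h.index[h.isna()]}
    valid = h.dropna()
    med = float(np.median(valid))
    mad = float(np.median(np.abs(valid - med)))
    threshold = med + k * mad
    for s in valid.index[valid > threshold]:
        flags[s] = REASON_HET_OUTLIER
    return flags


def curate(
    genotypes: CohortGenotypes,
    metadata: pd.DataFrame,
    allowed_phenotypes,
    het_k: float = 4.0,
) -> tuple[list[str], CurationReport]:
    """Reduce the cohort to the unrelated, phenotype-eligible analysis set.

    Applies the phenotype filter, then relatedness pruning, then the
    heterozygosity screen, and reports per-sample decisions plus the
    retained-variant fraction. Raises if nothing survives.
    """
    allowed = set(allowed_phenotypes)
    if not allowed:
        raise ValueError("allowed_phenotypes must be non-empty")
    meta = metadata.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    decision = pd.Series(REASON_KEPT, index=meta["sample_id"].to_numpy(), dtype=object)

    eligible = meta[meta["phenotype"].isin(allowed)]
    decision[~decision.index.isin(eligible["sample_id"])] = REASON_PHENOTYPE

    kept_rel = remove_related(eligible, genotypes)
    for s in eligible["sample_id"]:
        if s not in kept_rel:
            decision[s] = REASON_RELATED

    survivors = [s for s in genotypes.sample_ids if decision.get(s) == REASON_KEPT]
    if survivors:
        flags = flag_het_outliers(genotypes.subset_samples(survivors), k=het_k)
        for s, reason in flags.items():
            decision[s] = reason

    kept = [s for s in genotypes.sample_ids if decision.get(s) == REASON_KEPT]
    if not kept:
        raise ValueError("curation removed every sample")

    full = site_stats(genotypes)
    curated = site_stats(genotypes, kept)
    polymorphic_full = int((full["ac"] > 0).sum())
    retained = int((curated["ac"] > 0).sum())
    fraction = retained_variant_fraction(retained, polymorphic_full)

    counts = decision.value_counts().to_dict()
    report = CurationReport(
        decisions=pd.DataFrame({"decision": decision}),
        reason_counts={str(k): int(v) for k, v in counts.items()},
        retained_variant_fraction=float(fraction),
    )
    return kept, report
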