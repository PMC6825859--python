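"""Cohort input: multi-sample VCF, annotation table, sample metadata.

The reader consumes already-called, already-annotated variants. Records
must be biallelic (pre-split multiallelics upstream, e.g. with
``bcftools norm -m-``); every VCF record must have a matching annotation
row keyed by (chrom, pos, ref, alt) after uppercase normalisation of the
alleles. Only the GT FORMAT field is consulted; half-calls such as
``./1`` are treated as fully missing and counted in the read log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "CohortGenotypes",
    "variant_key",
    "read_cohort",
    "read_annotations",
    "read_metadata",
    "site_stats",
    "sample_call_stats",
]

MISSING = -1

ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "rsid", "gene", "impact",
    "clinical_significance", "inheritance", "site_quality", "ref_mean_coverage",
]
METADATA_COLUMNS = ["sample_id", "phenotype", "relatedness_group"]


def variant_key(chrom, pos, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref.upper()}:{alt.upper()}"


@dataclass(frozen=True)
class CohortGenotypes:
    """Dense alt-allele dosage matrix, variants x samples.

    ``dosages[i, j]`` is the number of alternate alleles carried by sample
    ``j`` at variant ``i`` (0, 1 or 2), or -1 for a missing genotype.
    """

    sample_ids: list[str]
    variant_keys: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.variant_keys), len(self.sample_ids)):
            raise ValueError("dosage matrix shape does not match id lists")
        vals = np.unique(self.dosages)
        if not np.all(np.isin(vals, [-1, 0, 1, 2])):
            raise ValueError("dosages must be in {0,1,2} or -1 for missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)

    def sample_indices(self, sample_subset) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([index[s] for s in sample_subset], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def subset_samples(self, sample_subset) -> "CohortGenotypes":
        idx = self.sample_indices(sample_subset)
        return CohortGenotypes(
            sample_ids=[self.sample_ids[i] for i in idx],
            variant_keys=list(self.variant_keys),
            dosages=self.dosages[:, idx],
        )


def read_annotations(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False,
                      na_values=[""])
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation table lacks required columns: {missing}")
    ann["rsid"] = ann["rsid"].replace(".", np.nan)
    ann.index = pd.Index(
        [variant_key(c, p, r, a)
         for c, p, r, a in zip(ann["chrom"], ann["pos"], ann["ref"], ann["alt"])],
        name="variant_key",
    )
    bad_af = []
    for col in ann.columns:
        if col.startswith("af_"):
            vals = ann[col].to_numpy(dtype=float)
            if np.any((vals < 0) | (vals > 1)):
                bad_af.append(col)
    if bad_af:
        raise ValueError(f"allele frequencies outside [0, 1] in columns {bad_af}")
    return ann


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata table lacks required columns: {missing}")
    meta["sample_id"] = meta["sample_id"].astype(str)
    return meta


def read_cohort(
    vcf_path: str | Path,
    annotations_path: str | Path,
    metadata_path: str | Path,
) -> tuple[CohortGenotypes, pd.DataFrame, pd.DataFrame]:
    """Read a cohort VCF plus its annotation and metadata tables.

    Returns genotypes, the annotation frame aligned to VCF record order,
    and the sample metadata. Raises on multiallelic records, on VCF sites
    without an annotation row, and on VCF/metadata sample-id mismatches.
    """
    ann = read_annotations(annotations_path)
    meta = read_metadata(metadata_path)

    vcf = pysam.VariantFile(str(vcf_path))
    samples = list(vcf.header.samples)
    if set(samples) != set(meta["sample_id"]):
        raise ValueError("VCF sample ids do not match metadata sample ids")

    keys: list[str] = []
    rows: list[np.ndarray] = []
    qualities: list[float] = []
    n_half_calls = 0
    multiallelic: list[str] = []
    unmatched: list[str] = []
    for rec in vcf:
        alts = rec.alts or ()
        if len(alts) != 1:
            multiallelic.append(f"{rec.chrom}:{rec.pos}")
            continue
        key = variant_key(rec.chrom, rec.pos, rec.ref, alts[0])
        if key not in ann.index:
            unmatched.append(key)
            continue
        dos = np.empty(len(samples), dtype=np.int8)
        for j, s in enumerate(samples):
            gt = rec.samples[s].get("GT", (None, None))
            if gt is None or len(gt) != 2 or gt[0] is None or gt[1] is None:
                if gt is not None and any(a is not None for a in (gt or ())):
                    n_half_calls += 1
                dos[j] = MISSING
            else:
                dos[j] = gt[0] + gt[1]
        keys.append(key)
        rows.append(dos)
        qualities.append(rec.qual if rec.qual is not None else np.nan)
    if multiallelic:
        raise ValueError(
            "multiallelic records are not supported; pre-split them "
            f"(e.g. bcftools norm -m-). Offending sites: {multiallelic[:20]}"
        )
    if unmatched:
        raise ValueError(f"VCF sites without annotation rows: {unmatched[:20]}")
    if n_half_calls:
        logger.warning("treated %d half-called genotypes as missing", n_half_calls)

    genotypes = CohortGenotypes(
        sample_ids=samples,
        variant_keys=keys,
        dosages=np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8),
    )
    ann = ann.loc[keys].copy()
    # VCF QUAL wins over the annotation column when both are present
    qual = np.asarray(qualities, dtype=float)
    ann.loc[:, "site_quality"] = np.where(np.isnan(qual), ann["site_quality"], qual)
    return genotypes, ann, meta


def site_stats(genotypes: CohortGenotypes, sample_subset=None) -> pd.DataFrame:
    """Per-site allele counts over a sample subset.

    Returns a frame indexed by variant key with columns ``ac`` (alternate
    allele count n), ``an`` (called alleles N = 2 x non-missing genotypes),
    ``af`` (n/N, NaN where N = 0), ``n_het``, ``n_hom_alt`` and the
    ``af_undefined`` flag.
    """
    if sample_subset is None:
        sub = genotypes.dosages
    else:
        idx = genotypes.sample_indices(sample_subset)
        if idx.size == 0:
            raise ValueError("sample subset is empty")
        sub = genotypes.dosages[:, idx]
    called = sub >= 0
    an = 2 * called.sum(axis=1)
    ac = np.where(called, sub, 0).sum(axis=1)
    n_het = (sub == 1).sum(axis=1)
    n_hom_alt = (sub == 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
    return pd.DataFrame(
        {
            "ac": ac,
            "an": an,
            "af": af,
            "n_het": n_het,
            "n_hom_alt": n_hom_alt,
            "af_undefined": an == 0,
        },
        index=pd.Index(genotypes.variant_keys, name="variant_key"),
    )


def sample_call_stats(genotypes: CohortGenotypes) -> pd.DataFrame:
    """Per-sample call rate and heterozygosity fraction.

    ``het_fraction`` is n_het / n_called and is NaN for samples with no
    called genotypes.
    """
    d = genotypes.dosages
    called = (d >= 0).sum(axis=0)
    het = (d == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_frac = np.where(called > 0, het / np.maximum(called, 1), np.nan)
    return pd.DataFrame(
        {
            "call_rate": called / max(1, genotypes.n_variants),
            "n_called": called,
            "n_het": het,
            "het_fraction": het_frac,
        },
        index=pd.Index(genotypes.sample_ids, name="sample_id"),
    )
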