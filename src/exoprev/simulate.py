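"""Forward simulation of reference panels and annotated exome cohorts.

The generator provides ground truth for every downstream stage: population
allele frequencies diverge from an ancestral frequency under the
Balding–Nichols model, cohort genotypes are drawn under Hardy–Weinberg
equilibrium from one target population, and known violations (enriched
pathogenic alleles, declared relative pairs, heterozygosity-inflated
samples, missing genotypes) are planted with recorded labels.

Outputs are plain-text files: a VCFv4.2 cohort file (GT-only FORMAT),
a per-variant annotation TSV, a sample-metadata TSV and truth TSVs, so a
full simulated study round-trips through :mod:`exoprev.io`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CohortGenotypes, variant_key

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "ReferencePanel",
    "simulate_reference_panel",
    "panel_from_afs",
    "simulate_cohort",
    "write_cohort",
]

DEFAULT_POPULATION_LABELS = ("pop0", "pop1", "pop2", "pop3", "pop4")

#: Phenotype labels considered analysis-eligible by default. The excluded
#: label marks samples with a severe early-onset Mendelian diagnosis.
ELIGIBLE_PHENOTYPES = ("control", "T2D", "MODY", "obesity", "ASD", "CTD_mild")
EXCLUDED_PHENOTYPE = "severe_mendelian"


@dataclass(frozen=True)
class ReferencePanel:
    """Populations x variants allele-frequency matrix with site coverage.

    Attributes
    ----------
    afs :
        DataFrame indexed by variant key with one column per population;
        entries are alternate-allele frequencies in [0, 1].
    mean_coverage :
        Per-variant mean sequencing depth across the panel's exomes,
        indexed like ``afs``.
    """

    afs: pd.DataFrame
    mean_coverage: pd.Series

    @property
    def populations(self) -> list[str]:
        return list(self.afs.columns)

    def overall_af(self) -> pd.Series:
        """Unweighted mean AF across populations (the whole-panel AF)."""
        return self.afs.mean(axis=1)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the forward model; every draw flows from ``seed``.

    Defaults describe the emulated study: a curated cohort of 372 diploid
    samples drawn from the least-diverged of five reference populations,
    a rare-skewed exome allele-frequency spectrum, ~9.3% of sites absent
    from the variant catalogue ("novel"), and a small fraction of
    pathogenic, autosomal-recessive annotated alleles.
    """

    n_populations: int = 5
    n_variants: int = 2000
    n_samples: int = 372
    ancestral_af_distribution: tuple[float, float] = (0.2, 1.8)
    fst_per_population: tuple[float, ...] = (0.01, 0.05, 0.08, 0.12, 0.2)
    target_population_index: int = 0
    population_labels: tuple[str, ...] | None = None
    pathogenic_fraction: float = 0.05
    variants_per_gene: int = 3
    enrichment_map: dict[int, float] = field(default_factory=dict)
    missing_rate: float = 0.02
    n_related_pairs: int = 0
    relative_redraw_prob: float = 0.05
    n_het_outliers: int = 0
    het_inflation: float = 2.0
    excluded_phenotype_fraction: float = 0.0
    novel_fraction: float = 0.093
    low_coverage_fraction: float = 0.1
    quality_mean: float = 60.0
    quality_sd: float = 10.0
    quality_af_slope: float = 0.0
    quality_novel_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 2:
            raise ValueError("need at least 2 populations")
        if len(self.fst_per_population) != self.n_populations:
            raise ValueError("fst_per_population length must equal n_populations")
        for f in self.fst_per_population:
            if not 0.0 <= f < 1.0:
                raise ValueError(f"Fst must lie in [0, 1), got {f}")
        a, b = self.ancestral_af_distribution
        if a <= 0 or b <= 0:
            raise ValueError("ancestral Beta shape parameters must be positive")
        if not 0 <= self.target_population_index < self.n_populations:
            raise ValueError("target_population_index out of range")
        for name in ("pathogenic_fraction", "missing_rate", "novel_fraction",
                     "low_coverage_fraction", "excluded_phenotype_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.relative_redraw_prob <= 0.1:
            raise ValueError("relative_redraw_prob must lie in [0, 0.1]")
        if self.het_inflation <= 1.0:
            raise ValueError("het_inflation must exceed 1")
        for idx, factor in self.enrichment_map.items():
            if not 0 <= idx < self.n_variants:
                raise ValueError(f"enrichment index {idx} out of range")
            if factor < 1.0:
                raise ValueError("enrichment factors must be >= 1")
        if self.n_related_pairs * 2 + self.n_het_outliers > self.n_samples:
            raise ValueError("related pairs plus het outliers exceed sample count")

    def labels(self) -> tuple[str, ...]:
        if self.population_labels is not None:
            if len(self.population_labels) != self.n_populations:
                raise ValueError("population_labels length mismatch")
            return tuple(self.population_labels)
        return tuple(f"pop{i}" for i in range(self.n_populations))


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth recorded by the generator.

    ``variants`` carries the true target-population AF after enrichment and
    the enrichment flag; ``samples`` the planted labels; ``genes`` the
    cumulative pathogenic allele frequency q_true per gene and the implied
    Hardy–Weinberg disease incidence q_true**2.
    """

    variants: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.DataFrame


def simulate_reference_panel(config: SimulationConfig) -> ReferencePanel:
    """Draw per-population AFs around an ancestral frequency.

    The ancestral frequency p of each variant is Beta-distributed with the
    configured shape parameters; each population's AF is then drawn from
    Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p and variance F*p*(1-p)
    (Balding–Nichols). F = 0 is the zero-divergence limit where the
    population AF equals p exactly.
    """
    rng = np.random.default_rng(config.seed)
    a, b = config.ancestral_af_distribution
    p = rng.beta(a, b, size=config.n_variants)
    p = np.clip(p, 1e-4, 1 - 1e-4)

    afs = np.empty((config.n_variants, config.n_populations))
    for j, fst in enumerate(config.fst_per_population):
        if fst == 0.0:
            afs[:, j] = p
        else:
            scale = (1.0 - fst) / fst
            afs[:, j] = rng.beta(p * scale, (1.0 - p) * scale)

    # bimodal coverage so a configurable share of sites fails a 15x filter
    low = rng.random(config.n_variants) < config.low_coverage_fraction
    coverage = np.where(low, rng.uniform(2.0, 15.0, config.n_variants),
                        rng.uniform(15.0, 120.0, config.n_variants))

    keys = [_synthetic_key(i) for i in range(config.n_variants)]
    af_frame = pd.DataFrame(afs, index=keys, columns=list(config.labels()))
    return ReferencePanel(afs=af_frame, mean_coverage=pd.Series(coverage, index=keys))


def panel_from_afs(
    afs: np.ndarray,
    labels=DEFAULT_POPULATION_LABELS,
    mean_coverage: np.ndarray | None = None,
) -> ReferencePanel:
    """Wrap a raw (variants x populations) AF array as a reference panel.

    Variant keys follow the simulator's synthetic site layout, so a cohort
    drawn from the returned panel round-trips through the VCF writer and
    reader. Intended for constructing panels with exactly known AFs.
    """
    afs = np.atleast_2d(np.asarray(afs, dtype=float))
    if afs.min() < 0 or afs.max() > 1:
        raise ValueError("allele frequencies must lie in [0, 1]")
    n_var, n_pop = afs.shape
    if len(labels) < n_pop:
        raise ValueError("not enough population labels")
    keys = [_synthetic_key(i) for i in range(n_var)]
    if mean_coverage is None:
        mean_coverage = np.full(n_var, 50.0)
    return ReferencePanel(
        afs=pd.DataFrame(afs, index=keys, columns=list(labels)[:n_pop]),
        mean_coverage=pd.Series(np.asarray(mean_coverage, dtype=float), index=keys),
    )


_BASES = np.array(list("ACGT"))


def _synthetic_key(i: int) -> str:
    chrom, pos, ref, alt = _synthetic_site(i)
    return variant_key(chrom, pos, ref, alt)


def _synthetic_site(i: int) -> tuple[str, int, str, str]:
    # deterministic site layout: one chromosome, evenly spaced biallelic SNVs
    ref = _BASES[i % 4]
    alt = _BASES[(i + 1) % 4]
    return "1", 10_001 + 100 * i, str(ref), str(alt)


def simulate_cohort(
    panel: ReferencePanel, config: SimulationConfig
) -> tuple[CohortGenotypes, pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Draw an annotated diploid cohort from the panel's target population.

    Genotypes are two Bernoulli draws per sample at the (possibly enriched,
    capped at 1) target-population AF — Hardy–Weinberg by construction.
    Relative pairs are copies with a small per-site re-draw probability;
    heterozygosity outliers are re-drawn with the heterozygote genotype
    probability multiplied by ``het_inflation``; missingness is applied
    independently per genotype afterwards.

    Returns the genotype matrix, the annotation table (one row per variant),
    the sample metadata table and the recorded :class:`SimulationTruth`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    labels = config.labels()
    target = labels[config.target_population_index]
    if target not in panel.afs.columns:
        raise ValueError(f"target population {target!r} absent from panel")
    base_af = panel.afs[target].to_numpy(copy=True)
    n_var, n_sam = len(base_af), config.n_samples

    for idx in config.enrichment_map:
        if idx >= n_var:
            raise ValueError(f"enrichment index {idx} not in panel")
    true_af = base_af.copy()
    enriched = np.zeros(n_var, dtype=bool)
    for idx, factor in config.enrichment_map.items():
        true_af[idx] = min(1.0, true_af[idx] * factor)
        enriched[idx] = True

    # HWE genotypes: dosage = sum of two Bernoulli(q) draws
    draws = rng.random((2, n_var, n_sam))
    dosages = (draws < true_af[None, :, None]).sum(axis=0).astype(np.int8)

    sample_ids = [f"S{i:04d}" for i in range(n_sam)]
    related_group = np.array([""] * n_sam, dtype=object)
    het_outlier = np.zeros(n_sam, dtype=bool)

    # related pairs occupy the front of the sample list, outliers follow
    for k in range(config.n_related_pairs):
        i, j = 2 * k, 2 * k + 1
        related_group[i] = related_group[j] = f"FAM{k:03d}"
        copy = dosages[:, i].copy()
        redraw = rng.random(n_var) < config.relative_redraw_prob
        fresh = (rng.random((2, int(redraw.sum()))) < true_af[redraw][None, :]).sum(axis=0)
        copy[redraw] = fresh.astype(np.int8)
        dosages[:, j] = copy

    first_outlier = 2 * config.n_related_pairs
    q = true_af
    p_hom_ref = (1 - q) ** 2
    p_het = 2 * q * (1 - q) * config.het_inflation
    p_hom_alt = q**2
    total = p_hom_ref + p_het + p_hom_alt
    cum1 = p_hom_ref / total
    cum2 = (p_hom_ref + p_het) / total
    for k in range(config.n_het_outliers):
        s = first_outlier + k
        het_outlier[s] = True
        u = rng.random(n_var)
        dosages[:, s] = np.where(u < cum1, 0, np.where(u < cum2, 1, 2)).astype(np.int8)

    if config.missing_rate > 0:
        miss = rng.random((n_var, n_sam)) < config.missing_rate
        dosages[miss] = -1

    phenotype = np.array(
        [ELIGIBLE_PHENOTYPES[i] for i in rng.integers(0, len(ELIGIBLE_PHENOTYPES), n_sam)],
        dtype=object,
    )
    if config.excluded_phenotype_fraction > 0:
        # exclusions drawn among samples not already serving another role
        free = np.arange(first_outlier + config.n_het_outliers, n_sam)
        n_excl = int(round(config.excluded_phenotype_fraction * n_sam))
        n_excl = min(n_excl, free.size)
        phenotype[rng.choice(free, size=n_excl, replace=False)] = EXCLUDED_PHENOTYPE

    annotations = _annotate(panel, config, rng, enriched)
    genotypes = CohortGenotypes(
        sample_ids=sample_ids,
        variant_keys=list(panel.afs.index),
        dosages=dosages,
    )
    metadata = pd.DataFrame(
        {"sample_id": sample_ids, "phenotype": phenotype, "relatedness_group": related_group}
    )

    variant_truth = pd.DataFrame(
        {
            "variant_key": list(panel.afs.index),
            "true_af": true_af,
            "enriched": enriched,
            "pathogenic": (annotations["clinical_significance"] == "pathogenic").to_numpy(),
            "gene": annotations["gene"].to_numpy(),
        }
    )
    sample_truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "relatedness_group": related_group,
            "het_outlier": het_outlier,
            "phenotype": phenotype,
        }
    )
    path = variant_truth[variant_truth["pathogenic"]]
    q_true = path.groupby("gene")["true_af"].sum()
    gene_truth = pd.DataFrame(
        {"gene": q_true.index, "q_true": q_true.to_numpy(), "incidence_true": q_true.to_numpy() ** 2}
    ).reset_index(drop=True)

    truth = SimulationTruth(variants=variant_truth, samples=sample_truth, genes=gene_truth)
    return genotypes, annotations, metadata, truth


def _annotate(
    panel: ReferencePanel,
    config: SimulationConfig,
    rng: np.random.Generator,
    enriched: np.ndarray,
) -> pd.DataFrame:
    """Build the per-variant annotation table the cohort reader consumes."""
    n_var = panel.afs.shape[0]
    sites = [_synthetic_site(i) for i in range(n_var)]

    n_path = int(round(config.pathogenic_fraction * n_var))
    # enriched variants are always pathogenic so planted signals are testable
    pathogenic = np.zeros(n_var, dtype=bool)
    pathogenic[enriched] = True
    target_af = panel.afs.iloc[:, config.target_population_index].to_numpy()
    extra = max(0, n_path - int(pathogenic.sum()))
    if extra > 0:
        # pathogenic recessive alleles are rare: prefer sites under 0.5% AF
        rare = np.flatnonzero(~pathogenic & (target_af < 0.005))
        if rare.size >= extra:
            chosen = rng.choice(rare, size=extra, replace=False)
        else:
            rest = np.flatnonzero(~pathogenic)
            chosen = rest[np.argsort(target_af[rest], kind="stable")[:extra]]
        pathogenic[chosen] = True

    clinsig = np.where(pathogenic, "pathogenic",
                       np.where(rng.random(n_var) < 0.1, "VUS", "benign"))
    inheritance = np.where(pathogenic, "AR",
                           np.where(rng.random(n_var) < 0.2, "AD", "unknown"))

    gene = np.array([f"GENE{1 + i // max(1, config.variants_per_gene):04d}"
                     for i in range(n_var)], dtype=object)
    # pathogenic variants are re-grouped onto consecutive disease genes so
    # per-gene cumulative frequencies aggregate over >1 variant
    path_idx = np.flatnonzero(pathogenic)
    for rank, i in enumerate(path_idx):
        gene[i] = f"DGENE{1 + rank // max(1, config.variants_per_gene):03d}"

    novel = rng.random(n_var) < config.novel_fraction
    rsid = np.array([("." if novel[i] else f"rs{900000 + i}") for i in range(n_var)],
                    dtype=object)

    impact = rng.choice(
        np.array(["MODIFIER", "LOW", "MODERATE", "HIGH"]),
        size=n_var,
        p=[0.55, 0.15, 0.25, 0.05],
    )

    cohort_af = panel.afs.iloc[:, config.target_population_index].to_numpy()
    quality = (
        config.quality_mean
        + config.quality_af_slope * cohort_af
        + config.quality_novel_effect * novel
        + rng.normal(0.0, config.quality_sd, n_var)
    )
    quality = np.clip(quality, 0.0, None)

    frame = pd.DataFrame(
        {
            "chrom": [s[0] for s in sites],
            "pos": [s[1] for s in sites],
            "ref": [s[2] for s in sites],
            "alt": [s[3] for s in sites],
            "rsid": rsid,
            "gene": gene,
            "impact": impact,
            "clinical_significance": clinsig,
            "inheritance": inheritance,
            "site_quality": np.round(quality, 2),
            "ref_mean_coverage": np.round(panel.mean_coverage.to_numpy(), 2),
            "af_ALL": panel.overall_af().to_numpy(),
        }
    )
    for pop in panel.populations:
        frame[f"af_{pop}"] = panel.afs[pop].to_numpy()
    frame.index = pd.Index(panel.afs.index, name="variant_key")
    return frame


# ---------------------------------------------------------------------------
# plain-text writers


def write_cohort(
    out_dir: str | Path,
    genotypes: CohortGenotypes,
    annotations: pd.DataFrame,
    metadata: pd.DataFrame,
    truth: SimulationTruth | None = None,
) -> dict[str, Path]:
    """Write VCF + TSV files for a simulated cohort; returns the paths.

    The VCF is VCFv4.2 with a GT-only FORMAT and ``./.`` for missing
    genotypes; identical inputs produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "annotations": out / "annotations.tsv",
        "metadata": out / "metadata.tsv",
    }
    write_vcf(paths["vcf"], genotypes, annotations)
    annotations.to_csv(paths["annotations"], sep="\t", index=False)
    metadata.to_csv(paths["metadata"], sep="\t", index=False)
    if truth is not None:
        paths["truth_variants"] = out / "truth_variants.tsv"
        paths["truth_samples"] = out / "truth_samples.tsv"
        paths["truth_genes"] = out / "truth_genes.tsv"
        truth.variants.to_csv(paths["truth_variants"], sep="\t", index=False)
        truth.samples.to_csv(paths["truth_samples"], sep="\t", index=False)
        truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    return paths


_GT_STRINGS = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(path: str | Path, genotypes: CohortGenotypes, annotations: pd.DataFrame) -> None:
    ann = annotations.reset_index(drop=True)
    if len(ann) != len(genotypes.variant_keys):
        raise ValueError("annotation rows must match variant count")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(ann["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(genotypes.sample_ids) + "\n")
        for i in range(len(ann)):
            row = ann.iloc[i]
            gts = "\t".join(_GT_STRINGS[int(d)] for d in genotypes.dosages[i])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['rsid']}\t{row['ref']}\t"
                f"{row['alt']}\t{row['site_quality']}\t.\t.\tGT\t{gts}\n"
            )


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["enrichment_map"] = {str(k): v for k, v in config.enrichment_map.items()}
    return d
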