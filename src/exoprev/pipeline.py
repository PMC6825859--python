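"""Pipeline orchestration: config, staged execution, fixtures, manifest.

``run_pipeline`` executes read → curate → spectrum → prevalence →
incidence, writing each stage's tables plus a machine-readable run
manifest (package version, seed, thresholds, input checksums). Identical
configuration and inputs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curation import curate
from .incidence import gene_incidence_table
from .io import read_cohort, site_stats
from .prevalence import filter_candidates, rank_enrichment
from .simulate import (
    ELIGIBLE_PHENOTYPES,
    ReferencePanel,
    SimulationConfig,
    SimulationTruth,
    simulate_cohort,
    simulate_reference_panel,
    write_cohort,
)
from .spectrum import af_concordance, af_rmsd, fit_quality_model, pca_populations, summarize_spectrum

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "make_fixture",
           "panel_from_annotations"]

ALL_STAGES = ("curate", "spectrum", "prevalence", "incidence")


@dataclass(frozen=True)
class PipelineConfig:
    """Paths, thresholds and options controlling one pipeline run."""

    vcf: str
    annotations: str
    metadata: str
    output_dir: str
    comparison_population: str
    allowed_phenotypes: tuple[str, ...] = tuple(ELIGIBLE_PHENOTYPES)
    af_max: float = 0.005
    min_gene_alleles: int = 4
    coverage_min: float = 15.0
    confidence: float = 0.95
    het_outlier_k: float = 4.0
    ci_method: str = "wilson"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.af_max <= 1.0:
            raise ValueError("af_max must lie in [0, 1]")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must lie in (0, 1)")
        if self.min_gene_alleles < 1:
            raise ValueError("min_gene_alleles must be >= 1")
        if self.coverage_min < 0:
            raise ValueError("coverage_min must be non-negative")
        if self.ci_method not in ("wilson", "clopper-pearson"):
            raise ValueError("ci_method must be 'wilson' or 'clopper-pearson'")


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    if "allowed_phenotypes" in raw:
        raw["allowed_phenotypes"] = tuple(raw["allowed_phenotypes"])
    return PipelineConfig(**raw)


def panel_from_annotations(annotations: pd.DataFrame) -> ReferencePanel:
    """Rebuild the reference panel from annotation ``af_<pop>`` columns."""
    pops = [c[3:] for c in annotations.columns
            if c.startswith("af_") and c != "af_ALL"]
    if not pops:
        raise ValueError("annotations carry no per-population AF columns")
    afs = annotations[[f"af_{p}" for p in pops]].copy()
    afs.columns = pops
    return ReferencePanel(
        afs=afs.astype(float),
        mean_coverage=annotations["ref_mean_coverage"].astype(float),
    )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.ndarray, pd.Series)):
        return list(x)
    raise TypeError(f"not JSON serialisable: {type(x)}")


def run_pipeline(config: PipelineConfig, stages=ALL_STAGES) -> dict:
    """Run the requested stages and return the in-memory run report.

    Later stages depend on earlier ones: prevalence and incidence always
    run on the curated sample set, and incidence consumes the prevalence
    candidates. Any stage failure aborts with the stage name in the
    exception message.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "stages": {}}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    genotypes, variants, metadata = _stage(
        "read", lambda: read_cohort(config.vcf, config.annotations, config.metadata)
    )
    full_stats = site_stats(genotypes)
    report["stages"]["read"] = {
        "n_samples": genotypes.n_samples,
        "n_variants": genotypes.n_variants,
    }

    kept = list(genotypes.sample_ids)
    if set(stages) & set(ALL_STAGES):
        def _curate():
            k, rep = curate(genotypes, metadata, config.allowed_phenotypes,
                            het_k=config.het_outlier_k)
            rep.decisions.to_csv(out / "curation_decisions.tsv", sep="\t")
            _write_json(out / "curation_summary.json", {
                "reason_counts": rep.reason_counts,
                "retained_variant_fraction": rep.retained_variant_fraction,
                "n_kept": len(k),
            })
            return k, rep

        kept, curation_report = _stage("curate", _curate)
        report["stages"]["curate"] = {
            "n_kept": len(kept),
            "reason_counts": curation_report.reason_counts,
            "retained_variant_fraction": curation_report.retained_variant_fraction,
        }
        logger.info("curation kept %d of %d samples (retained-variant fraction %.3f)",
                    len(kept), genotypes.n_samples,
                    curation_report.retained_variant_fraction)

    curated_stats = site_stats(genotypes, kept)
    panel = panel_from_annotations(variants)

    if "spectrum" in stages:
        def _spectrum():
            summary = summarize_spectrum(variants, full_stats, genotypes)
            res = {
                "impact_counts": summary.impact_counts.to_dict(),
                "novelty_counts": summary.novelty_counts.to_dict(),
                "novel_fraction": float(summary.novelty_fractions["novel"]),
                "chi2_statistic": summary.chi2_statistic,
                "chi2_pvalue": summary.chi2_pvalue,
                "mean_high_impact_per_sample": summary.mean_high_impact_per_sample,
            }
            summary.impact_by_novelty.to_csv(out / "impact_by_novelty.tsv", sep="\t")
            try:
                model = fit_quality_model(variants, full_stats)
                res["quality_model"] = {
                    "params": model.params.to_dict(),
                    "pvalues": model.pvalues.to_dict(),
                }
            except ValueError as exc:
                logger.warning("quality regression skipped: %s", exc)
            res["af_concordance"] = af_concordance(
                full_stats, panel, config.comparison_population,
                min_coverage=config.coverage_min,
            )
            cohort_af = full_stats["af"]
            if len(panel.populations) >= 3:
                coords = pca_populations(panel, cohort_af)
                coords.to_csv(out / "pca_coordinates.tsv", sep="\t")
                res["pca_populations"] = list(coords.index)
            dists = af_rmsd(cohort_af, panel, confidence=config.confidence,
                            seed=config.seed)
            pd.DataFrame([dataclasses.asdict(d) for d in dists]).to_csv(
                out / "rmsd.tsv", sep="\t", index=False)
            res["rmsd"] = {d.population: d.rmsd for d in dists}
            _write_json(out / "spectrum_summary.json", res)
            return res

        report["stages"]["spectrum"] = _stage("spectrum", _spectrum)

    enrichment = pd.DataFrame()
    if "prevalence" in stages or "incidence" in stages:
        def _prevalence():
            cand = filter_candidates(variants, curated_stats, af_max=config.af_max)
            if cand.empty:
                logger.warning("no candidate variants passed the prevalence filter")
                ranked = pd.DataFrame()
            else:
                ranked = rank_enrichment(
                    cand, curated_stats, config.comparison_population,
                    confidence=config.confidence, full_site_stats=full_stats,
                    ci_method=config.ci_method,
                )
            ranked.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            return cand, ranked

        candidates, enrichment = _stage("prevalence", _prevalence)
        report["stages"]["prevalence"] = {
            "n_candidates": len(candidates),
            "n_reported": len(enrichment),
        }

    if "incidence" in stages:
        def _incidence():
            table = gene_incidence_table(
                candidates, curated_stats,
                genotypes=genotypes.subset_samples(kept),
                min_alleles=config.min_gene_alleles,
                confidence=config.confidence,
                full_site_stats=full_stats,
            )
            table.to_csv(out / "incidence.tsv", sep="\t", index=False)
            _write_json(out / "incidence.json",
                        {r["gene"]: r for r in table.to_dict("records")})
            return table

        incidence_table = _stage("incidence", _incidence)
        report["stages"]["incidence"] = {"n_genes": len(incidence_table)}

    manifest = {
        "package": "exoprev",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "af_max": config.af_max,
            "min_gene_alleles": config.min_gene_alleles,
            "coverage_min": config.coverage_min,
            "confidence": config.confidence,
            "het_outlier_k": config.het_outlier_k,
            "ci_method": config.ci_method,
        },
        "inputs": {
            "vcf": _sha256(config.vcf),
            "annotations": _sha256(config.annotations),
            "metadata": _sha256(config.metadata),
        },
        "stages_run": list(stages),
    }
    _write_json(out / "manifest.json", manifest)
    report["manifest"] = manifest
    return report


# ---------------------------------------------------------------------------
# fixtures

FIXTURE_KINDS = ("table_arithmetic", "null_cohort", "enriched_cohort")

# (gene, disease, rsid, panel AF, comparison-population AF, het carrier counts
#  per variant). Counts follow the printed curated allele counts of the
# emulated study's self-consistent table rows.
_TABLE_GENES = [
    ("PAH", "Phenylketonuria", ["rs5030858", "rs5030861", "rs62516101"],
     [7.6e-4, 4.0e-4, 2.0e-4], [0.0015, 0.0006, 0.0003], [6, 3, 2]),
    ("ABCA4", "Stargardt disease", ["rs61750200", "rs61751374", "rs76157638"],
     [9.0e-4, 6.0e-4, 5.0e-4], [0.0012, 0.0008, 0.0007], [5, 4, 4]),
    ("F7", "Factor VII deficiency", ["rs36209567"], [5.6e-4], [0.0010], [5]),
    ("ATP7B", "Wilson's disease", ["rs76151636"], [9.2e-4], [0.0013], [4]),
]


def make_fixture(kind: str, out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a small deterministic input set of the requested kind.

    ``table_arithmetic`` plants exactly the curated heterozygous allele
    counts of the emulated study's result tables in a 372-sample cohort
    with no missingness (so N = 744 chromosomes at every site);
    ``null_cohort`` simulates a cohort with no planted enrichment;
    ``enriched_cohort`` plants three variants at 4–8x enrichment and
    records them in the truth tables.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    out = Path(out_dir)
    if kind == "table_arithmetic":
        return _table_arithmetic_fixture(out)
    if kind == "null_cohort":
        cfg = SimulationConfig(n_variants=1500, n_samples=372, seed=seed)
    else:
        cfg = SimulationConfig(
            n_variants=1500, n_samples=372, seed=seed,
            enrichment_map={10: 8.0, 11: 5.0, 12: 4.0},
        )
    panel = simulate_reference_panel(cfg)
    genotypes, ann, meta, truth = simulate_cohort(panel, cfg)
    return write_cohort(out, genotypes, ann, meta, truth)


def _table_arithmetic_fixture(out: Path) -> dict[str, Path]:
    n_samples = 372
    rows, dosage_rows = [], []
    pos = 10_001
    carrier_cursor = 0
    for gene, disease, rsids, panel_afs, comp_afs, counts in _TABLE_GENES:
        for rsid, p_af, c_af, count in zip(rsids, panel_afs, comp_afs, counts):
            dos = np.zeros(n_samples, dtype=np.int8)
            # spread carriers so nobody is homozygous at any single site
            for _ in range(count):
                dos[carrier_cursor % n_samples] = 1
                carrier_cursor += 1
            dosage_rows.append(dos)
            rows.append({
                "chrom": "1", "pos": pos, "ref": "G", "alt": "A",
                "rsid": rsid, "gene": gene, "impact": "MODERATE",
                "clinical_significance": "pathogenic", "inheritance": "AR",
                "site_quality": 100.0, "ref_mean_coverage": 50.0,
                "af_ALL": p_af, "af_NFE": c_af, "disease": disease,
            })
            pos += 1000
    # benign background sites give every sample a comparable heterozygosity,
    # so the planted carriers are not spurious het outliers under the QC rule
    rng = np.random.default_rng(20_240_101)
    for b in range(60):
        af = float(rng.uniform(0.2, 0.5))
        dos = rng.choice(np.int8([0, 1, 2]), size=n_samples,
                         p=[(1 - af) ** 2, 2 * af * (1 - af), af**2]).astype(np.int8)
        dosage_rows.append(dos)
        novel = b % 10 == 9
        rows.append({
            "chrom": "1", "pos": pos, "ref": "C", "alt": "T",
            "rsid": "." if novel else f"rs{100000 + b}", "gene": f"BG{b:03d}",
            "impact": "MODIFIER", "clinical_significance": "benign",
            "inheritance": "unknown",
            "site_quality": round(float(rng.normal(80.0, 5.0)), 2),
            "ref_mean_coverage": 50.0,
            "af_ALL": af, "af_NFE": af, "disease": "",
        })
        pos += 1000
    ann = pd.DataFrame(rows)
    from .io import CohortGenotypes, variant_key

    keys = [variant_key(r["chrom"], r["pos"], r["ref"], r["alt"]) for r in rows]
    ann.index = pd.Index(keys, name="variant_key")
    genotypes = CohortGenotypes(
        sample_ids=[f"S{i:04d}" for i in range(n_samples)],
        variant_keys=keys,
        dosages=np.vstack(dosage_rows),
    )
    meta = pd.DataFrame({
        "sample_id": genotypes.sample_ids,
        "phenotype": ["control"] * n_samples,
        "relatedness_group": [""] * n_samples,
    })
    return write_cohort(out, genotypes, ann, meta)
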