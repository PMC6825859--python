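import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from exoprev.io import CohortGenotypes
from exoprev.simulate import SimulationConfig, simulate_cohort, simulate_reference_panel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort with planted relatives and het outliers."""
    cfg = SimulationConfig(
        n_variants=500,
        n_samples=80,
        missing_rate=0.02,
        n_related_pairs=5,
        n_het_outliers=3,
        het_inflation=2.5,
        seed=11,
    )
    panel = simulate_reference_panel(cfg)
    genotypes, ann, meta, truth = simulate_cohort(panel, cfg)
    return {"config": cfg, "panel": panel, "genotypes": genotypes,
            "annotations": ann, "metadata": meta, "truth": truth}


@pytest.fixture()
def toy_genotypes():
    """Three samples, two sites, hand-checkable counts."""
    return CohortGenotypes(
        sample_ids=["s1", "s2", "s3"],
        variant_keys=["1:100:A:G", "1:200:C:T"],
        dosages=np.array([[1, 0, -1], [-1, -1, -1]], dtype=np.int8),
    )


def make_genotypes(dosages, prefix="s"):
    dosages = np.asarray(dosages, dtype=np.int8)
    return CohortGenotypes(
        sample_ids=[f"{prefix}{j}" for j in range(dosages.shape[1])],
        variant_keys=[f"1:{100 + i}:A:G" for i in range(dosages.shape[0])],
        dosages=dosages,
    )


def make_metadata(sample_ids, phenotype="control", groups=None):
    return pd.DataFrame({
        "sample_id": list(sample_ids),
        "phenotype": [phenotype] * len(sample_ids)
        if isinstance(phenotype, str) else list(phenotype),
        "relatedness_group": [""] * len(sample_ids) if groups is None else list(groups),
    })
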