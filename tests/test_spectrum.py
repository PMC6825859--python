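"""Spectrum analysis: novelty/impact tabulation, quality OLS, AF concordance,
population PCA and RMSD."""

import numpy as np
import pandas as pd
import pytest

from exoprev.io import site_stats
from exoprev.simulate import (
    SimulationConfig,
    panel_from_afs,
    simulate_cohort,
    simulate_reference_panel,
)
from exoprev.spectrum import (
    af_concordance,
    af_rmsd,
    fit_quality_model,
    pca_populations,
    summarize_spectrum,
)


def _variants(n, novel_mask, impact=None, quality=None, keys=None):
    frame = pd.DataFrame(
        {
            "rsid": [np.nan if novel_mask[i] else f"rs{i}" for i in range(n)],
            "impact": impact if impact is not None else ["MODIFIER"] * n,
            "site_quality": quality if quality is not None else np.full(n, 50.0),
        },
        index=pd.Index(keys if keys is not None else [f"1:{i}:A:G" for i in range(n)],
                       name="variant_key"),
    )
    return frame


def test_novelty_and_impact_tabulation():
    novel = np.array([True, False, False, True, False])
    impact = ["HIGH", "HIGH", "MODERATE", "MODIFIER", "LOW"]
    summary = summarize_spectrum(_variants(5, novel, impact))
    assert summary.novelty_counts["novel"] == 2
    assert summary.impact_counts["HIGH"] == 2
    assert summary.impact_by_novelty.loc["HIGH", "novel"] == 1
    assert summary.impact_by_novelty.to_numpy().sum() == 5
    assert summary.novelty_fractions.sum() == pytest.approx(1.0)


def test_chi2_zero_when_strata_match():
    # identical novelty proportions in high-impact and rest: no association
    novel = np.array([True, False, False, False] * 10)
    impact = (["HIGH"] * 4 + ["LOW"] * 4) * 5
    summary = summarize_spectrum(_variants(40, novel, impact))
    assert summary.chi2_statistic == pytest.approx(0.0, abs=1e-12)


def test_quality_model_null_recovery():
    rng = np.random.default_rng(4)
    n = 10_000
    novel = rng.random(n) < 0.1
    quality = rng.normal(60, 5, n)
    variants = _variants(n, novel, quality=quality)
    st = pd.DataFrame({"af": rng.uniform(0, 0.5, n)}, index=variants.index)
    model = fit_quality_model(variants, st)
    assert abs(model.params["novel"]) < 3 * model.bse["novel"]


def test_quality_model_af_slope_recovery():
    rng = np.random.default_rng(5)
    n = 10_000
    novel = rng.random(n) < 0.1
    af = rng.uniform(0, 1, n)
    quality = 50 + 10 * af + rng.normal(0, 1, n)
    variants = _variants(n, novel, quality=quality)
    st = pd.DataFrame({"af": af}, index=variants.index)
    model = fit_quality_model(variants, st)
    assert model.params["af"] == pytest.approx(10.0, abs=0.5)


def test_quality_model_exact_interpolation():
    # three points determine the plane exactly: residuals vanish
    variants = _variants(3, np.array([True, False, False]),
                         quality=np.array([40.0, 55.0, 61.0]))
    st = pd.DataFrame({"af": [0.1, 0.2, 0.5]}, index=variants.index)
    model = fit_quality_model(variants, st)
    X = np.column_stack([np.ones(3), [1, 0, 0], [0.1, 0.2, 0.5]])
    pred = X @ model.params.to_numpy()
    assert np.allclose(pred, [40.0, 55.0, 61.0], atol=1e-8)


def test_quality_model_requires_both_classes():
    variants = _variants(5, np.zeros(5, dtype=bool))
    st = pd.DataFrame({"af": np.linspace(0, 1, 5)}, index=variants.index)
    with pytest.raises(ValueError, match="novel"):
        fit_quality_model(variants, st)


def test_ols_matches_normal_equations_oracle():
    rng = np.random.default_rng(8)
    for _ in range(10):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        import statsmodels.api as sm

        fit = sm.OLS(y, X).fit()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.params, beta, atol=1e-8)


def test_af_concordance_perfect_match():
    afs = np.linspace(0.05, 0.5, 30)[:, None] * np.ones((1, 5))
    panel = panel_from_afs(afs)
    st = pd.DataFrame({"af": afs[:, 0], "af_undefined": False}, index=panel.afs.index)
    res = af_concordance(st, panel, "pop0", min_coverage=15)
    assert res["r_squared"] == pytest.approx(1.0)
    assert res["slope"] == pytest.approx(1.0)


def test_af_concordance_coverage_filter_errors_when_empty():
    afs = np.full((10, 5), 0.2)
    panel = panel_from_afs(afs, mean_coverage=np.full(10, 5.0))
    st = pd.DataFrame({"af": afs[:, 0], "af_undefined": False}, index=panel.afs.index)
    with pytest.raises(ValueError, match="qualifying sites"):
        af_concordance(st, panel, "pop0", min_coverage=15)


def test_af_concordance_high_r2_at_low_divergence():
    cfg = SimulationConfig(
        n_variants=20_000, n_samples=300, missing_rate=0.0,
        fst_per_population=(0.001, 0.05, 0.08, 0.12, 0.2), seed=31,
    )
    panel = simulate_reference_panel(cfg)
    genotypes, _, _, _ = simulate_cohort(panel, cfg)
    st = site_stats(genotypes)
    res = af_concordance(st, panel, "pop0", min_coverage=15)
    assert res["r_squared"] >= 0.95


def test_pca_small_instance_matches_eigendecomposition():
    afs = np.array([[0.1, 0.5], [0.2, 0.4], [0.9, 0.1]]).T  # 2 variants x 3 pops
    panel = panel_from_afs(afs, labels=("a", "b", "c"))
    cohort = pd.Series([0.15, 0.45], index=panel.afs.index)
    coords = pca_populations(panel, cohort)
    # brute force: eigendecomposition of the covariance of centred rows
    mat = np.vstack([afs.T, [0.15, 0.45]])
    c = mat - mat.mean(axis=0)
    evals, evecs = np.linalg.eigh(c @ c.T)
    order = np.argsort(evals)[::-1]
    for k in range(2):
        brute = evecs[:, order[k]] * np.sqrt(max(evals[order[k]], 0))
        got = coords.iloc[:, k].to_numpy()
        if brute[0] < 0:
            brute = -brute
        assert np.allclose(got, brute, atol=1e-9)


def test_pca_identical_populations_coincide():
    afs = np.column_stack([np.linspace(0.1, 0.9, 8)] * 2 + [np.linspace(0.9, 0.1, 8)])
    panel = panel_from_afs(afs, labels=("a", "b", "c"))
    cohort = pd.Series(np.linspace(0.1, 0.9, 8), index=panel.afs.index)
    coords = pca_populations(panel, cohort)
    assert np.allclose(coords.loc["a"], coords.loc["b"], atol=1e-12)


def test_pca_invariant_to_variant_order():
    rng = np.random.default_rng(12)
    afs = rng.uniform(0, 1, size=(50, 4))
    panel = panel_from_afs(afs, labels=("a", "b", "c", "d"))
    cohort = pd.Series(rng.uniform(0, 1, 50), index=panel.afs.index)
    coords = pca_populations(panel, cohort)
    perm = rng.permutation(50)
    from exoprev.simulate import ReferencePanel

    panel2 = ReferencePanel(afs=panel.afs.iloc[perm], mean_coverage=panel.mean_coverage.iloc[perm])
    coords2 = pca_populations(panel2, cohort.iloc[perm])
    assert np.allclose(coords.to_numpy(), coords2.to_numpy(), atol=1e-9)


def test_rmsd_hand_arithmetic_and_identity():
    afs = np.column_stack([[0.1, 0.4], [0.1, 0.2]])
    panel = panel_from_afs(afs, labels=("far", "same"))
    cohort = pd.Series([0.1, 0.2], index=panel.afs.index)
    dists = {d.population: d for d in af_rmsd(cohort, panel)}
    assert dists["same"].rmsd == pytest.approx(0.0, abs=1e-15)
    assert dists["far"].rmsd == pytest.approx(np.sqrt(0.02))
    for d in dists.values():
        assert d.ci_lower <= d.rmsd <= d.ci_upper or d.rmsd == 0.0


def test_rmsd_symmetric():
    rng = np.random.default_rng(3)
    x = pd.Series(rng.uniform(0, 1, 40))
    y = pd.Series(rng.uniform(0, 1, 40))
    d_xy = np.sqrt(((x - y) ** 2).mean())
    panel = panel_from_afs(np.column_stack([y, x]), labels=("p", "q"))
    x.index = panel.afs.index
    y.index = panel.afs.index
    dists = {d.population: d.rmsd for d in af_rmsd(x, panel)}
    assert dists["p"] == pytest.approx(d_xy)
    # swapping the roles of the two AF vectors leaves the RMSD unchanged
    dists_swapped = {d.population: d.rmsd for d in af_rmsd(y, panel_from_afs(
        np.column_stack([x, y]), labels=("p", "q")))}
    assert dists_swapped["p"] == pytest.approx(d_xy)


def test_rmsd_bootstrap_ci_seeded():
    rng = np.random.default_rng(6)
    afs = rng.uniform(0, 1, size=(60, 2))
    panel = panel_from_afs(afs, labels=("p", "q"))
    cohort = pd.Series(rng.uniform(0, 1, 60), index=panel.afs.index)
    a = af_rmsd(cohort, panel, method="bootstrap", seed=5)
    b = af_rmsd(cohort, panel, method="bootstrap", seed=5)
    assert [(d.ci_lower, d.ci_upper) for d in a] == [(d.ci_lower, d.ci_upper) for d in b]
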