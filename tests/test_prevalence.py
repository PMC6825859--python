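"""Candidate filtering, binomial enrichment test and binomial proportion CIs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from exoprev.prevalence import (
    binomial_enrichment,
    clopper_pearson_ci,
    filter_candidates,
    rank_enrichment,
    wilson_ci,
)


def _candidate_frame(rows):
    frame = pd.DataFrame(rows)
    frame.index = pd.Index([f"1:{100 + i}:A:G" for i in range(len(rows))],
                           name="variant_key")
    return frame


def _stats_frame(index, ac, an, n_hom_alt=None):
    ac = np.asarray(ac)
    an = np.asarray(an)
    return pd.DataFrame(
        {
            "ac": ac,
            "an": an,
            "af": np.where(an > 0, ac / np.maximum(an, 1), np.nan),
            "n_het": ac if n_hom_alt is None else ac - 2 * np.asarray(n_hom_alt),
            "n_hom_alt": 0 if n_hom_alt is None else n_hom_alt,
            "af_undefined": an == 0,
        },
        index=index,
    )


def test_filter_rules():
    variants = _candidate_frame([
        # retained: rare pathogenic AR, strictly het
        {"clinical_significance": "pathogenic", "inheritance": "AR",
         "af_ALL": 0.0015, "rsid": "rs1", "gene": "PAH"},
        # excluded: hom-alt carrier present
        {"clinical_significance": "pathogenic", "inheritance": "AR",
         "af_ALL": 0.001, "rsid": "rs2", "gene": "G2"},
        # excluded: benign
        {"clinical_significance": "benign", "inheritance": "AR",
         "af_ALL": 0.0001, "rsid": "rs3", "gene": "G3"},
        # excluded: too common in the panel
        {"clinical_significance": "pathogenic", "inheritance": "AR",
         "af_ALL": 0.02, "rsid": "rs4", "gene": "G4"},
        # excluded: not observed in cohort
        {"clinical_significance": "pathogenic", "inheritance": "AR",
         "af_ALL": 0.001, "rsid": "rs5", "gene": "G5"},
        # retained and flagged: absent from panel
        {"clinical_significance": "pathogenic", "inheritance": "AR",
         "af_ALL": np.nan, "rsid": "rs6", "gene": "G6"},
        # excluded: dominant inheritance
        {"clinical_significance": "pathogenic", "inheritance": "AD",
         "af_ALL": 0.001, "rsid": "rs7", "gene": "G7"},
    ])
    stats = _stats_frame(variants.index,
                         ac=[6, 4, 2, 3, 0, 1, 2],
                         an=[744] * 7,
                         n_hom_alt=[0, 1, 0, 0, 0, 0, 0])
    out = filter_candidates(variants, stats, af_max=0.005)
    assert list(out["rsid"]) == ["rs1", "rs6"]
    assert not out.loc[out["rsid"] == "rs1", "absent_from_panel"].iloc[0]
    assert out.loc[out["rsid"] == "rs6", "absent_from_panel"].iloc[0]
    assert out.loc[out["rsid"] == "rs6", "panel_af"].iloc[0] == 0.0


def test_binomial_boundary_cases():
    assert binomial_enrichment(0, 744, 0.1) == 1.0
    assert binomial_enrichment(1, 2, 0.5) == pytest.approx(0.75)
    with pytest.warns(UserWarning, match="degenerate"):
        assert binomial_enrichment(3, 100, 0.0) == 0.0
    with pytest.raises(ValueError):
        binomial_enrichment(5, 4, 0.1)
    with pytest.raises(ValueError):
        binomial_enrichment(1, 10, 1.5)


def test_binomial_tail_example():
    # frozen from direct summation of the Binomial(744, 0.0015) pmf, k=0..5
    assert binomial_enrichment(6, 744, 0.0015) == pytest.approx(
        1.0276689553e-3, rel=1e-8
    )


def test_binomial_tail_matches_summation_oracle():
    # exhaustive sweep over n <= N <= 200 at a fixed reference AF
    p = 0.013
    for N in range(1, 201):
        pmf = sps.binom.pmf(np.arange(N + 1), N, p)
        tail = np.concatenate([np.cumsum(pmf[::-1])[::-1], [0.0]])
        for n in range(0, N + 1, max(1, N // 7)):
            expected = 1.0 if n == 0 else tail[n]
            assert binomial_enrichment(n, N, p) == pytest.approx(expected, abs=1e-12)


@given(st.integers(1, 150), st.integers(0, 150), st.floats(1e-6, 0.5))
def test_binomial_monotone_in_count_and_null(N, n, af):
    n = min(n, N)
    p1 = binomial_enrichment(n, N, af)
    if n < N:
        assert binomial_enrichment(n + 1, N, af) <= p1
    assert binomial_enrichment(n, N, min(af * 1.5, 1.0)) >= p1


def test_wilson_printed_values():
    lo, hi = wilson_ci(6, 744)
    assert (round(lo, 4), round(hi, 4)) == (0.0037, 0.0175)
    assert round(wilson_ci(5, 744)[0], 4) == 0.0029
    assert wilson_ci(0, 100)[0] == 0.0


def test_wilson_rejects_bad_input():
    with pytest.raises(ValueError):
        wilson_ci(1, 0)
    with pytest.raises(ValueError):
        wilson_ci(5, 4)
    with pytest.raises(ValueError):
        wilson_ci(1, 10, confidence=1.0)


def _wilson_oracle(n, N, confidence=0.95):
    # closed-form solution of the score-test quadratic
    z = sps.norm.ppf(1 - (1 - confidence) / 2)
    p = n / N
    denom = 1 + z**2 / N
    center = (p + z**2 / (2 * N)) / denom
    half = z * np.sqrt(p * (1 - p) / N + z**2 / (4 * N**2)) / denom
    return center - half, center + half


def test_wilson_matches_quadratic_oracle():
    for N in range(1, 201, 7):
        for n in range(0, N + 1, max(1, N // 5)):
            got = wilson_ci(n, N)
            want = _wilson_oracle(n, N)
            assert got[0] == pytest.approx(want[0], abs=1e-12)
            assert got[1] == pytest.approx(want[1], abs=1e-12)


def test_wilson_contains_point_estimate_exhaustive():
    for N in range(1, 201):
        n = np.arange(N + 1)
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = proportion_confint(n, N, method="wilson")
        p = n / N
        assert (lo <= p + 1e-15).all() and (p <= hi + 1e-15).all()
        # spot-check the scalar API agrees
        mid = N // 2
        assert wilson_ci(mid, N) == (pytest.approx(np.atleast_1d(lo)[mid]),
                                     pytest.approx(np.atleast_1d(hi)[mid]))


def test_clopper_pearson_wider_than_wilson():
    # width comparison holds away from the n=0 / n=N boundaries
    for n, N in [(3, 100), (6, 744), (5, 744), (20, 50)]:
        w = wilson_ci(n, N)
        cp = clopper_pearson_ci(n, N)
        assert cp[1] - cp[0] >= w[1] - w[0] - 1e-12
        assert cp[0] <= n / N + 1e-12 and n / N <= cp[1] + 1e-12
    for n, N in [(0, 50), (50, 50)]:
        lo, hi = clopper_pearson_ci(n, N)
        assert 0 <= lo <= n / N <= hi <= 1


def test_rank_enrichment_table_values_and_order():
    variants = _candidate_frame([
        {"clinical_significance": "pathogenic", "inheritance": "AR",
         "af_ALL": 7.6e-4, "af_NFE": 0.0015, "rsid": "rs5030858", "gene": "PAH",
         "disease": "Phenylketonuria"},
        {"clinical_significance": "pathogenic", "inheritance": "AR",
         "af_ALL": 5.6e-4, "af_NFE": 0.0010, "rsid": "rs36209567", "gene": "F7",
         "disease": "Factor VII deficiency"},
    ])
    stats = _stats_frame(variants.index, ac=[6, 5], an=[744, 744])
    cand = filter_candidates(variants, stats)
    ranked = rank_enrichment(cand, stats, "NFE")
    assert list(ranked["gene"]) == ["PAH", "F7"]
    assert ranked["estimated_af"].round(4).tolist() == [0.0081, 0.0067]
    assert ranked["ci_lower"].round(4).tolist() == [0.0037, 0.0029]
    assert ranked["ci_upper"].round(4).tolist()[0] == 0.0175
    assert (ranked["p_value"] <= 1).all() and (ranked["p_value"] >= 0).all()
    # ties on estimated AF break by ascending p-value
    stats_tie = _stats_frame(variants.index, ac=[4, 4], an=[744, 744])
    cand_tie = filter_candidates(variants, stats_tie)
    ranked_tie = rank_enrichment(cand_tie, stats_tie, "NFE")
    assert ranked_tie["p_value"].is_monotonic_increasing


def test_null_pvalues_conservative():
    # under the null (af_ref = true AF) the test must not be anticonservative
    rng = np.random.default_rng(99)
    n_rep = 20_000
    af = rng.uniform(5e-4, 5e-3, n_rep)
    N = 744
    ac = rng.binomial(N, af)
    pvals = sps.binom.sf(ac - 1, N, af)
    pvals[ac == 0] = 1.0
    assert (pvals < 0.05).mean() <= 0.06
    # scalar API agrees with the vectorised computation on a sample
    for i in range(0, n_rep, 4000):
        assert binomial_enrichment(int(ac[i]), N, float(af[i])) == pytest.approx(
            pvals[i]
        )
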