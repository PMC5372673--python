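"""Unit and property tests for the single-SNP association machinery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

import cytoqtl as cq
from cytoqtl.association import RESULT_COLUMNS


# ---------------------------------------------------------------- compute_maf

@pytest.mark.parametrize(
    "dosages, maf, flipped",
    [
        ([1, 1, 1, 1], 0.5, False),
        ([0, 0, 1], 1 / 6, False),
        ([2, 2, 1], 1 / 6, True),
        ([0, 0, 0], 0.0, False),
    ],
)
def test_compute_maf(dosages, maf, flipped):
    got_maf, got_flip = cq.compute_maf(dosages)
    assert got_maf == pytest.approx(maf, abs=1e-12)
    assert got_flip is flipped


def test_compute_maf_empty_raises():
    with pytest.raises(ValueError):
        cq.compute_maf([])


# ------------------------------------------------------------ HWE exact test

from tests_support_hwe import hwe_enumeration_oracle  # noqa: E402


@pytest.mark.parametrize(
    "counts, expected",
    [
        ((10, 0, 0), 1.0),  # monomorphic, by convention
        ((25, 50, 25), 1.0),  # observed het count is the modal configuration
    ],
)
def test_hwe_exact_known_values(counts, expected):
    assert cq.hwe_exact_test(*counts) == pytest.approx(expected, abs=1e-9)


def test_hwe_all_heterozygote_is_extreme_tail():
    assert cq.hwe_exact_test(0, 68, 0) < 1e-6


def test_hwe_negative_counts_raise():
    with pytest.raises(ValueError):
        cq.hwe_exact_test(-1, 2, 3)
    with pytest.raises(ValueError):
        cq.hwe_exact_test(0, 0, 0)


@settings(max_examples=150, derandomize=True)
@given(
    st.integers(min_value=0, max_value=30),
    st.integers(min_value=0, max_value=30),
    st.integers(min_value=0, max_value=30),
)
def test_hwe_matches_enumeration_oracle(n_aa, n_ab, n_bb):
    """The log-gamma implementation equals exact rational enumeration."""
    if n_aa + n_ab + n_bb == 0:
        return
    oracle = float(hwe_enumeration_oracle(n_aa, n_ab, n_bb))
    assert cq.hwe_exact_test(n_aa, n_ab, n_bb) == pytest.approx(oracle, rel=1e-9, abs=1e-12)


def test_hwe_symmetric_in_homozygote_labels():
    assert cq.hwe_exact_test(20, 9, 3) == pytest.approx(cq.hwe_exact_test(3, 9, 20))


# ----------------------------------------------------------------- snp_filter

def test_snp_filter_thresholds():
    samples = [f"s{i}" for i in range(60)]
    rng = np.random.default_rng(4)
    good = rng.binomial(2, 0.24, 60).astype(float)
    rare = rng.binomial(2, 0.02, 60).astype(float)
    hwe_bad = np.array([0.0] * 30 + [2.0] * 30)  # no heterozygotes at all
    gm = cq.GenotypeMatrix.from_dosages(
        samples, ["chr1:100", "chr1:200", "chr1:300"],
        np.column_stack([good, rare, hwe_bad]),
    )
    kept, log = cq.snp_filter(gm, cq.AnalysisConfig())
    assert kept.snp_ids == ["chr1:100"]
    assert log["removed_maf"] == 1 and log["removed_hwe"] == 1
    assert log["n_in"] == 3 and log["n_out"] == 1


def test_snp_filter_empty_result_is_not_an_error():
    gm = cq.GenotypeMatrix.from_dosages(
        ["a", "b", "c"], ["chr1:1"], np.array([[0.0], [0.0], [0.0]])
    )
    kept, log = cq.snp_filter(gm)
    assert kept.n_snps == 0 and log["n_out"] == 0


# -------------------------------------------------------------- regress_trait

def test_regress_perfect_fit():
    x = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 0], dtype=float)
    r = cq.regress_trait(x, x)
    assert r.r2 == pytest.approx(1.0)
    assert r.p < 1e-15
    assert r.beta == pytest.approx(1.0)


def test_regress_orthogonal_trait():
    x = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0])
    y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])  # centred, orthogonal to x
    r = cq.regress_trait(x, y)
    assert r.beta == pytest.approx(0.0, abs=1e-12)
    assert r.p == pytest.approx(1.0)


def test_regress_constant_dosage_degenerate_not_exception():
    r = cq.regress_trait([1, 1, 1, 1], [0.1, 0.5, 0.2, 0.9])
    assert r.degenerate and r.p == 1.0 and r.beta == 0.0


def test_regress_too_few_pairs_raises():
    with pytest.raises(ValueError):
        cq.regress_trait([0, 1], [1.0, 2.0])


def test_regress_matches_statsmodels_oracle(rng):
    """beta/se/t/p agree with an independent full-matrix OLS to 1e-10."""
    import statsmodels.api as sm

    for _ in range(10):
        x = rng.binomial(2, 0.3, 20).astype(float)
        if x.std() == 0:
            continue
        y = rng.normal(size=20)
        r = cq.regress_trait(x, y)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert r.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert r.se == pytest.approx(fit.bse[1], abs=1e-10)
        assert r.t == pytest.approx(fit.tvalues[1], abs=1e-8)
        assert r.p == pytest.approx(fit.pvalues[1], abs=1e-10)
        assert r.r2 == pytest.approx(r.t**2 / (r.t**2 + r.n - 2), abs=1e-9)


# ----------------------------------------------------------- association_scan

def _null_panel(n_snps, n_traits, n=68, seed=0):
    rng = np.random.default_rng(seed)
    gm = cq.GenotypeMatrix.from_dosages(
        [f"s{i}" for i in range(n)],
        [f"chr1:{100 + j}" for j in range(n_snps)],
        rng.binomial(2, rng.uniform(0.1, 0.5, n_snps), (n, n_snps)).astype(float),
    )
    traits = pd.DataFrame(
        rng.normal(size=(n, n_traits)),
        index=gm.samples,
        columns=[f"t{k}" for k in range(n_traits)],
    )
    return gm, traits


def test_scan_null_calibration():
    """5,000 null pairs: tail fraction near the nominal 0.001 level."""
    gm, traits = _null_panel(100, 50, seed=5)
    res = cq.association_scan(gm, traits)
    frac = float((res["p"] <= 0.001).mean())
    assert 0.0002 <= frac <= 0.003
    assert kstest(res["p"], "uniform").pvalue >= 0.01


def test_scan_r2_t_consistency():
    gm, traits = _null_panel(30, 10, seed=6)
    res = cq.association_scan(gm, traits)
    expect = res["t"] ** 2 / (res["t"] ** 2 + res["n"] - 2)
    assert np.allclose(res["r2"], expect, atol=1e-9)


def test_scan_empty_trait_matrix():
    gm, traits = _null_panel(5, 3)
    res = cq.association_scan(gm, traits.iloc[:, :0])
    assert len(res) == 0 and list(res.columns) == RESULT_COLUMNS


def test_scan_sample_mismatch_raises():
    gm, traits = _null_panel(5, 3)
    traits.index = [f"other{i}" for i in range(len(traits))]
    with pytest.raises(ValueError, match="sample ids"):
        cq.association_scan(gm, traits)


def test_scan_missing_values_use_pairwise_deletion():
    gm, traits = _null_panel(8, 2, seed=7)
    traits.iloc[[0, 3, 5], 0] = np.nan
    res = cq.association_scan(gm, traits)
    row = res[(res["snp_id"] == gm.snp_ids[2]) & (res["trait_id"] == "t0")].iloc[0]
    mask = traits["t0"].notna().to_numpy()
    direct = cq.regress_trait(gm.dosages[mask, 2], traits["t0"].to_numpy()[mask])
    assert row["n"] == direct.n == mask.sum()
    assert row["p"] == pytest.approx(direct.p, abs=1e-12)


def test_scan_best_keeps_min_p_per_snp():
    gm, traits = _null_panel(20, 15, seed=8)
    full = cq.association_scan(gm, traits)
    best = cq.association_scan(gm, traits, keep="best")
    assert len(best) == gm.n_snps
    mins = full.groupby("snp_id")["p"].min()
    for _, row in best.iterrows():
        assert row["p"] == pytest.approx(mins[row["snp_id"]], abs=0)


def test_scan_recovers_planted_pair(small_cohort):
    cohort, _ = small_cohort
    gm = cohort["genotypes"]
    res = cq.association_scan(gm, cohort["expression"])
    top = res.loc[res["p"].idxmin()]
    assert top["snp_id"] == "chr1:15000" and top["trait_id"] == "gene0001"


# ------------------------------------------------------------------------ LD

def test_ld_r2_identical_and_complementary():
    g = np.array([0, 1, 2, 1, 0, 2, 1, 1], dtype=float)
    assert cq.ld_r2(g, g) == pytest.approx(1.0)
    assert cq.ld_r2(g, 2 - g) == pytest.approx(1.0)


def test_ld_r2_independent_snps_near_zero(rng):
    a = rng.binomial(2, 0.3, 10_000).astype(float)
    b = rng.binomial(2, 0.3, 10_000).astype(float)
    assert cq.ld_r2(a, b) < 0.01


def test_ld_r2_constant_vector_is_zero_by_convention():
    assert cq.ld_r2([1, 1, 1], [0, 1, 2]) == 0.0


def _pruning_panel(seed=9):
    rng = np.random.default_rng(seed)
    base = rng.binomial(2, 0.4, 50).astype(float)
    indep = rng.binomial(2, 0.4, 50).astype(float)
    gm = cq.GenotypeMatrix.from_dosages(
        [f"s{i}" for i in range(50)],
        ["chr1:1000", "chr1:2000", "chr1:900000"],
        np.column_stack([base, base.copy(), indep]),
    )
    return gm


def test_ld_prune_keeps_best_of_correlated_pair():
    gm = _pruning_panel()
    cand = pd.DataFrame(
        {"snp_id": ["chr1:1000", "chr1:2000", "chr1:900000"], "p": [1e-4, 1e-5, 0.5]}
    )
    kept = cq.ld_prune(cand, gm)
    assert "chr1:2000" in kept and "chr1:1000" not in kept
    assert "chr1:900000" in kept  # independent SNP survives


def test_ld_prune_uncorrelated_all_kept_and_deterministic():
    gm, _ = _null_panel(10, 1, n=400, seed=10)
    cand = pd.DataFrame({"snp_id": gm.snp_ids, "p": np.linspace(0.01, 0.1, 10)})
    kept1 = cq.ld_prune(cand, gm)
    kept2 = cq.ld_prune(cand.sample(frac=1, random_state=1), gm)
    assert kept1 == kept2
    assert set(kept1) == set(gm.snp_ids)


def test_ld_prune_soundness_invariant():
    """Every retained pair within the window has r2 <= threshold."""
    cfg = cq.SimulationConfig(
        n_samples=120, n_snps=40, maf_spec=0.3, ld_blocks=[(10, 0.9), (10, 0.9)],
        seed=3,
    )
    gm = cq.simulate_genotypes(cfg)
    acfg = cq.AnalysisConfig()
    cand = pd.DataFrame(
        {"snp_id": gm.snp_ids, "p": np.random.default_rng(2).uniform(size=40)}
    )
    kept = cq.ld_prune(cand, gm, acfg)
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            pa, pb = gm.snps.at[a, "pos"], gm.snps.at[b, "pos"]
            if abs(pa - pb) <= acfg.ld_window_bp:
                assert cq.ld_r2(gm.dosage_vector(a), gm.dosage_vector(b)) <= acfg.ld_r2_max


# -------------------------------------------------------------- classify_qtls

def test_classify_qtls_thresholds():
    mk = lambda rows: pd.DataFrame(rows, columns=["snp_id", "trait_id", "p"]).assign(
        n=68, beta=0.1, se=0.1, t=1.0, r2=0.1, degenerate=False
    )
    pheno = mk([("s1", "log2_ic50", 0.0009), ("s2", "log2_ic50", 0.002)])
    expr = mk([("s1", "geneA", 5e-5), ("s2", "geneB", 2e-4)])
    qtls = cq.classify_qtls(pheno, expr, None, snp_universe=["s1", "s2"])
    assert bool(qtls.at["s1", "is_dqtl"]) is True  # p = 0.0009 <= 0.001
    assert bool(qtls.at["s2", "is_dqtl"]) is False
    assert bool(qtls.at["s1", "is_eqtl"]) is True  # 5e-5 <= 1e-4
    assert bool(qtls.at["s2", "is_eqtl"]) is False  # 2e-4 > 1e-4
    assert not qtls["is_pqtl"].any()
    assert qtls.at["s1", "eqtl_trait"] == "geneA"


# --------------------------------------------------------------------- BH FDR

def bh_definition_oracle(p, q):
    """Literal step-up definition: scan all k for the largest passing index."""
    p = np.asarray(p, dtype=float)
    m = p.size
    sp = np.sort(p)
    k_star = 0
    for k in range(1, m + 1):
        if sp[k - 1] <= k * q / m:
            k_star = k
    if k_star == 0:
        return np.zeros(m, dtype=bool)
    return p <= sp[k_star - 1]


def test_bh_fdr_examples():
    mask, thr = cq.bh_fdr([0.01, 0.02, 0.03, 0.5], 0.05)
    assert mask.tolist() == [True, True, True, False]  # 0.03 <= 3 * 0.05 / 4
    mask, _ = cq.bh_fdr([0.9, 0.9, 0.9], 0.05)
    assert not mask.any()
    mask, _ = cq.bh_fdr([], 0.05)
    assert mask.size == 0


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
def test_bh_fdr_matches_definition_oracle(pvals):
    mask, _ = cq.bh_fdr(pvals, 0.05)
    assert mask.tolist() == bh_definition_oracle(pvals, 0.05).tolist()


def test_bh_fdr_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(12)
    p = rng.uniform(size=200) ** 2
    mask, _ = cq.bh_fdr(p, 0.05)
    ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
    assert (mask == ref).all()


# ------------------------------------------------------------------ QQ points

def test_qq_points_on_uniform_grid_is_diagonal():
    m = 99
    p = np.arange(1, m + 1) / (m + 1)
    qq = cq.qq_points(p)
    assert np.allclose(qq["expected_neglog10"], qq["observed_neglog10"], atol=1e-12)


def test_qq_points_single_value():
    qq = cq.qq_points([0.5])
    assert qq["expected_neglog10"].iloc[0] == pytest.approx(-math.log10(0.5))


def test_qq_points_zero_clipped_with_warning():
    with pytest.warns(UserWarning):
        qq = cq.qq_points([0.0, 0.5])
    assert np.isfinite(qq["observed_neglog10"]).all()
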