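"""Tests of the synthetic-cohort generators and their ground-truth record."""

import math

import numpy as np
import pytest

import cytoqtl as cq


# ------------------------------------------------------------------ genotypes

def test_genotype_mean_dosage_at_maf_half():
    cfg = cq.SimulationConfig(n_samples=10_000, n_snps=1, maf_spec=0.5, seed=2)
    gm = cq.simulate_genotypes(cfg)
    assert 0.97 <= gm.dosages.mean() <= 1.03  # binomial(2, 0.5)


def test_genotype_determinism():
    cfg = cq.SimulationConfig(n_samples=68, n_snps=30, seed=5,
                              ld_blocks=[(10, 0.8)])
    a = cq.simulate_genotypes(cfg)
    b = cq.simulate_genotypes(cfg)
    assert np.array_equal(a.dosages, b.dosages)
    assert a.snp_ids == b.snp_ids


def test_genotypes_conform_to_hwe():
    """>= 99% of generated SNPs pass the exact HWE test at p >= 0.001."""
    cfg = cq.SimulationConfig(n_samples=1000, n_snps=1000, maf_spec=0.3, seed=3)
    gm = cq.simulate_genotypes(cfg)
    assert (gm.snps["hwe_p"] >= 0.001).mean() >= 0.99


def test_ld_blocks_are_correlated_and_separated():
    cfg = cq.SimulationConfig(
        n_samples=2000, n_snps=20, maf_spec=0.3, ld_blocks=[(10, 0.9)], seed=4
    )
    gm = cq.simulate_genotypes(cfg)
    within = np.corrcoef(gm.dosages[:, :10], rowvar=False)
    off = within[np.triu_indices(10, 1)]
    assert off.min() > 0.5  # latent rho 0.9 keeps dosage correlation high
    cross = np.corrcoef(gm.dosages[:, 0], gm.dosages[:, 15])[0, 1]
    assert abs(cross) < 0.1


def test_invalid_configs_raise():
    with pytest.raises(ValueError):
        cq.SimulationConfig(n_samples=2)
    with pytest.raises(ValueError):
        cq.SimulationConfig(hill_slope=0.0)
    with pytest.raises(ValueError):
        cq.SimulationConfig(maf_spec=0.01)
    with pytest.raises(ValueError):
        cq.SimulationConfig(concentrations=[100.0, 50.0])


# ----------------------------------------------------------------- expression

def test_null_expression_mean_r2():
    """Under the null, E[in-sample R^2] = 1/(n-1); 10,000 pooled pairs."""
    cfg = cq.SimulationConfig(n_samples=68, n_snps=100, n_genes=100, seed=6)
    gm = cq.simulate_genotypes(cfg)
    expr, _ = cq.simulate_expression(gm, cfg)
    res = cq.association_scan(gm, expr)
    assert 0.012 <= res["r2"].mean() <= 0.018  # 1/67 = 0.0149


def test_planted_gene_effect_recovered_on_average():
    """Mean realized in-sample R^2 hovers at the planted 0.36."""
    r2s = []
    for rep in range(300):
        cfg = cq.SimulationConfig(
            n_samples=68, n_snps=1, maf_spec=0.3, n_genes=1, seed=3000 + rep,
            planted_effects=[cq.PlantedEffect("chr1:10000", "gene", "gene0000", 0.36, 1)],
        )
        gm = cq.simulate_genotypes(cfg)
        expr, _ = cq.simulate_expression(gm, cfg)
        r2s.append(cq.regress_trait(gm.dosages[:, 0], expr["gene0000"].to_numpy()).r2)
    assert 0.33 <= float(np.mean(r2s)) <= 0.43


def test_undetected_gene_missingness():
    cfg = cq.SimulationConfig(
        n_samples=68, n_snps=5, n_genes=3, undetected_genes=["gene0002"], seed=7
    )
    gm = cq.simulate_genotypes(cfg)
    expr, _ = cq.simulate_expression(gm, cfg)
    assert expr["gene0002"].isna().sum() == 68 - 3
    assert expr["gene0000"].notna().all()


def test_unknown_planted_snp_raises():
    cfg = cq.SimulationConfig(n_samples=10, n_snps=2, n_genes=1, seed=8)
    bad = cq.SimulationConfig(
        n_samples=10, n_snps=2, n_genes=1, seed=8,
        planted_effects=[cq.PlantedEffect("chr9:1", "gene", "gene0000", 0.2, 1)],
    )
    gm = cq.simulate_genotypes(cfg)
    with pytest.raises(KeyError):
        cq.simulate_expression(gm, bad)


# ------------------------------------------------------------------- proteins

def test_mediated_zero_noise_residuals_vanish():
    """Full mediation with no protein noise: residuals on mRNA are null."""
    cfg = cq.SimulationConfig(
        n_samples=68, n_snps=1, maf_spec=0.3, n_genes=1, n_proteins=1, seed=9,
        planted_effects=[
            cq.PlantedEffect("chr1:10000", "gene", "gene0000", 0.4, 1),
            cq.PlantedEffect("chr1:10000", "protein", "gene0000|iso1", 0.4, 1, "mediated"),
        ],
    )
    gm = cq.simulate_genotypes(cfg)
    expr, _ = cq.simulate_expression(gm, cfg)
    prot, _ = cq.simulate_proteins(gm, expr, cfg)
    rt = cq.residualize_protein_on_mrna(prot["gene0000|iso1"], expr["gene0000"])
    assert rt.adjustment_status == "adjusted"
    assert np.abs(rt.residuals.to_numpy()).max() < 1e-10
    r = cq.regress_trait(gm.dosages[:, 0], rt.residuals.to_numpy())
    assert r.r2 == pytest.approx(0.0, abs=1e-9)


def test_direct_effect_bypasses_mrna():
    cfg = cq.SimulationConfig(
        n_samples=2000, n_snps=1, maf_spec=0.3, n_genes=1, n_proteins=1, seed=10,
        planted_effects=[
            cq.PlantedEffect("chr1:10000", "protein", "gene0000|iso1", 0.21, 1, "direct")
        ],
    )
    gm = cq.simulate_genotypes(cfg)
    expr, _ = cq.simulate_expression(gm, cfg)
    prot, _ = cq.simulate_proteins(gm, expr, cfg)
    r_prot = cq.regress_trait(gm.dosages[:, 0], prot["gene0000|iso1"].to_numpy())
    r_mrna = cq.regress_trait(gm.dosages[:, 0], expr["gene0000"].to_numpy())
    assert 0.15 <= r_prot.r2 <= 0.27  # around the planted 0.21 at n = 2000
    assert r_mrna.r2 < 0.01  # mRNA stays at null level


def test_isoform_pair_opposite_signs():
    cfg = cq.SimulationConfig(
        n_samples=68, n_snps=1, maf_spec=0.3, n_genes=1, n_proteins=2, seed=11,
        isoform_pairs=[("gene0000|iso1", "gene0000|iso2")],
        planted_effects=[
            cq.PlantedEffect("chr1:10000", "protein", "gene0000|iso1", 0.3, 1, "direct")
        ],
    )
    gm = cq.simulate_genotypes(cfg)
    expr, _ = cq.simulate_expression(gm, cfg)
    prot, truth = cq.simulate_proteins(gm, expr, cfg)
    a = truth.coefficients[("chr1:10000", "gene0000|iso1")]
    b = truth.coefficients[("chr1:10000", "gene0000|iso2")]
    assert math.copysign(1, a) == -math.copysign(1, b)


def test_isoform_pair_same_sign_config_rejected():
    with pytest.raises(ValueError, match="opposite-sign"):
        cq.SimulationConfig(
            n_samples=68, n_snps=1, maf_spec=0.3, n_genes=1, n_proteins=2,
            isoform_pairs=[("gene0000|iso1", "gene0000|iso2")],
            planted_effects=[
                cq.PlantedEffect("chr1:10000", "protein", "gene0000|iso1", 0.3, 1, "direct"),
                cq.PlantedEffect("chr1:10000", "protein", "gene0000|iso2", 0.3, 1, "direct"),
            ],
        )


def test_mediated_effect_on_undetected_gene_rejected():
    with pytest.raises(ValueError, match="undetected"):
        cq.SimulationConfig(
            n_samples=68, n_snps=1, maf_spec=0.3, n_genes=1, n_proteins=1,
            undetected_genes=["gene0000"],
            planted_effects=[
                cq.PlantedEffect("chr1:10000", "gene", "gene0000", 0.4, 1),
                cq.PlantedEffect("chr1:10000", "protein", "gene0000|iso1", 0.3, 1, "mediated"),
            ],
        )


# -------------------------------------------------------------- dose-response

def test_survival_is_half_at_true_ic50():
    assert cq.four_pl_survival(176.5, 176.5, 1.5) == pytest.approx(50.0)


def test_dose_response_default_location():
    """With no effects and no phenotype spread, every true IC50 is 176.5 uM."""
    cfg = cq.SimulationConfig(
        n_samples=10, n_snps=2, log2_ic50_sd=0.0, survival_noise_sd=0.0, seed=12
    )
    gm = cq.simulate_genotypes(cfg)
    dose, truth = cq.simulate_dose_response(gm, cfg)
    assert np.allclose(truth.true_curve_params["ic50_uM"], 176.5)
    mid = dose[dose["concentration_uM"] == 175.0]["pct_survival"]
    assert np.allclose(mid, cq.four_pl_survival(175.0, 176.5, 1.5))


def test_dose_response_determinism():
    cfg = cq.SimulationConfig(n_samples=20, n_snps=3, seed=13)
    gm = cq.simulate_genotypes(cfg)
    d1, _ = cq.simulate_dose_response(gm, cfg)
    d2, _ = cq.simulate_dose_response(gm, cfg)
    assert d1.equals(d2)


def test_survival_noise_truncated_at_zero():
    cfg = cq.SimulationConfig(n_samples=50, n_snps=2, survival_noise_sd=40.0, seed=14)
    gm = cq.simulate_genotypes(cfg)
    dose, _ = cq.simulate_dose_response(gm, cfg)
    assert (dose["pct_survival"] >= 0).all()
    assert (dose["pct_survival"] > 100).any()  # upper side is not clipped


# --------------------------------------------------------- variance bookkeeping

def test_variance_bookkeeping_is_exact(small_cohort):
    """Var(genetic)/Var(trait) from recorded population quantities equals
    the planted variance_explained to 1e-12, for every effect kind."""
    cohort, cfg = small_cohort
    truth = cohort["truth"]
    checks = {
        ("chr1:10000", "log2_ic50"): 0.36,
        ("chr1:15000", "gene0001"): 0.4,
        ("chr1:15000", "gene0001|iso1"): 0.25,
        ("chr1:20000", "gene0002|iso1"): 0.3,
    }
    for (snp, trait), v in checks.items():
        assert truth.genetic_variance_ratio(snp, trait) == pytest.approx(v, abs=1e-12)
    assert truth.planted_r2("chr1:10000", "gene0005") == 0.0


def test_cohort_determinism(small_cohort):
    cohort, cfg = small_cohort
    again = cq.simulate_cohort(cfg)
    assert np.array_equal(cohort["genotypes"].dosages, again["genotypes"].dosages)
    assert cohort["expression"].equals(again["expression"])
    assert cohort["proteins"].equals(again["proteins"])
    assert cohort["dose_response"].equals(again["dose_response"])
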