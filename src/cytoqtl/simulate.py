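"""Synthetic cohorts with the statistical structure the analysis assumes.

The generators emulate a pharmacogenomic cell-line panel: biallelic SNP
genotypes in Hardy-Weinberg equilibrium with configurable minor allele
frequencies and optional LD blocks; gene/protein expression matrices with
planted genotype effects (mediated through mRNA, or direct and therefore
mRNA-independent); and four-parameter-logistic survival curves with a
planted genotype effect on log2 IC50. Every generator is a pure function
of ``(config, seed)`` and records its generating quantities in a
:class:`GroundTruth` so that recovery tests can compare estimate against
truth.

Effect sizes are scaled against the *population* dosage variance
``2 f (1 - f)``: a planted ``variance_explained`` of v makes the genetic
part of the trait explain exactly v of the generating population variance,
while the realized in-sample R^2 fluctuates around v as it does in real
cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import PlantedEffect, SimulationConfig
from .containers import GenotypeMatrix, parse_protein_id

__all__ = [
    "GroundTruth",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_proteins",
    "simulate_dose_response",
    "simulate_cohort",
]


@dataclass
class GroundTruth:
    """Record of the generating model behind one simulated data set.

    ``coefficients`` maps ``(snp_id, trait_id)`` to the generating slope in
    trait units per minor-allele copy; ``variance_explained`` maps the same
    keys to the planted population variance fraction (zero for everything
    not planted); ``noise_sd`` and ``trait_var`` are per-trait generating
    quantities. Phenotype entries use trait id ``"log2_ic50"``.
    """

    coefficients: dict = field(default_factory=dict)
    variance_explained: dict = field(default_factory=dict)
    noise_sd: dict = field(default_factory=dict)
    trait_var: dict = field(default_factory=dict)
    snp_maf: dict = field(default_factory=dict)
    true_log2_ic50: pd.Series | None = None
    true_curve_params: pd.DataFrame | None = None

    def planted_r2(self, snp_id: str, trait_id: str) -> float:
        return self.variance_explained.get((snp_id, trait_id), 0.0)

    def genetic_variance_ratio(self, snp_id: str, trait_id: str) -> float:
        """Var(genetic part)/Var(trait) from the recorded population
        quantities; equals the planted variance_explained exactly."""
        beta = self.coefficients.get((snp_id, trait_id), 0.0)
        f = self.snp_maf[snp_id]
        return beta**2 * 2 * f * (1 - f) / self.trait_var[trait_id]


def _snp_ids(config: SimulationConfig) -> tuple[list[str], list[str], list[int]]:
    """Deterministic SNP naming: chr1, positions spaced 5 kb apart."""
    ids, chroms, poss = [], [], []
    for j in range(config.n_snps):
        pos = 10_000 + 5_000 * j
        ids.append(f"chr1:{pos}")
        chroms.append("1")
        poss.append(pos)
    return ids, chroms, poss


def _draw_mafs(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    spec = config.maf_spec
    if isinstance(spec, (int, float)):
        return np.full(config.n_snps, float(spec))
    if isinstance(spec, tuple) and len(spec) == 3 and spec[0] == "uniform":
        return rng.uniform(float(spec[1]), float(spec[2]), size=config.n_snps)
    return np.asarray([float(x) for x in spec])


def simulate_genotypes(config: SimulationConfig, seed: int | None = None) -> GenotypeMatrix:
    """Draw hard-call genotypes in Hardy-Weinberg equilibrium.

    Independent SNPs are two Bernoulli(MAF) allele draws per sample.
    SNPs inside an LD block share a latent Gaussian factor (a Gaussian
    copula with within-block correlation ``rho``) whose uniforms are
    thresholded at the HWE genotype-class boundaries, so marginal HWE is
    preserved while dosages within a block are correlated.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n, m = config.n_samples, config.n_snps
    mafs = _draw_mafs(config, rng)
    dosages = np.empty((n, m), dtype=float)

    j = 0
    for size, rho in config.ld_blocks:
        common = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, size))
        z = math.sqrt(rho) * common + math.sqrt(1.0 - rho) * own
        u = norm.cdf(z)
        f = mafs[j : j + size]
        lo = (1.0 - f) ** 2          # P(dosage 0)
        hi = lo + 2.0 * f * (1.0 - f)  # P(dosage <= 1)
        dosages[:, j : j + size] = (u >= lo).astype(float) + (u >= hi)
        j += size
    if j < m:
        dosages[:, j:] = rng.binomial(2, mafs[j:], size=(n, m - j)).astype(float)

    ids, chroms, poss = _snp_ids(config)
    samples = [f"sample{i:03d}" for i in range(n)]
    gm = GenotypeMatrix.from_dosages(samples, ids, dosages, chrom=chroms, pos=poss)
    # keep the generating (population) MAF alongside the realized one
    gm.snps["target_maf"] = mafs
    return gm


def _effect_beta(v: float, f: float, trait_var: float, sign: int) -> float:
    """Slope giving genetic variance v * trait_var at population dosage
    variance 2 f (1 - f)."""
    return sign * math.sqrt(v * trait_var / (2.0 * f * (1.0 - f)))


def _target_maf(genotypes: GenotypeMatrix, snp_id: str) -> float:
    if snp_id not in genotypes.snps.index:
        raise KeyError(f"planted effect references unknown SNP {snp_id!r}")
    if "target_maf" in genotypes.snps.columns:
        return float(genotypes.snps.at[snp_id, "target_maf"])
    return float(genotypes.snps.at[snp_id, "maf"])


def simulate_expression(
    genotypes: GenotypeMatrix, config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Gene expression with planted cis/trans genotype effects.

    Each gene has unit generating variance: planted genes are
    ``beta * dosage + N(0, 1 - sum(v))``, unplanted genes pure N(0, 1)
    noise. Genes in ``config.undetected_genes`` are emitted as missing
    (NaN) in all but ``n_detected_for_undetected`` samples, mirroring a
    transcript detected above background in only a handful of lines.
    """
    seed = (config.seed + 1) if seed is None else seed
    rng = np.random.default_rng(seed)
    genes = config.gene_ids()
    n = genotypes.n_samples
    truth = GroundTruth(snp_maf={s: _target_maf(genotypes, s) for s in genotypes.snp_ids})

    effects: dict[str, list[PlantedEffect]] = {}
    for e in config.effects_of("gene"):
        if e.trait_id not in genes:
            raise KeyError(f"planted effect references unknown gene {e.trait_id!r}")
        _target_maf(genotypes, e.snp_id)  # raises on unknown SNP
        effects.setdefault(e.trait_id, []).append(e)

    X = np.empty((n, len(genes)))
    for k, g in enumerate(genes):
        planted = effects.get(g, [])
        v_total = sum(e.variance_explained for e in planted)
        noise_sd = math.sqrt(1.0 - v_total)
        col = rng.normal(0.0, noise_sd, size=n)
        for e in planted:
            f = _target_maf(genotypes, e.snp_id)
            beta = _effect_beta(e.variance_explained, f, 1.0, e.sign)
            col = col + beta * genotypes.dosage_vector(e.snp_id)
            truth.coefficients[(e.snp_id, g)] = beta
            truth.variance_explained[(e.snp_id, g)] = e.variance_explained
        truth.noise_sd[g] = noise_sd
        truth.trait_var[g] = 1.0
        X[:, k] = col

    expr = pd.DataFrame(X, index=pd.Index(genotypes.samples, name="sample"), columns=genes)
    for g in config.undetected_genes:
        if g not in genes:
            raise KeyError(f"undetected gene {g!r} not among simulated genes")
        detected = rng.choice(n, size=min(config.n_detected_for_undetected, n), replace=False)
        mask = np.ones(n, dtype=bool)
        mask[detected] = False
        expr.loc[mask, g] = np.nan
    return expr, truth


def simulate_proteins(
    genotypes: GenotypeMatrix,
    expression: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Protein expression with mediated and direct genotype effects.

    A *mediated* effect makes the protein a scaled copy of its encoding
    gene's mRNA plus noise, so any genotype association exists only
    through the transcript and vanishes after residualisation. A *direct*
    effect regresses the protein on the dosage itself and carries no mRNA
    dependence. Isoform pairs are constrained to opposite-sign genotype
    coefficients: when only one member of a pair carries a planted effect,
    the mirrored effect is planted on the other member automatically.
    """
    seed = (config.seed + 2) if seed is None else seed
    rng = np.random.default_rng(seed)
    proteins = config.protein_ids()
    n = genotypes.n_samples
    truth = GroundTruth(snp_maf={s: _target_maf(genotypes, s) for s in genotypes.snp_ids})

    effects: dict[str, list[PlantedEffect]] = {}
    for e in config.effects_of("protein"):
        if e.trait_id not in proteins:
            raise KeyError(f"planted effect references unknown protein {e.trait_id!r}")
        effects.setdefault(e.trait_id, []).append(e)
    # mirror single-sided isoform-pair effects with the opposite sign
    for a, b in config.isoform_pairs:
        for src, dst in ((a, b), (b, a)):
            if src in effects and dst not in effects:
                effects[dst] = [
                    PlantedEffect(e.snp_id, "protein", dst, e.variance_explained,
                                  -e.sign, e.mode)
                    for e in effects[src]
                ]

    # gene-level planted variance and sign, needed to scale mediated effects
    gene_v: dict[tuple[str, str], tuple[float, int]] = {}
    for e in config.effects_of("gene"):
        gene_v[(e.snp_id, e.trait_id)] = (e.variance_explained, e.sign)

    X = np.empty((n, len(proteins)))
    for k, pid in enumerate(proteins):
        gene, _ = parse_protein_id(pid)
        planted = effects.get(pid, [])
        v_total = sum(e.variance_explained for e in planted)
        if v_total >= 1.0:
            raise ValueError(f"total variance_explained for {pid!r} must be < 1")
        col = np.zeros(n)
        explained = 0.0
        for e in planted:
            f = _target_maf(genotypes, e.snp_id)
            if e.mode == "mediated":
                if gene is None:
                    raise ValueError(f"mediated effect on {pid!r}: no encoding gene")
                if gene in config.undetected_genes:
                    raise ValueError(
                        f"mediated effect on {pid!r}: encoding gene {gene!r} is undetected"
                    )
                vg, gene_sign = gene_v.get((e.snp_id, gene), (0.0, 1))
                if vg <= 0.0:
                    raise ValueError(
                        f"mediated effect on {pid!r} needs a planted effect of "
                        f"{e.snp_id} on {gene}"
                    )
                if e.variance_explained > vg:
                    raise ValueError(
                        "mediated variance_explained cannot exceed the gene's"
                    )
                # sign of the protein-on-dosage effect is e.sign; the loading
                # on mRNA absorbs the gene effect's own sign
                a = e.sign * gene_sign * math.sqrt(e.variance_explained / vg)
                col = col + a * expression[gene].to_numpy()
                explained += a**2  # mRNA has unit generating variance
                beta_gene = gene_sign * truth_gene_beta(e.snp_id, gene, f, vg)
                truth.coefficients[(e.snp_id, pid)] = a * beta_gene
            else:  # direct
                beta = _effect_beta(e.variance_explained, f, 1.0, e.sign)
                col = col + beta * genotypes.dosage_vector(e.snp_id)
                explained += e.variance_explained
                truth.coefficients[(e.snp_id, pid)] = beta
            truth.variance_explained[(e.snp_id, pid)] = e.variance_explained
        noise_sd = math.sqrt(max(1.0 - explained, 0.0))
        col = col + rng.normal(0.0, noise_sd, size=n)
        truth.noise_sd[pid] = noise_sd
        truth.trait_var[pid] = 1.0
        X[:, k] = col

    prot = pd.DataFrame(X, index=pd.Index(genotypes.samples, name="sample"), columns=proteins)
    return prot, truth


def truth_gene_beta(snp_id: str, gene: str, f: float, v: float) -> float:
    """Generating slope of a gene with planted variance v at MAF f."""
    return math.sqrt(v / (2.0 * f * (1.0 - f)))


def four_pl_survival(conc, ic50: float, hill: float, bottom: float = 0.0, top: float = 100.0):
    """Four-parameter logistic survival (% of no-drug control)."""
    c = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def simulate_dose_response(
    genotypes: GenotypeMatrix, config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-sample survival curves with a planted genotype effect on log2 IC50.

    True log2 IC50 is ``mean_log2_ic50 + sum(beta * dosage) + noise`` with
    each slope scaled so the SNP explains its planted fraction of the
    phenotype variance (``log2_ic50_sd**2``). Survival at concentration c
    is ``100 / (1 + (c / IC50)^hill)`` plus Gaussian measurement noise,
    truncated at 0 but allowed above 100% as real no-drug-normalised
    readouts are.

    Returns a tidy DataFrame (sample, concentration_uM, pct_survival) and
    the ground truth with per-sample true log2 IC50 and curve parameters.
    """
    seed = (config.seed + 3) if seed is None else seed
    rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    truth = GroundTruth(snp_maf={s: _target_maf(genotypes, s) for s in genotypes.snp_ids})

    var_pheno = config.log2_ic50_sd**2
    planted = config.effects_of("phenotype")
    v_total = sum(e.variance_explained for e in planted)
    noise_sd = math.sqrt((1.0 - v_total) * var_pheno)
    log2_ic50 = config.mean_log2_ic50 + rng.normal(0.0, noise_sd, size=n)
    for e in planted:
        f = _target_maf(genotypes, e.snp_id)
        beta = _effect_beta(e.variance_explained, f, var_pheno, e.sign)
        log2_ic50 = log2_ic50 + beta * genotypes.dosage_vector(e.snp_id)
        truth.coefficients[(e.snp_id, "log2_ic50")] = beta
        truth.variance_explained[(e.snp_id, "log2_ic50")] = e.variance_explained
    truth.noise_sd["log2_ic50"] = noise_sd
    truth.trait_var["log2_ic50"] = var_pheno
    truth.true_log2_ic50 = pd.Series(log2_ic50, index=genotypes.samples, name="log2_ic50")

    ic50 = np.exp2(log2_ic50)
    conc = np.asarray(config.concentrations, dtype=float)
    rows = []
    for i, sample in enumerate(genotypes.samples):
        surv = four_pl_survival(conc, ic50[i], config.hill_slope)
        if config.survival_noise_sd > 0:
            surv = surv + rng.normal(0.0, config.survival_noise_sd, size=conc.size)
        surv = np.maximum(surv, 0.0)
        for c, s in zip(conc, surv):
            rows.append((sample, c, s))
    dose = pd.DataFrame(rows, columns=["sample", "concentration_uM", "pct_survival"])
    truth.true_curve_params = pd.DataFrame(
        {
            "ic50_uM": ic50,
            "log2_ic50": log2_ic50,
            "hill": config.hill_slope,
            "bottom": 0.0,
            "top": 100.0,
        },
        index=pd.Index(genotypes.samples, name="sample"),
    )
    return dose, truth


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> dict:
    """Generate a complete cohort: genotypes, expression, proteins, curves.

    Per-stage seeds are derived from the root seed in a fixed order so
    that adding a stage never perturbs earlier stages' randomness.
    """
    root = config.seed if seed is None else seed
    ss = np.random.SeedSequence(root).spawn(4)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    genotypes = simulate_genotypes(config, seed=sub[0])
    expression, truth_e = simulate_expression(genotypes, config, seed=sub[1])
    proteins, truth_p = simulate_proteins(genotypes, expression, config, seed=sub[2])
    dose, truth_d = simulate_dose_response(genotypes, config, seed=sub[3])
    truth = GroundTruth(snp_maf=truth_e.snp_maf)
    for t in (truth_e, truth_p, truth_d):
        truth.coefficients.update(t.coefficients)
        truth.variance_explained.update(t.variance_explained)
        truth.noise_sd.update(t.noise_sd)
        truth.trait_var.update(t.trait_var)
    truth.true_log2_ic50 = truth_d.true_log2_ic50
    truth.true_curve_params = truth_d.true_curve_params
    return {
        "genotypes": genotypes,
        "expression": expression,
        "proteins": proteins,
        "dose_response": dose,
        "truth": truth,
    }
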