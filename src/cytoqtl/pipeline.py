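"""End-to-end orchestration: simulate/load -> phenotype -> scans -> enrichment.

A single structured configuration (YAML or dict) drives the whole flow::

    seed: 42
    simulate:            # either this block ...
      n_samples: 68
      n_snps: 500
      planted_effects:
        - {snp_id: "chr1:10000", trait_kind: phenotype, variance_explained: 0.36}
    inputs:              # ... or explicit input files
      genotypes_vcf: cohort.vcf
      dose_response: curves.tsv
      expression: expression.tsv
      proteins: proteins.tsv
    analysis:
      dqtl_p: 0.001

All randomness flows from one root seed through a fixed derivation order,
so rerunning the same configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .association import (
    association_scan,
    bh_fdr,
    classify_qtls,
    ld_prune,
    qq_points,
    regress_trait,
    snp_filter,
)
from .config import AnalysisConfig, PlantedEffect, SimulationConfig
from .containers import GenotypeMatrix, protein_gene_map
from .enrichment import enrichment_test, mrna_independent_pqtl_scan
from .io import (
    RunManifest,
    file_digest,
    read_dosage_tsv,
    read_dose_response_tsv,
    read_genotypes_vcf,
    read_matrix_tsv,
    write_dosage_tsv,
    write_dose_response_tsv,
    write_genotypes_vcf,
    write_matrix_tsv,
)
from .phenotype import fit_ic50_table, log2_phenotypes
from .simulate import simulate_cohort

__all__ = ["PipelineError", "load_config", "build_simulation_config", "run_pipeline"]

log = logging.getLogger("cytoqtl")

# fixed seed-derivation order; appending new stages never perturbs earlier ones
_STAGE_SEED_NAMES = (
    "simulate",
    "enrich_eqtl",
    "enrich_pqtl",
    "enrich_mrna_independent",
    "reserved_0",
    "reserved_1",
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def build_simulation_config(block: dict) -> SimulationConfig:
    """Turn the YAML ``simulate`` block into a SimulationConfig."""
    block = dict(block)
    effects = [
        PlantedEffect(
            snp_id=e["snp_id"],
            trait_kind=e["trait_kind"],
            trait_id=e.get("trait_id"),
            variance_explained=float(e["variance_explained"]),
            sign=int(e.get("sign", 1)),
            mode=e.get("mode"),
        )
        for e in block.pop("planted_effects", [])
    ]
    if "maf_spec" in block and isinstance(block["maf_spec"], list):
        spec = block["maf_spec"]
        if len(spec) == 3 and spec[0] == "uniform":
            block["maf_spec"] = ("uniform", float(spec[1]), float(spec[2]))
    if "ld_blocks" in block:
        block["ld_blocks"] = [tuple(b) for b in block["ld_blocks"]]
    if "isoform_pairs" in block:
        block["isoform_pairs"] = [tuple(p) for p in block["isoform_pairs"]]
    return SimulationConfig(planted_effects=effects, **block)


def _derive_seeds(root_seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(root_seed).spawn(len(_STAGE_SEED_NAMES))
    return {
        name: int(c.generate_state(1)[0] % (2**31))
        for name, c in zip(_STAGE_SEED_NAMES, children)
    }


def _load_inputs(inputs: dict, out: Path, manifest: RunManifest):
    for key, path in inputs.items():
        if not Path(path).exists():
            raise PipelineError("inputs", f"missing input file {path!r} ({key})")
        manifest.input_digests[key] = file_digest(path)
    if "genotypes_vcf" in inputs:
        genotypes = read_genotypes_vcf(inputs["genotypes_vcf"])
    elif "genotypes_tsv" in inputs:
        genotypes = read_dosage_tsv(inputs["genotypes_tsv"])
    else:
        raise PipelineError("inputs", "no genotype input (genotypes_vcf or genotypes_tsv)")
    if "dose_response" not in inputs:
        raise PipelineError("inputs", "no dose_response input")
    dose = read_dose_response_tsv(inputs["dose_response"])
    expression = (
        read_matrix_tsv(inputs["expression"], "expression")
        if "expression" in inputs
        else None
    )
    proteins = (
        read_matrix_tsv(inputs["proteins"], "protein") if "proteins" in inputs else None
    )
    return genotypes, dose, expression, proteins


def run_pipeline(config, out_dir, seed: int | None = None) -> RunManifest:
    """Execute the full analysis and write every stage's outputs.

    ``config`` is a dict or a YAML path (see module docstring). ``seed``
    overrides the configuration's root seed. Returns the run manifest
    (also written to ``<out_dir>/manifest.json``).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_seed = int(seed if seed is not None else config.get("seed", 0))
    seeds = _derive_seeds(root_seed)
    manifest = RunManifest(config=config, seeds={"root": root_seed, **seeds})
    acfg = AnalysisConfig(**config.get("analysis", {}))
    stage = "inputs"
    try:
        # -- inputs / simulation ------------------------------------------
        if "simulate" in config:
            stage = "simulate"
            sim_cfg = build_simulation_config(config["simulate"])
            cohort = simulate_cohort(sim_cfg, seed=seeds["simulate"])
            genotypes: GenotypeMatrix = cohort["genotypes"]
            dose = cohort["dose_response"]
            expression = cohort["expression"] if cohort["expression"].shape[1] else None
            proteins = cohort["proteins"] if cohort["proteins"].shape[1] else None
            truth = cohort["truth"]
            write_genotypes_vcf(genotypes, out / "genotypes.vcf")
            write_dosage_tsv(genotypes, out / "dosages.tsv")
            write_matrix_tsv(cohort["expression"], out / "expression.tsv")
            write_matrix_tsv(cohort["proteins"], out / "proteins.tsv")
            write_dose_response_tsv(dose, out / "dose_response.tsv")
            truth_rows = [
                {"snp_id": s, "trait_id": t,
                 "beta": truth.coefficients.get((s, t), 0.0),
                 "variance_explained": v}
                for (s, t), v in sorted(truth.variance_explained.items())
            ]
            pd.DataFrame(
                truth_rows, columns=["snp_id", "trait_id", "beta", "variance_explained"]
            ).to_csv(out / "ground_truth.tsv", sep="\t", index=False)
            manifest.add_stage("simulate", n_samples=genotypes.n_samples,
                               n_snps=genotypes.n_snps,
                               n_genes=cohort["expression"].shape[1],
                               n_proteins=cohort["proteins"].shape[1])
        else:
            cohort_inputs = config.get("inputs", {})
            genotypes, dose, expression, proteins = _load_inputs(
                cohort_inputs, out, manifest
            )
            manifest.add_stage("inputs", n_samples=genotypes.n_samples,
                               n_snps=genotypes.n_snps)

        # -- phenotype ----------------------------------------------------
        stage = "phenotype"
        phenotypes = fit_ic50_table(dose, method=config.get("ic50_method", "auto"))
        phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
        pheno_vec, normality = log2_phenotypes(phenotypes)
        manifest.add_stage("phenotype", n_samples=len(phenotypes),
                           n_uncensored=normality["n"],
                           ks_p=round(normality["ks_p"], 6),
                           normal=normality["normal"])

        # -- SNP filter ---------------------------------------------------
        stage = "filter"
        genotypes_f, filter_log = snp_filter(genotypes, acfg)
        if genotypes_f.n_snps == 0:
            log.warning("SNP filter removed every SNP; downstream scans are empty")
        manifest.add_stage("filter", **filter_log)

        # -- dQTL scan + LD pruning --------------------------------------
        stage = "dqtl_scan"
        trait = pheno_vec.reindex(genotypes_f.samples)
        dqtl_scan = association_scan(genotypes_f, trait.rename("log2_ic50"))
        dqtl_scan.to_csv(out / "dqtl_scan.tsv", sep="\t", index=False)
        candidates = dqtl_scan[dqtl_scan["p"] <= acfg.dqtl_p]
        stage = "ld_prune"
        pruned = ld_prune(candidates[["snp_id", "p"]], genotypes_f, acfg)
        pd.DataFrame({"snp_id": pruned}).to_csv(
            out / "dqtl_pruned.tsv", sep="\t", index=False
        )
        manifest.add_stage("dqtl_scan", n_candidates=int(len(candidates)),
                           n_pruned=len(pruned))
        manhattan = dqtl_scan.merge(
            genotypes_f.snps[["chrom", "pos"]], left_on="snp_id", right_index=True
        )[["chrom", "pos", "p"]]
        manhattan.to_csv(out / "dqtl_manhattan.tsv", sep="\t", index=False)

        # -- eQTL / pQTL scans -------------------------------------------
        stage = "qtl_scans"
        eqtl_best = pqtl_best = None
        if expression is not None:
            eqtl_best = association_scan(genotypes_f, expression, keep="best")
            eqtl_best.to_csv(out / "eqtl_best.tsv", sep="\t", index=False)
        if proteins is not None:
            pqtl_best = association_scan(genotypes_f, proteins, keep="best")
            pqtl_best.to_csv(out / "pqtl_best.tsv", sep="\t", index=False)
        else:
            log.info("no protein matrix: pQTL stages skipped")
        qtls = classify_qtls(dqtl_scan, eqtl_best, pqtl_best, acfg,
                             snp_universe=genotypes_f.snp_ids)
        manifest.add_stage(
            "classify",
            n_dqtl=int(qtls["is_dqtl"].sum()),
            n_eqtl=int(qtls["is_eqtl"].sum()),
            n_pqtl=int(qtls["is_pqtl"].sum()),
        )

        # -- conditional (mRNA-independent pQTL) scan ---------------------
        stage = "conditional"
        if proteins is not None:
            cond_results, cond_flags, statuses = mrna_independent_pqtl_scan(
                genotypes_f, proteins, expression, cfg=acfg
            )
            cond_results.to_csv(out / "conditional_scan.tsv", sep="\t", index=False)
            qtls = qtls.join(cond_flags)
            manifest.add_stage(
                "conditional",
                n_mrna_independent=int(cond_flags["is_mrna_independent_pqtl"].sum()),
                n_unadjusted=sum(
                    1 for s in statuses.values() if s == "unadjusted_mrna_missing"
                ),
            )
        else:
            qtls["is_mrna_independent_pqtl"] = False
        qtls.to_csv(out / "qtl_flags.tsv", sep="\t")

        # -- enrichment ---------------------------------------------------
        stage = "enrichment"
        target = pruned if acfg.enrich_on_pruned else list(candidates["snp_id"])
        enrich_rows = []
        flag_seeds = (
            ("eqtl", "enrich_eqtl"),
            ("pqtl", "enrich_pqtl"),
            ("mrna_independent_pqtl", "enrich_mrna_independent"),
        )
        for flag, seed_name in flag_seeds:
            if f"is_{flag}" not in qtls.columns:
                continue
            if flag != "eqtl" and proteins is None:
                continue
            if flag == "eqtl" and expression is None:
                continue
            if len(target) == 0:
                log.warning("empty dQTL target set: enrichment for %s skipped", flag)
                continue
            res = enrichment_test(
                target, genotypes_f.snps, qtls, flag, acfg, seed=seeds[seed_name]
            )
            enrich_rows.append(res.summary())
        enrich_df = pd.DataFrame(enrich_rows)
        enrich_df.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        manifest.add_stage("enrichment", n_tests=len(enrich_rows),
                           target_size=len(target))

        # -- protein ~ phenotype scan with FDR ----------------------------
        stage = "protein_phenotype"
        if proteins is not None:
            rows = []
            aligned = proteins.loc[trait.index]
            for pid in proteins.columns:
                r = regress_trait(
                    aligned[pid].to_numpy(), trait.to_numpy(),
                    snp_id=pid, trait_id="log2_ic50",
                )
                rows.append((pid, r.n, r.beta, r.se, r.t, r.r2, r.p))
            pp = pd.DataFrame(
                rows, columns=["protein_id", "n", "beta", "se", "t", "r2", "p"]
            )
            rejected, thr = bh_fdr(pp["p"].to_numpy(), acfg.fdr_q)
            pp["fdr_significant"] = rejected
            pp.to_csv(out / "protein_phenotype.tsv", sep="\t", index=False)
            qq_points(pp["p"].to_numpy()).to_csv(
                out / "protein_phenotype_qq.tsv", sep="\t", index=False
            )
            manifest.add_stage("protein_phenotype", n_proteins=len(pp),
                               n_fdr_significant=int(rejected.sum()),
                               fdr_threshold=thr)
    except PipelineError:
        raise
    except Exception as exc:  # annotate the failing stage; keep partial outputs
        (out / "FAILED_STAGE.txt").write_text(f"{stage}\n")
        raise PipelineError(stage, str(exc)) from exc

    manifest.write(out / "manifest.json")
    return manifest
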