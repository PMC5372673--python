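"""Genome-wide association of SNPs with drug cytotoxicity (dQTL scan).

Simulates a cohort with one strong planted phenotype effect, filters
SNPs (MAF >= 5%, HWE p >= 0.001), regresses log2 IC50 on minor-allele
copies SNP by SNP, and prunes the hits for linkage disequilibrium.
"""

import cytoqtl as cq

cfg = cq.SimulationConfig(
    n_samples=68,
    n_snps=500,
    seed=3,
    ld_blocks=[(10, 0.9)],  # the causal SNP sits in a 10-SNP LD block
    planted_effects=[cq.PlantedEffect("chr1:10000", "phenotype", None, 0.36, 1)],
)
gm = cq.simulate_genotypes(cfg)
dose, _ = cq.simulate_dose_response(gm, cfg)

phenotypes = cq.fit_ic50_table(dose)
pheno_vec, _ = cq.log2_phenotypes(phenotypes)

filtered, log = cq.snp_filter(gm)
print(f"SNP filter: {log['n_in']} -> {log['n_out']} "
      f"(-{log['removed_maf']} MAF, -{log['removed_hwe']} HWE)")

scan = cq.association_scan(
    filtered, pheno_vec.reindex(filtered.samples).rename("log2_ic50")
)
top = scan.loc[scan["p"].idxmin()]
print(f"top SNP: {top['snp_id']}  beta={top['beta']:.3f}  "
      f"R^2={top['r2']:.2f}  p={top['p']:.2e}")

candidates = scan[scan["p"] <= 0.001]
pruned = cq.ld_prune(candidates[["snp_id", "p"]], filtered)
print(f"dQTLs at p <= 0.001: {len(candidates)}; after LD pruning: {len(pruned)}")
# The LD block makes every tag of the causal SNP a dQTL; greedy pruning at
# r^2 <= 0.2 collapses the block back to its best representative.
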