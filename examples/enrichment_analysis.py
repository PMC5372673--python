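"""MAF-matched permutation enrichment of eQTLs among drug-associated SNPs.

Runs the complete planted-overlap study: ~100 dQTLs tagged through two LD
blocks whose causal SNPs also drive gene expression, against a ~5%
background eQTL rate, tested with 1,000 frequency-matched random SNP sets.
"""

from cytoqtl.workflows import eqtl_enrichment_study

study = eqtl_enrichment_study(seed=1)

print(f"universe after filters: {study.n_snps} SNPs")
print(f"dQTLs at p <= 0.001:    {study.n_dqtls}")
print(f"eQTLs among them:       {study.observed_eqtl_count}")
print(f"null expectation:       {study.null_mean:.1f} (max over 1000 sets: {study.null_max})")
print(f"empirical p:            {study.empirical_p:.6f}")
# The observed overlap dwarfs every frequency-matched random draw, so the
# add-one-smoothed empirical p sits at its floor 1/1001 -- reported as
# "<= 0.001", the strongest statement 1,000 permutations can make.
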