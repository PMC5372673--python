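import numpy as np
import pytest

import cytoqtl as cq


@pytest.fixture(scope="session")
def small_cohort():
    """A 68-sample cohort with one planted effect of each kind."""
    cfg = cq.SimulationConfig(
        n_samples=68,
        n_snps=60,
        n_genes=12,
        n_proteins=6,
        seed=11,
        planted_effects=[
            cq.PlantedEffect("chr1:10000", "phenotype", None, 0.36, 1),
            cq.PlantedEffect("chr1:15000", "gene", "gene0001", 0.4, 1),
            cq.PlantedEffect(
                "chr1:15000", "protein", "gene0001|iso1", 0.25, 1, "mediated"
            ),
            cq.PlantedEffect(
                "chr1:20000", "protein", "gene0002|iso1", 0.3, 1, "direct"
            ),
        ],
    )
    return cq.simulate_cohort(cfg), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
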