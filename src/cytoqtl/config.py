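"""Configuration objects for simulation and analysis.

``SimulationConfig`` encodes the study conditions the generators emulate:
a panel of 68 unrelated lymphoblastoid cell lines, biallelic SNPs with
minor allele frequency >= 5% in Hardy-Weinberg equilibrium, optional LD
blocks, expression/protein matrices with planted genotype effects, and
dose-response survival curves on a six-concentration grid with mean IC50
176.5 uM. ``AnalysisConfig`` holds the scan thresholds: dQTLs at
p <= 0.001, eQTLs/pQTLs at p <= 0.0001, MAF >= 0.05, HWE p >= 0.001,
FDR 0.05, and the permutation-enrichment settings (1000 MAF-matched sets,
bin width 0.02).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "PlantedEffect",
    "SimulationConfig",
    "AnalysisConfig",
    "DEFAULT_CONCENTRATIONS",
    "DEFAULT_MEAN_LOG2_IC50",
]

#: The six-point drug concentration grid used for cell-line phenotyping (uM).
DEFAULT_CONCENTRATIONS: tuple[float, ...] = (50.0, 100.0, 175.0, 250.0, 375.0, 500.0)

#: log2 of the mean LCL IC50 (176.5 uM).
DEFAULT_MEAN_LOG2_IC50: float = math.log2(176.5)


@dataclass(frozen=True)
class PlantedEffect:
    """A single genotype -> trait effect planted by the generators.

    ``variance_explained`` is the fraction of the trait's population
    variance attributable to the SNP; ``mode`` distinguishes, for proteins
    only, an effect routed through the encoding gene's mRNA (``mediated``)
    from one that bypasses it (``direct``).
    """

    snp_id: str
    trait_kind: str  # "phenotype" | "gene" | "protein"
    trait_id: str | None
    variance_explained: float
    sign: int = 1
    mode: str | None = None  # "mediated" | "direct"; proteins only

    def __post_init__(self) -> None:
        if self.trait_kind not in ("phenotype", "gene", "protein"):
            raise ValueError(f"unknown trait_kind {self.trait_kind!r}")
        if not (0.0 <= self.variance_explained < 1.0):
            raise ValueError("variance_explained must lie in [0, 1)")
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")
        if self.trait_kind == "protein":
            if self.mode not in ("mediated", "direct"):
                raise ValueError("protein effects need mode 'mediated' or 'direct'")
        elif self.mode is not None:
            raise ValueError("mode applies to protein effects only")
        if self.trait_kind != "phenotype" and self.trait_id is None:
            raise ValueError("gene/protein effects need a trait_id")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort generators.

    ``maf_spec`` may be a single frequency, a ``("uniform", lo, hi)``
    tuple, or an explicit per-SNP sequence; all values must lie in
    ``[0.05, 0.5]``. ``ld_blocks`` lists ``(size, rho)`` pairs consumed
    from the first SNP onward: each block of ``size`` consecutive SNPs
    shares a latent Gaussian factor with correlation ``rho``; remaining
    SNPs are independent. ``isoform_pairs`` name protein pairs (e.g. a
    38 kDa monomer and 75 kDa multimer of one gene) constrained to carry
    genotype effects of opposite sign. Genes in ``undetected_genes`` are
    reported missing in all but ``n_detected_for_undetected`` samples.
    """

    n_samples: int = 68
    n_snps: int = 100
    maf_spec: object = ("uniform", 0.05, 0.5)
    ld_blocks: list[tuple[int, float]] = field(default_factory=list)
    n_genes: int = 20
    n_proteins: int = 10
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    isoform_pairs: list[tuple[str, str]] = field(default_factory=list)
    undetected_genes: list[str] = field(default_factory=list)
    n_detected_for_undetected: int = 3
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS
    mean_log2_ic50: float = DEFAULT_MEAN_LOG2_IC50
    log2_ic50_sd: float = 0.45
    hill_slope: float = 1.5
    survival_noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        for f in self.resolve_mafs():
            if not (0.05 <= f <= 0.5):
                raise ValueError(f"MAF {f} outside [0.05, 0.5]")
        conc = list(self.concentrations)
        if len(conc) < 2 or any(c <= 0 for c in conc):
            raise ValueError("concentrations must be positive")
        if any(b >= a for a, b in zip(conc[1:], conc[:-1])):
            raise ValueError("concentrations must be strictly increasing")
        if self.hill_slope <= 0:
            raise ValueError("hill_slope must be positive")
        if self.survival_noise_sd < 0:
            raise ValueError("survival_noise_sd must be >= 0")
        n_block = sum(size for size, _ in self.ld_blocks)
        if n_block > self.n_snps:
            raise ValueError("LD blocks cover more SNPs than n_snps")
        for size, rho in self.ld_blocks:
            if size < 1 or not (0.0 <= rho < 1.0):
                raise ValueError("LD block needs size >= 1 and rho in [0, 1)")
        self._validate_effects()

    # -- helpers -----------------------------------------------------------

    def resolve_mafs(self) -> list[float]:
        """Per-SNP target MAFs implied by ``maf_spec`` (deterministic part).

        A ``("uniform", lo, hi)`` spec is resolved at generation time from
        the RNG; here it contributes only its bounds for validation.
        """
        spec = self.maf_spec
        if isinstance(spec, (int, float)):
            return [float(spec)] * self.n_snps
        if isinstance(spec, tuple) and len(spec) == 3 and spec[0] == "uniform":
            return [float(spec[1]), float(spec[2])]
        seq = [float(x) for x in spec]
        if len(seq) != self.n_snps:
            raise ValueError("explicit maf_spec length must equal n_snps")
        return seq

    def gene_ids(self) -> list[str]:
        return [f"gene{i:04d}" for i in range(self.n_genes)]

    def protein_ids(self) -> list[str]:
        """Protein feature ids, ``<gene>|iso<k>`` mapped round-robin to genes."""
        ids = []
        for j in range(self.n_proteins):
            gene = f"gene{j % max(self.n_genes, 1):04d}"
            ids.append(f"{gene}|iso{j // max(self.n_genes, 1) + 1}")
        return ids

    def effects_of(self, kind: str) -> list[PlantedEffect]:
        return [e for e in self.planted_effects if e.trait_kind == kind]

    def _validate_effects(self) -> None:
        if not self.planted_effects:
            return
        by_trait: dict[tuple[str, str | None], float] = {}
        gene_effects = {e.trait_id for e in self.effects_of("gene")}
        for e in self.planted_effects:
            key = (e.trait_kind, e.trait_id)
            by_trait[key] = by_trait.get(key, 0.0) + e.variance_explained
        for key, total in by_trait.items():
            if total >= 1.0:
                raise ValueError(
                    f"total variance_explained {total:.3f} for {key} must be < 1"
                )
        for e in self.effects_of("protein"):
            if e.mode == "mediated":
                from .containers import parse_protein_id

                gene, _ = parse_protein_id(e.trait_id)
                if gene is None or gene not in gene_effects:
                    raise ValueError(
                        f"mediated effect on {e.trait_id!r} requires a planted "
                        "genotype effect on its encoding gene"
                    )
                if gene in self.undetected_genes:
                    raise ValueError(
                        f"mediated effect on {e.trait_id!r}: encoding gene "
                        f"{gene!r} is listed as undetected"
                    )
        # opposite-sign constraint for isoform pairs (checked when both planted)
        prot_sign = {e.trait_id: e.sign for e in self.effects_of("protein")}
        for a, b in self.isoform_pairs:
            if a in prot_sign and b in prot_sign and prot_sign[a] == prot_sign[b]:
                raise ValueError(
                    f"isoform pair ({a!r}, {b!r}) must carry opposite-sign effects"
                )


@dataclass
class AnalysisConfig:
    """Thresholds and tuning knobs for the association/enrichment stages."""

    dqtl_p: float = 0.001
    qtl_p: float = 0.0001
    maf_min: float = 0.05
    hwe_p_min: float = 0.001
    fdr_q: float = 0.05
    ld_r2_max: float = 0.2
    ld_window_bp: int = 1_000_000
    n_permutations: int = 1000
    maf_bin_width: float = 0.02
    mrna_detection_threshold: float = 0.5
    enrich_on_pruned: bool = True

    def __post_init__(self) -> None:
        for name in ("dqtl_p", "qtl_p", "maf_min", "hwe_p_min", "fdr_q",
                     "ld_r2_max", "maf_bin_width", "mrna_detection_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.ld_window_bp < 1:
            raise ValueError("ld_window_bp must be >= 1")
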