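"""MAF-matched permutation enrichment and mRNA-independent protein QTLs.

The enrichment question: among the SNPs associated with the drug-response
phenotype (the dQTL set), are expression or protein QTLs over-represented
relative to frequency-matched chance? The null is built by drawing B
random SNP sets from the post-filter universe, each matching the target
set's minor-allele-frequency histogram bin-for-bin exactly, and counting
QTLs in each. The empirical p-value is add-one smoothed,
``(1 + #{null >= observed}) / (1 + B)``, so with B = 1000 the smallest
reportable value is 1/1001 (reported as "<= 0.001").

The conditional analysis asks whether a protein QTL acts through its
encoding gene's transcript: each protein is residualised on its mRNA by
OLS, and SNPs are scanned against the residuals. A genotype effect that
is fully mediated by mRNA vanishes in the residuals; one that bypasses
mRNA survives, and is flagged an mRNA-independent pQTL. Proteins whose
transcript is undetected in most samples (or unmapped) cannot be adjusted
and are scanned as centred values, labelled ``unadjusted_mrna_missing``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import association_scan, regress_trait
from .config import AnalysisConfig
from .containers import GenotypeMatrix, protein_gene_map

__all__ = [
    "EnrichmentResult",
    "ResidualTrait",
    "maf_matched_null_sets",
    "count_qtls",
    "empirical_enrichment_p",
    "residualize_protein_on_mrna",
    "mrna_independent_pqtl_scan",
    "enrichment_test",
]


@dataclass
class EnrichmentResult:
    """Observed QTL count in a target SNP set against B matched null counts."""

    target_size: int
    observed_count: int
    null_counts: np.ndarray
    empirical_p: float
    maf_bin_width: float
    n_permutations: int
    seed: int | None = None
    flag: str | None = None

    def summary(self) -> dict:
        return {
            "flag": self.flag,
            "target_size": self.target_size,
            "observed": self.observed_count,
            "null_mean": float(np.mean(self.null_counts)),
            "null_sd": float(np.std(self.null_counts, ddof=1)),
            "empirical_p": self.empirical_p,
            "n_permutations": self.n_permutations,
            "maf_bin_width": self.maf_bin_width,
            "seed": self.seed,
        }


@dataclass
class ResidualTrait:
    """A protein trait after (attempted) adjustment for its mRNA."""

    protein_id: str
    gene_id: str | None
    residuals: pd.Series
    adjustment_status: str  # "adjusted" | "unadjusted_mrna_missing"


def _maf_bins(mafs: np.ndarray, width: float) -> np.ndarray:
    """Assign MAFs to half-open frequency bins of the given width.

    Bin k covers [k*width, (k+1)*width); 0.5 lands in the top bin.
    """
    idx = np.floor(np.asarray(mafs, dtype=float) / width).astype(int)
    top = int(np.floor(0.5 / width))
    return np.minimum(idx, top)


def maf_matched_null_sets(
    target_snps,
    universe: pd.DataFrame,
    cfg: AnalysisConfig | None = None,
    seed: int | None = None,
) -> list[np.ndarray]:
    """Draw B random SNP sets matching the target's MAF histogram exactly.

    ``universe`` is the post-filter SNP metadata (indexed by snp_id, with
    a ``maf`` column); target SNPs remain eligible for sampling so small
    universes are not biased. Each null set draws, uniformly without
    replacement within each MAF bin, exactly as many SNPs as the target
    holds in that bin. Raises when a bin's target count exceeds its
    universe count, naming the bin.
    """
    cfg = cfg or AnalysisConfig()
    rng = np.random.default_rng(seed)
    target_snps = list(target_snps)
    missing = [s for s in target_snps if s not in universe.index]
    if missing:
        raise KeyError(f"target SNPs not in universe: {missing[:5]}")
    u_bins = _maf_bins(universe["maf"].to_numpy(), cfg.maf_bin_width)
    t_bins = _maf_bins(
        universe.loc[target_snps, "maf"].to_numpy(), cfg.maf_bin_width
    )
    universe_ids = universe.index.to_numpy(dtype=object)
    by_bin: dict[int, np.ndarray] = {
        b: universe_ids[u_bins == b] for b in np.unique(t_bins)
    }
    need = {b: int((t_bins == b).sum()) for b in np.unique(t_bins)}
    for b, k in need.items():
        have = by_bin[b].size
        if k > have:
            lo, hi = b * cfg.maf_bin_width, (b + 1) * cfg.maf_bin_width
            raise ValueError(
                f"MAF bin [{lo:.3f}, {hi:.3f}) needs {k} SNPs but the "
                f"universe holds only {have}"
            )
    sets = []
    for _ in range(cfg.n_permutations):
        parts = [rng.choice(by_bin[b], size=k, replace=False) for b, k in need.items()]
        sets.append(np.concatenate(parts))
    return sets


def count_qtls(snp_set, qtls: pd.DataFrame, flag: str) -> int:
    """Number of SNPs in ``snp_set`` whose QTL flag is set.

    ``flag`` is one of ``eqtl``, ``pqtl``, ``mrna_independent_pqtl``
    (or ``dqtl``); ``qtls`` is the classification table indexed by snp_id.
    """
    col = f"is_{flag}" if not flag.startswith("is_") else flag
    if col not in qtls.columns:
        raise KeyError(f"unknown QTL flag {flag!r}")
    snp_set = np.asarray(list(snp_set), dtype=object)
    if snp_set.size == 0:
        return 0
    idx = qtls.index.get_indexer(snp_set)
    if (idx < 0).any():
        unknown = snp_set[idx < 0][:5].tolist()
        raise KeyError(f"SNPs without QTL classification: {unknown}")
    return int(qtls[col].to_numpy()[idx].sum())


def empirical_enrichment_p(
    observed_count: int,
    null_counts,
    *,
    target_size: int | None = None,
    maf_bin_width: float = 0.02,
    seed: int | None = None,
    flag: str | None = None,
) -> EnrichmentResult:
    """Add-one smoothed permutation p for an observed QTL count.

    ``p = (1 + #{b: null_b >= observed}) / (1 + B)`` — never zero, and at
    B = 1000 the floor 1/1001 is exactly the "<= 0.001" boundary.
    """
    null_counts = np.asarray(null_counts, dtype=int)
    B = null_counts.size
    if B < 100:
        raise ValueError("need at least 100 permutation sets")
    p = (1 + int((null_counts >= observed_count).sum())) / (1 + B)
    return EnrichmentResult(
        target_size=int(target_size if target_size is not None else observed_count),
        observed_count=int(observed_count),
        null_counts=null_counts,
        empirical_p=float(p),
        maf_bin_width=maf_bin_width,
        n_permutations=B,
        seed=seed,
        flag=flag,
    )


def enrichment_test(
    target_snps,
    universe: pd.DataFrame,
    qtls: pd.DataFrame,
    flag: str,
    cfg: AnalysisConfig | None = None,
    seed: int | None = None,
) -> EnrichmentResult:
    """End-to-end MAF-matched enrichment of one QTL flag in a target set."""
    cfg = cfg or AnalysisConfig()
    target_snps = list(target_snps)
    observed = count_qtls(target_snps, qtls, flag)
    null_sets = maf_matched_null_sets(target_snps, universe, cfg, seed=seed)
    nulls = [count_qtls(s, qtls, flag) for s in null_sets]
    res = empirical_enrichment_p(
        observed,
        nulls,
        target_size=len(target_snps),
        maf_bin_width=cfg.maf_bin_width,
        seed=seed,
        flag=flag,
    )
    return res


def residualize_protein_on_mrna(
    protein: pd.Series,
    mrna: pd.Series | None,
    protein_id: str = "protein",
    gene_id: str | None = None,
    detection_threshold: float = 0.5,
) -> ResidualTrait:
    """Residuals of a protein after OLS regression on its mRNA.

    When the transcript is detected (non-missing) in at least
    ``detection_threshold`` of the samples, the protein is regressed on
    mRNA with intercept over complete pairs and the residuals are
    returned (``adjusted``); samples missing either value stay missing.
    Otherwise — transcript absent, undetected in most samples, or
    constant — the centred protein values are returned and the trait is
    labelled ``unadjusted_mrna_missing``.
    """
    prot = protein.astype(float)
    if mrna is not None:
        mrna = mrna.reindex(prot.index).astype(float)
        detected = float(np.isfinite(mrna.to_numpy()).mean())
    else:
        detected = 0.0
    if mrna is not None and detected >= detection_threshold:
        mask = np.isfinite(prot.to_numpy()) & np.isfinite(mrna.to_numpy())
        x = mrna.to_numpy()[mask]
        y = prot.to_numpy()[mask]
        if x.size >= 3 and float(x.max() - x.min()) > 0:
            xc = x - x.mean()
            beta = float(xc @ (y - y.mean())) / float(xc @ xc)
            resid = np.full(len(prot), np.nan)
            resid[mask] = y - (y.mean() + beta * xc)
            # exact linear dependence leaves only rounding error; snap it to
            # zero so downstream scans see a truly null (degenerate) trait
            tiny = 1e-10 * max(1.0, float(np.abs(y).max()))
            if np.nanmax(np.abs(resid[mask])) <= tiny:
                resid[mask] = 0.0
            return ResidualTrait(
                protein_id,
                gene_id,
                pd.Series(resid, index=prot.index, name=protein_id),
                "adjusted",
            )
        warnings.warn(
            f"mRNA for {protein_id!r} is constant or too sparse among complete "
            "pairs; treating as missing"
        )
    centred = prot - prot.mean(skipna=True)
    return ResidualTrait(
        protein_id,
        gene_id,
        pd.Series(centred.to_numpy(), index=prot.index, name=protein_id),
        "unadjusted_mrna_missing",
    )


def mrna_independent_pqtl_scan(
    genotypes: GenotypeMatrix,
    proteins: pd.DataFrame,
    expression: pd.DataFrame | None,
    gene_map: dict[str, str] | None = None,
    cfg: AnalysisConfig | None = None,
    *,
    keep: str = "all",
):
    """Scan SNPs against mRNA-adjusted protein residuals.

    Builds a :class:`ResidualTrait` for every protein (using ``gene_map``
    or, by default, the ``GENE|isoform`` header convention), scans all
    SNPs against the residual matrix, and flags a SNP as an
    mRNA-independent pQTL when its minimum residual-trait p is at or
    below ``cfg.qtl_p``.

    Returns ``(results, flags, statuses)``: the association rows with an
    ``adjustment_status`` column, a per-SNP flag table, and the per-protein
    adjustment statuses.
    """
    cfg = cfg or AnalysisConfig()
    if gene_map is None:
        gene_map = protein_gene_map(proteins.columns)
    residuals = {}
    statuses = {}
    for pid in proteins.columns:
        gene = gene_map.get(pid)
        mrna = None
        if gene is not None and expression is not None and gene in expression.columns:
            mrna = expression[gene]
        rt = residualize_protein_on_mrna(
            proteins[pid], mrna, protein_id=pid, gene_id=gene,
            detection_threshold=cfg.mrna_detection_threshold,
        )
        residuals[pid] = rt.residuals
        statuses[pid] = rt.adjustment_status
    resid_df = pd.DataFrame(residuals, index=proteins.index)
    results = association_scan(genotypes, resid_df, keep=keep)
    results = results.assign(
        adjustment_status=results["trait_id"].map(statuses)
    )
    best = (
        results.sort_values(["p", "trait_id"], kind="mergesort")
        .groupby("snp_id", sort=False)
        .head(1)
        .set_index("snp_id")
    )
    flags = pd.DataFrame(index=pd.Index(genotypes.snp_ids, name="snp_id"))
    flags["is_mrna_independent_pqtl"] = False
    flags["mrna_independent_pqtl_p"] = np.nan
    flags["mrna_independent_pqtl_trait"] = pd.Series(pd.NA, index=flags.index, dtype=object)
    common = best.index.intersection(flags.index)
    flags.loc[common, "mrna_independent_pqtl_p"] = best.loc[common, "p"]
    flags.loc[common, "mrna_independent_pqtl_trait"] = best.loc[common, "trait_id"]
    flags.loc[common, "is_mrna_independent_pqtl"] = best.loc[common, "p"] <= cfg.qtl_p
    return results, flags, statuses
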