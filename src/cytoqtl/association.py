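"""Single-SNP association scans and the per-SNP filters around them.

The model throughout is ordinary least squares of a trait on the number of
minor-allele copies, with intercept and no covariates, as appropriate for a
small panel of unrelated cell lines. Two-sided p-values come from the t
distribution with n - 2 degrees of freedom. Missing trait values are
handled by pairwise deletion and the per-result sample size is recorded.

QTL classification follows the nominal thresholds of the study design:
drug QTLs (dQTLs) at p <= 0.001 against the log2 IC50 phenotype, and
expression/protein QTLs (eQTLs/pQTLs) at p <= 0.0001 against any of the
genes/proteins genome-wide (no cis window).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import t as t_dist

from .config import AnalysisConfig
from .containers import GenotypeMatrix

__all__ = [
    "AssociationResult",
    "compute_maf",
    "hwe_exact_test",
    "snp_filter",
    "regress_trait",
    "association_scan",
    "ld_r2",
    "ld_prune",
    "classify_qtls",
    "bh_fdr",
    "qq_points",
]

RESULT_COLUMNS = ["snp_id", "trait_id", "n", "beta", "se", "t", "r2", "p", "degenerate"]


@dataclass(frozen=True)
class AssociationResult:
    """OLS slope of one trait on one dosage vector.

    ``r2`` is the coefficient of determination and satisfies
    ``r2 = t**2 / (t**2 + n - 2)`` exactly. ``degenerate`` marks constant
    dosage or trait: such results carry ``p = 1`` and ``beta = 0`` so that
    genome-scale scans never abort mid-run.
    """

    snp_id: str
    trait_id: str
    n: int
    beta: float
    se: float
    t: float
    r2: float
    p: float
    degenerate: bool = False


def compute_maf(dosages) -> tuple[float, bool]:
    """Minor allele frequency of a dosage vector.

    Returns ``(maf, flipped)`` where ``maf = min(f, 1 - f)`` for
    ``f = mean(dosage) / 2`` and ``flipped`` is True when the coded allele
    was the major one (frequency above 0.5).
    """
    d = np.asarray(dosages, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("empty dosage vector")
    f = float(d.mean()) / 2.0
    return min(f, 1.0 - f), f > 0.5


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional test of Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one
    (two-sided by probability ordering). Monomorphic sites return 1 by
    convention. The labelling of the two homozygote classes is irrelevant.
    """
    counts = (n_hom_major, n_het, n_hom_minor)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise ValueError("need at least one genotype")
    m = 2 * min(n_hom_major, n_hom_minor) + n_het  # minor allele count
    if m == 0:
        return 1.0
    # possible heterozygote counts share the parity of the minor allele count
    hets = np.arange(m % 2, m + 1, 2)
    logw = (
        hets * math.log(2.0)
        - gammaln((m - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln(n - (m + hets) / 2 + 1)
    )
    probs = np.exp(logw - logw.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def snp_filter(genotypes: GenotypeMatrix, cfg: AnalysisConfig | None = None):
    """Drop SNPs failing the MAF >= 5% or HWE p >= 0.001 criteria.

    Returns ``(filtered, log)`` where ``log`` counts removals per criterion.
    An empty result is a warning condition, not an error.
    """
    cfg = cfg or AnalysisConfig()
    maf = genotypes.snps["maf"].to_numpy()
    hwe = genotypes.snps["hwe_p"].to_numpy()
    keep = (maf >= cfg.maf_min) & (hwe >= cfg.hwe_p_min)
    log = {
        "n_in": genotypes.n_snps,
        "removed_maf": int((maf < cfg.maf_min).sum()),
        "removed_hwe": int(((maf >= cfg.maf_min) & (hwe < cfg.hwe_p_min)).sum()),
        "n_out": int(keep.sum()),
    }
    kept_ids = [s for s, k in zip(genotypes.snp_ids, keep) if k]
    return genotypes.subset(kept_ids), log


def _ols_stats(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float, bool]:
    """Slope, SE, t, r2, two-sided p for y ~ 1 + x. Degenerate inputs flagged."""
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx <= 0.0 or syy <= 0.0:
        return 0.0, float("nan"), 0.0, 0.0, 1.0, True
    sxy = float(xc @ yc)
    beta = sxy / sxx
    sse = max(syy - beta * sxy, 0.0)
    df = n - 2
    se = math.sqrt(sse / df / sxx) if df > 0 else float("nan")
    if se > 0:
        tval = beta / se
    else:  # perfect fit
        tval = math.copysign(float("inf"), beta) if beta != 0 else 0.0
    r2 = 1.0 - sse / syy
    p = float(2.0 * t_dist.sf(abs(tval), df)) if df > 0 else 1.0
    return beta, se, tval, r2, p, False


def regress_trait(dosages, trait, snp_id: str = "snp", trait_id: str = "trait") -> AssociationResult:
    """OLS of one trait on minor-allele copies, with pairwise deletion.

    Raises ``ValueError`` with fewer than 3 complete pairs. Constant dosage
    or trait yields a flagged degenerate result (p = 1) rather than an
    exception, so scans continue.
    """
    x = np.asarray(dosages, dtype=float)
    y = np.asarray(trait, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage and trait vectors must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError(f"need >= 3 paired observations, got {x.size}")
    beta, se, tval, r2, p, degen = _ols_stats(x, y)
    return AssociationResult(snp_id, trait_id, int(x.size), beta, se, tval, r2, p, degen)


def _scan_block(G: np.ndarray, Y: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised OLS of every trait column in Y on every dosage column in G.

    Assumes fully observed data. Returns (m, k) arrays of beta/se/t/r2/p
    plus a degeneracy mask.
    """
    n = G.shape[0]
    Gc = G - G.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sxx = np.einsum("ij,ij->j", Gc, Gc)
    syy = np.einsum("ij,ij->j", Yc, Yc)
    S = Gc.T @ Yc  # (m, k)
    degen = (sxx <= 0)[:, None] | (syy <= 0)[None, :]
    sxx_safe = np.where(sxx > 0, sxx, 1.0)
    syy_safe = np.where(syy > 0, syy, 1.0)
    beta = S / sxx_safe[:, None]
    sse = np.maximum(syy_safe[None, :] - beta * S, 0.0)
    df = n - 2
    se = np.sqrt(sse / df / sxx_safe[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta / se, np.where(beta != 0, np.inf * np.sign(beta), 0.0))
    r2 = 1.0 - sse / syy_safe[None, :]
    p = 2.0 * t_dist.sf(np.abs(tval), df)
    beta = np.where(degen, 0.0, beta)
    tval = np.where(degen, 0.0, tval)
    r2 = np.where(degen, 0.0, r2)
    p = np.where(degen, 1.0, p)
    return {"beta": beta, "se": se, "t": tval, "r2": r2, "p": p, "degenerate": degen,
            "n": np.full(beta.shape, n, dtype=int)}


def association_scan(
    genotypes: GenotypeMatrix,
    traits,
    *,
    keep: str = "all",
) -> pd.DataFrame:
    """Regress every trait against every SNP.

    Parameters
    ----------
    genotypes
        The (filtered) genotype panel.
    traits
        Samples x traits DataFrame (index = sample ids) or a named Series
        for a single trait. Sample ids must match the genotype panel as a
        set; rows are aligned by id.
    keep
        ``"all"`` returns one row per (SNP, trait) pair; ``"best"`` keeps
        only each SNP's minimum-p trait, which is what QTL classification
        consumes.

    Returns a DataFrame with columns snp_id, trait_id, n, beta, se, t, r2,
    p, degenerate. An empty trait matrix yields an empty result.
    """
    if isinstance(traits, pd.Series):
        traits = traits.to_frame(name=traits.name or "trait")
    if keep not in ("all", "best"):
        raise ValueError("keep must be 'all' or 'best'")
    if set(traits.index) != set(genotypes.samples):
        raise ValueError("sample ids of traits do not match the genotype panel")
    traits = traits.loc[genotypes.samples]
    if traits.shape[1] == 0:
        return pd.DataFrame(columns=RESULT_COLUMNS)

    G = genotypes.dosages
    Y = traits.to_numpy(dtype=float)
    snp_ids = np.asarray(genotypes.snp_ids, dtype=object)
    trait_ids = np.asarray(traits.columns, dtype=object)

    complete_cols = ~np.isnan(Y).any(axis=0)
    pieces: list[pd.DataFrame] = []

    if complete_cols.any() and not np.isnan(G).any():
        stats = _scan_block(G, Y[:, complete_cols])
        pieces.append(_block_to_frame(stats, snp_ids, trait_ids[complete_cols]))
    else:
        complete_cols = np.zeros(Y.shape[1], dtype=bool)

    # traits with missing values: pairwise deletion, one column at a time
    for j in np.flatnonzero(~complete_cols):
        y = Y[:, j]
        rows = []
        for i, sid in enumerate(snp_ids):
            x = G[:, i]
            mask = np.isfinite(x) & np.isfinite(y)
            if mask.sum() < 3:
                rows.append((sid, trait_ids[j], int(mask.sum()), 0.0, np.nan, 0.0, 0.0, 1.0, True))
                continue
            beta, se, tval, r2, p, degen = _ols_stats(x[mask], y[mask])
            rows.append((sid, trait_ids[j], int(mask.sum()), beta, se, tval, r2, p, degen))
        pieces.append(pd.DataFrame(rows, columns=RESULT_COLUMNS))

    out = pd.concat(pieces, ignore_index=True) if pieces else pd.DataFrame(columns=RESULT_COLUMNS)
    if keep == "best" and len(out):
        present = set(out["snp_id"])
        order = [s for s in snp_ids if s in present]
        out = (
            out.sort_values(["p", "trait_id"], kind="mergesort")
            .groupby("snp_id", sort=False)
            .head(1)
            .set_index("snp_id")
            .loc[order]
            .reset_index()
        )
    return out


def _block_to_frame(stats, snp_ids, trait_ids) -> pd.DataFrame:
    m, k = stats["beta"].shape
    return pd.DataFrame(
        {
            "snp_id": np.repeat(snp_ids, k),
            "trait_id": np.tile(trait_ids, m),
            "n": stats["n"].ravel(),
            "beta": stats["beta"].ravel(),
            "se": stats["se"].ravel(),
            "t": stats["t"].ravel(),
            "r2": stats["r2"].ravel(),
            "p": stats["p"].ravel(),
            "degenerate": stats["degenerate"].ravel(),
        }
    )


def ld_r2(dosages_i, dosages_j) -> float:
    """Squared Pearson correlation of two dosage vectors.

    A constant vector has undefined LD; by convention 0 is returned (the
    pruner then never removes on its account).
    """
    x = np.asarray(dosages_i, dtype=float)
    y = np.asarray(dosages_j, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage vectors must have equal length")
    xc = x - x.mean()
    yc = y - y.mean()
    den = float((xc @ xc) * (yc @ yc))
    if den <= 0:
        return 0.0
    return float((xc @ yc) ** 2 / den)


def ld_prune(
    candidates: pd.DataFrame,
    genotypes: GenotypeMatrix,
    cfg: AnalysisConfig | None = None,
) -> list[str]:
    """Greedy keep-best LD pruning of an association candidate list.

    Candidates are visited by ascending p (ties broken by chromosome,
    position, then snp_id); a SNP is kept iff its dosage r^2 with every
    already-kept SNP within ``ld_window_bp`` on the same chromosome is at
    most ``ld_r2_max``. Deterministic by construction.
    """
    cfg = cfg or AnalysisConfig()
    if len(candidates) == 0:
        return []
    meta = genotypes.snps
    order = candidates.copy()
    order["chrom"] = [meta.at[s, "chrom"] for s in order["snp_id"]]
    order["pos"] = [meta.at[s, "pos"] for s in order["snp_id"]]
    order = order.sort_values(["p", "chrom", "pos", "snp_id"], kind="mergesort")
    kept: list[str] = []
    kept_meta: list[tuple[str, int, np.ndarray]] = []
    for sid, chrom, pos in zip(order["snp_id"], order["chrom"], order["pos"]):
        x = genotypes.dosage_vector(sid)
        ok = True
        for kchrom, kpos, kx in kept_meta:
            if kchrom == chrom and abs(kpos - pos) <= cfg.ld_window_bp:
                if ld_r2(x, kx) > cfg.ld_r2_max:
                    ok = False
                    break
        if ok:
            kept.append(sid)
            kept_meta.append((chrom, int(pos), x))
    return kept


def classify_qtls(
    phenotype_results: pd.DataFrame | None,
    expression_best: pd.DataFrame | None,
    protein_best: pd.DataFrame | None,
    cfg: AnalysisConfig | None = None,
    snp_universe=None,
) -> pd.DataFrame:
    """Per-SNP QTL flags at the study thresholds.

    ``is_dqtl`` iff the phenotype p <= ``dqtl_p``; ``is_eqtl`` /
    ``is_pqtl`` iff the minimum gene / protein p <= ``qtl_p``. Best
    supporting trait and p are stored per flag. Scans passed as ``None``
    leave their flag False throughout.
    """
    cfg = cfg or AnalysisConfig()
    ids: list = list(snp_universe) if snp_universe is not None else []
    if not ids:
        seen = set()
        for df in (phenotype_results, expression_best, protein_best):
            if df is not None:
                for s in df["snp_id"]:
                    if s not in seen:
                        seen.add(s)
                        ids.append(s)
    out = pd.DataFrame(index=pd.Index(ids, name="snp_id"))
    for name, df, thr, pcol, tcol in (
        ("dqtl", phenotype_results, cfg.dqtl_p, "dqtl_p", "dqtl_trait"),
        ("eqtl", expression_best, cfg.qtl_p, "eqtl_p", "eqtl_trait"),
        ("pqtl", protein_best, cfg.qtl_p, "pqtl_p", "pqtl_trait"),
    ):
        flag = pd.Series(False, index=out.index)
        pbest = pd.Series(np.nan, index=out.index)
        tbest = pd.Series(pd.NA, index=out.index, dtype=object)
        if df is not None and len(df):
            best = (
                df.sort_values(["p", "trait_id"], kind="mergesort")
                .groupby("snp_id", sort=False)
                .head(1)
                .set_index("snp_id")
            )
            common = best.index.intersection(out.index)
            pbest.loc[common] = best.loc[common, "p"]
            tbest.loc[common] = best.loc[common, "trait_id"]
            flag.loc[common] = best.loc[common, "p"] <= thr
        out[f"is_{name}"] = flag
        out[pcol] = pbest
        out[tcol] = tbest
    return out


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up at level ``q``.

    Returns a boolean rejection mask (in input order) and the adjusted
    p-value threshold (0 when nothing is rejected). Empty input yields an
    empty mask.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    crit = (np.arange(1, m + 1) / m) * q
    passing = np.flatnonzero(sorted_p <= crit)
    if passing.size == 0:
        return np.zeros(m, dtype=bool), 0.0
    k = passing[-1] + 1
    thr = sorted_p[k - 1]
    return p <= thr, float(thr)


def qq_points(p_values) -> pd.DataFrame:
    """Expected vs observed -log10 p pairs for a quantile-quantile plot.

    Expected quantiles are ``i / (m + 1)`` for rank ``i``. Zero p-values
    are clipped to the smallest positive float with a warning.
    """
    import warnings

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p-values of 0 clipped to the smallest positive float")
        p = np.where(p == 0, np.finfo(float).tiny, p)
    m = p.size
    observed = np.sort(p)
    expected = np.arange(1, m + 1) / (m + 1)
    return pd.DataFrame(
        {
            "expected_neglog10": -np.log10(expected),
            "observed_neglog10": -np.log10(observed),
        }
    )
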