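"""In-memory containers shared across the pipeline.

The central object is :class:`GenotypeMatrix`: a sample x SNP matrix of
minor-allele dosages plus per-SNP metadata (position, alleles, minor allele
frequency, exact Hardy-Weinberg p-value). Expression, protein and
dose-response data travel as plain :class:`pandas.DataFrame` objects with
documented layouts; only genotypes need a richer type because every stage
consumes them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "parse_protein_id", "protein_gene_map"]

_CHRPOS_RE = re.compile(r"^(?:chr)?([0-9XYM]+):(\d+)$")


def _maf_from_dosages(d: np.ndarray) -> tuple[float, bool]:
    """Minor allele frequency of a dosage vector; second value flags
    whether the coded allele is actually the major one (freq > 0.5)."""
    f = float(np.nanmean(d)) / 2.0
    return (min(f, 1.0 - f), f > 0.5)


@dataclass
class GenotypeMatrix:
    """Sample x SNP minor-allele dosage matrix with per-SNP metadata.

    Parameters
    ----------
    samples
        Ordered unique sample identifiers.
    snps
        Per-SNP metadata indexed by SNP id, with at least columns
        ``chrom``, ``pos`` (1-based), ``ref``, ``alt``, ``maf``, ``hwe_p``.
    dosages
        ``(n_samples, n_snps)`` array of minor-allele copies in ``[0, 2]``.
        Hard calls are integral; mean-imputed entries may be fractional.
    """

    samples: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in GenotypeMatrix")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if self.dosages.size and (
            np.nanmin(self.dosages) < -1e-9 or np.nanmax(self.dosages) > 2 + 1e-9
        ):
            raise ValueError("dosages must lie in [0, 2]")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_dosages(
        cls,
        samples: list[str],
        snp_ids: list[str],
        dosages: np.ndarray,
        *,
        chrom: list | None = None,
        pos: list | None = None,
        ref: list | None = None,
        alt: list | None = None,
    ) -> "GenotypeMatrix":
        """Build a matrix from raw dosages, computing MAF and HWE metadata.

        SNP ids of the form ``chr<k>:<pos>`` are parsed to fill chromosome
        and position when not given explicitly; anything else gets
        chromosome ``"."`` and position 0.
        """
        from .association import hwe_exact_test  # local import: avoid cycle

        dosages = np.asarray(dosages, dtype=float).copy()
        n_snps = len(snp_ids)
        if chrom is None or pos is None:
            chrom, pos = [], []
            for sid in snp_ids:
                m = _CHRPOS_RE.match(str(sid))
                chrom.append(m.group(1) if m else ".")
                pos.append(int(m.group(2)) if m else 0)
        ref = list(ref) if ref is not None else ["A"] * n_snps
        alt = list(alt) if alt is not None else ["G"] * n_snps
        mafs = np.empty(n_snps)
        flipped = np.zeros(n_snps, dtype=bool)
        hwe = np.empty(n_snps)
        for j in range(n_snps):
            mafs[j], flipped[j] = _maf_from_dosages(dosages[:, j])
            if flipped[j]:  # orient to minor-allele copies
                dosages[:, j] = 2.0 - dosages[:, j]
                ref[j], alt[j] = alt[j], ref[j]
            col = dosages[:, j]
            hard = np.rint(col[np.isfinite(col)]).astype(int)
            counts = np.bincount(hard, minlength=3)
            hwe[j] = hwe_exact_test(int(counts[0]), int(counts[1]), int(counts[2]))
        meta = pd.DataFrame(
            {
                "chrom": [str(c) for c in chrom],
                "pos": [int(p) for p in pos],
                "ref": ref,
                "alt": alt,
                "maf": mafs,
                "hwe_p": hwe,
                "flipped": flipped,
            },
            index=pd.Index([str(s) for s in snp_ids], name="snp_id"),
        )
        return cls(samples=list(samples), snps=meta, dosages=dosages)

    # -- accessors --------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps.index)

    def dosage_vector(self, snp_id: str) -> np.ndarray:
        j = self.snps.index.get_loc(snp_id)
        return self.dosages[:, j]

    def subset(self, snp_ids) -> "GenotypeMatrix":
        """Return a new matrix restricted to ``snp_ids`` (order preserved)."""
        snp_ids = list(snp_ids)
        idx = [self.snps.index.get_loc(s) for s in snp_ids]
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=self.snps.iloc[idx].copy(),
            dosages=self.dosages[:, idx].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Dosages as a samples x SNPs DataFrame."""
        return pd.DataFrame(
            self.dosages, index=pd.Index(self.samples, name="sample"),
            columns=self.snps.index,
        )

    def __eq__(self, other) -> bool:  # value equality, used by round-trip tests
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and list(self.snps.index) == list(other.snps.index)
            and np.allclose(self.dosages, other.dosages, equal_nan=True)
            and np.allclose(self.snps["maf"], other.snps["maf"])
            and list(self.snps["chrom"]) == list(other.snps["chrom"])
            and list(self.snps["pos"]) == list(other.snps["pos"])
        )


def parse_protein_id(feature_id: str) -> tuple[str | None, str | None]:
    """Split a protein column header ``GENE|isoform`` into its parts.

    ``"HOXD10|75kDa"`` -> ``("HOXD10", "75kDa")``. Headers without the
    delimiter return ``(None, None)``: such proteins have no known encoding
    gene and are scanned unadjusted downstream.
    """
    if "|" in feature_id:
        gene, iso = feature_id.split("|", 1)
        return gene, iso
    return None, None


def protein_gene_map(protein_ids) -> dict[str, str]:
    """Mapping protein feature id -> encoding gene id, from parseable headers."""
    out = {}
    for pid in protein_ids:
        gene, _ = parse_protein_id(pid)
        if gene is not None:
            out[pid] = gene
    return out
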