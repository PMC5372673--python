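"""Readers and writers for the pipeline's standard formats.

Genotypes come in as VCF (hard GT calls, biallelic records, 1-based
positions) via cyvcf2, or as a plain samples x SNPs dosage TSV; both
yield the same :class:`GenotypeMatrix` for equivalent content, with MAF
and exact-HWE metadata recomputed from the calls. Expression and protein
matrices, dose-response curves, and all result tables are TSV. A
:class:`RunManifest` records the configuration snapshot, seeds, input
digests and per-stage row counts of a pipeline run; it is serialised as
canonical JSON with no wall-clock fields so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = [
    "read_genotypes_vcf",
    "write_genotypes_vcf",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_dose_response_tsv",
    "write_dose_response_tsv",
    "RunManifest",
    "file_digest",
]

log = logging.getLogger("cytoqtl")

MISSINGNESS_MAX = 0.05  # SNPs missing in more than this fraction are dropped


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read hard GT calls from a VCF into a minor-allele dosage matrix.

    Multiallelic records are skipped (counted in the log). Missing
    genotypes follow a drop-or-impute policy: SNPs missing in more than
    5% of samples are dropped; remaining missing dosages are mean-imputed
    (HWE is computed from the observed hard calls before imputation).
    Records whose ALT allele is the major one are flipped to minor-allele
    coding. Positions stay 1-based.
    """
    from cyvcf2 import VCF

    from .association import hwe_exact_test

    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF contains no samples")
    ids, chroms, poss, refs, alts = [], [], [], [], []
    cols, mafs, hwes, flips = [], [], [], []
    n_multi = n_dropped_missing = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types
        missing = gt == 2
        if missing.mean() > MISSINGNESS_MAX:
            n_dropped_missing += 1
            continue
        dose = np.where(gt == 3, 2.0, np.where(gt == 1, 1.0, 0.0))
        dose[missing] = np.nan
        obs = dose[~missing].astype(int)
        counts = np.bincount(obs, minlength=3)
        alt_freq = float(np.nanmean(dose)) / 2.0
        flipped = alt_freq > 0.5
        if flipped:
            dose = 2.0 - dose
            counts = counts[::-1]
        hwe_p = hwe_exact_test(int(counts[0]), int(counts[1]), int(counts[2]))
        if missing.any():
            dose[np.isnan(dose)] = np.nanmean(dose)
        ids.append(rec.ID if rec.ID not in (None, ".") else f"chr{rec.CHROM}:{rec.POS}".replace("chrchr", "chr"))
        chroms.append(str(rec.CHROM).removeprefix("chr"))
        poss.append(int(rec.POS))
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        cols.append(dose)
        mafs.append(min(alt_freq, 1.0 - alt_freq))
        hwes.append(hwe_p)
        flips.append(flipped)
    if n_multi:
        log.info("skipped %d multiallelic records", n_multi)
    if n_dropped_missing:
        log.info("dropped %d records with >%.0f%% missing genotypes",
                 n_dropped_missing, 100 * MISSINGNESS_MAX)
    if not ids:
        raise ValueError(f"{path}: no usable biallelic records")
    meta = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts,
         "maf": mafs, "hwe_p": hwes, "flipped": flips},
        index=pd.Index(ids, name="snp_id"),
    )
    return GenotypeMatrix(samples=samples, snps=meta, dosages=np.column_stack(cols))


def write_genotypes_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write hard-call genotypes as a minimal VCF 4.2 (ALT = minor allele)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, (sid, row) in enumerate(genotypes.snps.iterrows()):
            calls = [
                gt_str[int(round(d))] if np.isfinite(d) else "./."
                for d in genotypes.dosages[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{sid}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    """Samples x SNPs minor-allele dosage table."""
    genotypes.to_frame().to_csv(path, sep="\t")


def read_dosage_tsv(path) -> GenotypeMatrix:
    """Read a samples x SNPs dosage TSV (sample ids in the first column).

    SNP ids of the form ``chr<k>:<pos>`` recover chromosome/position
    metadata; MAF and HWE are recomputed from the dosages.
    """
    df = _read_tsv_checked(path)
    return GenotypeMatrix.from_dosages(
        list(df.index), list(df.columns), df.to_numpy(dtype=float)
    )


def _read_tsv_checked(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA"], float_precision="round_trip"
    )
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    df.index = df.index.astype(str)
    df.index.name = "sample"
    return df


def read_matrix_tsv(path, kind: str = "expression") -> pd.DataFrame:
    """Read an expression or protein matrix (samples in rows, NA = missing).

    Protein headers following the ``GENE|isoform`` convention are kept
    verbatim; :func:`cytoqtl.containers.protein_gene_map` parses them.
    """
    if kind not in ("expression", "protein"):
        raise ValueError("kind must be 'expression' or 'protein'")
    df = _read_tsv_checked(path)
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate feature id {dup!r}")
    return df.astype(float)


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA")


def read_dose_response_tsv(path) -> pd.DataFrame:
    """Read a tidy dose-response table (sample, concentration_uM, pct_survival)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"sample", "concentration_uM", "pct_survival"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(required)}")
    df["sample"] = df["sample"].astype(str)
    return df


def write_dose_response_tsv(dose: pd.DataFrame, path) -> None:
    dose.to_csv(path, sep="\t", index=False)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Deterministic record of a pipeline run.

    Holds the configuration snapshot, the root seed and every derived
    stage seed, sha256 digests of file inputs, and one entry per executed
    stage with its row counts. Serialised as sorted-key JSON; reruns of
    the same configuration produce byte-identical manifests (wall-clock
    times are deliberately excluded and go to the log instead).
    """

    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)

    def add_stage(self, name: str, **counts) -> None:
        self.stages.append({"order": len(self.stages), "stage": name, **counts})

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "seeds": self.seeds,
            "input_digests": self.input_digests,
            "stages": self.stages,
        }
        return json.dumps(payload, sort_keys=True, indent=2, default=_jsonable) + "\n"

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        d = json.loads(text)
        return cls(
            config=d["config"],
            seeds=d["seeds"],
            input_digests=d["input_digests"],
            stages=d["stages"],
        )

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls.from_json(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, tuple, set)):
        return list(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
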