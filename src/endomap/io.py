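"""Readers for genotypes (VCF or dosage TSV) and subject-keyed phenotype
tables.  All joins are by subject ID, never by row order."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .datatypes import MISSING, GenotypeMatrix, QTMatrix

log = logging.getLogger(__name__)

_SEX_MAP = {"M": 1.0, "F": 0.0, "0": 0.0, "1": 1.0, 0: 0.0, 1: 1.0}


def read_genotypes(path, fmt: str | None = None, coding: str = "minor") -> GenotypeMatrix:
    """Read genotypes from a VCF (GT field) or an additive-dosage TSV.

    ``fmt`` is inferred from the suffix when omitted.  With
    ``coding="minor"`` (default) columns whose ALT/counted allele is the
    major one are flipped (g -> 2 - g) so values count minor alleles; with
    ``coding="alt"`` the file's coding is kept as-is.  Multi-allelic VCF
    records are rejected.
    """
    if coding not in ("minor", "alt"):
        raise ValidationError(f"unknown coding {coding!r}")
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix == ".vcf" or path.name.endswith(".vcf.gz") else "tsv"
    if fmt == "vcf":
        gm = _read_vcf(path)
    elif fmt == "tsv":
        gm = _read_dosage_tsv(path)
    else:
        raise ValidationError(f"unknown genotype format {fmt!r}")
    if coding == "minor":
        gm = _flip_to_minor(gm)
    return gm


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    subjects = np.asarray(vcf.samples, dtype=object)
    snp_ids: list[str] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValidationError(
                f"multi-allelic record at {var.CHROM}:{var.POS} ({var.ID}); "
                "split or drop multi-allelic sites first"
            )
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        # gts012: 0/1/2 ALT-allele dosage, 3 = unknown
        g = var.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        cols.append(g)
    if not cols:
        raise ValidationError(f"no variant records in {path}")
    return GenotypeMatrix(np.column_stack(cols), subjects, np.asarray(snp_ids, dtype=object))


def _read_dosage_tsv(path: Path, missing_token: str = "NA") -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.index.has_duplicates:
        raise ValidationError(f"duplicate subject IDs in {path}")
    vals = df.replace(missing_token, str(MISSING)).apply(pd.to_numeric)
    if not ((vals == MISSING) | vals.isin([0, 1, 2])).all().all():
        raise ValidationError(f"dosage values in {path} must be 0/1/2 or {missing_token}")
    return GenotypeMatrix(
        vals.to_numpy(dtype=np.int8),
        df.index.to_numpy(dtype=object),
        df.columns.to_numpy(dtype=object),
    )


def _flip_to_minor(gm: GenotypeMatrix) -> GenotypeMatrix:
    vals = gm.values.copy()
    flipped = []
    for j in range(gm.n_snps):
        g = vals[:, j]
        obs = g[g != MISSING]
        if obs.size and obs.sum() > obs.size:  # counted-allele frequency > 0.5
            g[g != MISSING] = 2 - g[g != MISSING]
            flipped.append(str(gm.snp_ids[j]))
    if flipped:
        log.info("flipped %d SNP(s) to minor-allele coding: %s", len(flipped), flipped[:10])
    return GenotypeMatrix(vals, gm.subject_ids, gm.snp_ids)


def read_qts(path) -> QTMatrix:
    """Subject-keyed TSV of imaging QTs (first column = subject ID)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValidationError(f"duplicate subject IDs in {path}")
    return QTMatrix(
        df.to_numpy(dtype=float),
        df.index.to_numpy(dtype=object),
        df.columns.to_numpy(dtype=object),
    )


def read_covariates(path) -> pd.DataFrame:
    """Subject-keyed TSV with age, sex, education; sex parsed from {M,F,0,1}."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValidationError(f"duplicate subject IDs in {path}")
    if "sex" in df.columns:
        try:
            df["sex"] = df["sex"].map(lambda v: _SEX_MAP[v if isinstance(v, str) else int(v)])
        except KeyError as exc:
            raise ValidationError(f"unparseable sex value {exc} in {path}") from exc
    return df.astype(float)


def read_diagnosis(path) -> pd.Series:
    """Subject-keyed TSV with a single diagnosis-label column."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        raise ValidationError(f"duplicate subject IDs in {path}")
    if df.shape[1] != 1:
        raise ValidationError(f"diagnosis file {path} must have exactly one label column")
    return df.iloc[:, 0].rename("diagnosis")


def common_subjects(*id_arrays) -> np.ndarray:
    """Subject IDs present in every input, in the order of the first."""
    first = np.asarray(id_arrays[0], dtype=object)
    keep = np.ones(len(first), dtype=bool)
    for other in id_arrays[1:]:
        keep &= np.isin(first, np.asarray(other, dtype=object))
    out = first[keep]
    if len(out) == 0:
        raise ValidationError("no overlapping subject IDs across input files")
    return out
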