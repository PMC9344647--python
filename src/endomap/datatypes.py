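"""Core in-memory containers for the imaging-genetics pipeline.

Subjects are always identified by string IDs and joined by ID, never by row
order.  Genotypes use additive minor-allele coding: each entry counts copies
of the minor allele (0, 1 or 2), with ``MISSING`` (-1) marking no-calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import AlignmentError, ValidationError

#: sentinel for a missing genotype call
MISSING: int = -1


def _as_str_array(ids, what: str) -> np.ndarray:
    arr = np.asarray(list(ids), dtype=object)
    if arr.ndim != 1:
        raise ValidationError(f"{what} must be a 1-D sequence of identifiers")
    if len(set(arr)) != len(arr):
        dupes = pd.Index(arr)[pd.Index(arr).duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")
    return arr


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs additive genotype matrix.

    ``values[i, j]`` is the number of minor alleles subject ``i`` carries at
    SNP ``j`` (0/1/2), or :data:`MISSING` for a failed call.
    """

    values: np.ndarray
    subject_ids: np.ndarray
    snp_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            if np.isnan(np.asarray(self.values, dtype=float)).any():
                raise ValidationError(
                    "genotype values must be integers; encode missing calls "
                    f"as {MISSING}, not NaN"
                )
            self.values = self.values.astype(np.int8)
        self.subject_ids = _as_str_array(self.subject_ids, "subject IDs")
        self.snp_ids = _as_str_array(self.snp_ids, "SNP IDs")
        if self.values.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise ValidationError(
                f"genotype matrix shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.snp_ids)} SNPs"
            )
        ok = (self.values == MISSING) | (
            (self.values >= 0) & (self.values <= 2)
        )
        if not ok.all():
            raise ValidationError(
                "genotype values must be in {0, 1, 2} or the missing marker "
                f"{MISSING}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def column(self, snp_id: str) -> np.ndarray:
        j = np.flatnonzero(self.snp_ids == snp_id)
        if len(j) == 0:
            raise KeyError(snp_id)
        return self.values[:, j[0]]

    def subset_subjects(self, subject_ids) -> "GenotypeMatrix":
        idx = _index_of(self.subject_ids, subject_ids, "subjects")
        return GenotypeMatrix(self.values[idx], np.asarray(subject_ids, dtype=object), self.snp_ids)

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        idx = _index_of(self.snp_ids, snp_ids, "SNPs")
        return GenotypeMatrix(self.values[:, idx], self.subject_ids, np.asarray(snp_ids, dtype=object))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.snp_ids)


@dataclass
class QTMatrix:
    """Subjects x ROIs table of imaging quantitative traits (e.g. SUVR means)."""

    values: np.ndarray
    subject_ids: np.ndarray
    roi_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = _as_str_array(self.subject_ids, "subject IDs")
        self.roi_ids = _as_str_array(self.roi_ids, "ROI IDs")
        if self.values.shape != (len(self.subject_ids), len(self.roi_ids)):
            raise ValidationError(
                f"QT matrix shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.roi_ids)} ROIs"
            )
        if len(self.roi_ids) < 3:
            raise ValidationError("need at least 3 ROIs (map correlation needs df)")
        if not np.isfinite(self.values).all():
            raise ValidationError("QT values must be finite")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    def subset_subjects(self, subject_ids) -> "QTMatrix":
        idx = _index_of(self.subject_ids, subject_ids, "subjects")
        return QTMatrix(self.values[idx], np.asarray(subject_ids, dtype=object), self.roi_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.roi_ids)


@dataclass
class Contrast:
    """One case/control diagnostic comparison (e.g. CN vs AD).

    ``x`` codes control subjects 0 and case subjects 1; ``covariates`` is a
    subjects x k table (age, sex, education) aligned with ``subject_ids``.
    """

    name: str
    subject_ids: np.ndarray
    x: np.ndarray
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.subject_ids = _as_str_array(self.subject_ids, "subject IDs")
        self.x = np.asarray(self.x, dtype=float)
        if self.x.shape != (len(self.subject_ids),):
            raise AlignmentError("diagnosis vector does not align with subject IDs")
        classes = np.unique(self.x)
        if not np.isin(classes, [0.0, 1.0]).all():
            raise ValidationError("diagnosis vector must be coded 0 (control) / 1 (case)")
        if len(classes) < 2:
            raise ValidationError(f"contrast {self.name!r} must contain both classes")
        if len(self.covariates) != len(self.subject_ids):
            raise AlignmentError("covariate rows do not align with subject IDs")
        self.covariates = self.covariates.set_axis(self.subject_ids, axis=0)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_cases(self) -> int:
        return int(self.x.sum())

    @property
    def Z(self) -> np.ndarray:
        return self.covariates.to_numpy(dtype=float)


@dataclass
class EffectResult:
    """One covariate-adjusted linear fit: coefficient of the predictor of
    interest, its standard error, t statistic and two-sided p."""

    beta: float
    se: float
    t: float
    p: float
    n_used: int
    gamma: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class EffectMap:
    """Per-ROI significance map for one predictor: ``values[j]`` is
    -log10(p) for the predictor's coefficient in ROI ``j``'s regression."""

    predictor_id: str
    roi_ids: np.ndarray
    values: np.ndarray
    signs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.roi_ids = _as_str_array(self.roi_ids, "ROI IDs")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.roi_ids),):
            raise AlignmentError("map values do not align with ROI IDs")
        if (self.values < 0).any():
            raise ValidationError("-log10(p) map values must be non-negative")
        if self.signs is not None:
            self.signs = np.asarray(self.signs)
            if self.signs.shape != self.values.shape:
                raise AlignmentError("sign vector does not align with map values")

    def to_frame(self) -> pd.DataFrame:
        d = {"roi_id": self.roi_ids, "neglog10_p": self.values}
        if self.signs is not None:
            d["sign"] = self.signs
        return pd.DataFrame(d)


@dataclass
class MapAssociation:
    """Step-3 result for one SNP: correlation of its genetic effect map with
    the diagnostic effect map, with raw and Bonferroni-corrected p."""

    snp_id: str
    contrast: str
    r: float
    p_raw: float
    p_corrected: float
    n_rois_used: int
    significant: bool


@dataclass
class DirectAssociation:
    """A direct SNP-diagnosis association from one of the comparator
    methods (covariate-adjusted GWAS, Pearson, partial correlation)."""

    snp_id: str
    contrast: str
    method: str
    statistic: float
    p_raw: float
    p_corrected: float
    significant: bool
    converged: bool = True
    note: str = ""


def _index_of(haystack: np.ndarray, wanted, what: str) -> np.ndarray:
    """Positions of ``wanted`` IDs inside ``haystack`` (ID join, order of
    ``wanted`` preserved)."""
    lookup = {v: i for i, v in enumerate(haystack)}
    missing = [w for w in wanted if w not in lookup]
    if missing:
        raise AlignmentError(f"{len(missing)} {what} not found (e.g. {missing[:3]})")
    return np.asarray([lookup[w] for w in wanted], dtype=int)
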