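"""Synthetic imaging-genetics cohorts with controllable mediation structure.

The generator emulates the data layout the pipeline consumes — a subjects x
SNPs genotype matrix, a subjects x ROIs imaging-QT table, covariates (age,
sex, education) and a diagnostic label — with a known causal structure:

* genotypes are drawn independently per SNP from Hardy-Weinberg proportions
  at a stated minor-allele frequency, with optional missingness;
* each QT is a baseline plus additive per-allele shifts for planted
  (SNP, ROI) pairs, covariate effects, and unit-variance Gaussian noise, so
  effect sizes are in noise-SD units;
* diagnosis is assigned by a liability threshold: a weighted sum of the
  subject's QTs plus Gaussian liability noise, thresholded at the
  ``case_fraction`` sample quantile.  There is *no* direct SNP -> diagnosis
  edge: any marginal SNP-diagnosis association flows through the QT channel,
  making "endophenotype" literal;
* after diagnosis is assigned, cases additionally receive a QT shift on a
  designated affected-ROI set (the disease's own imaging signature).

Multi-class disease stages are emulated by splitting cases into tiers of
increasing liability with increasing QT shifts, mirroring a
CN / early-MCI / late-MCI / AD progression against a single control group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .datatypes import MISSING, Contrast, GenotypeMatrix, QTMatrix

CONTROL_LABEL = "CN"

#: realistic covariate ranges for a late-life memory-clinic cohort
AGE_RANGE = (60.0, 90.0)
EDUCATION_RANGE = (12.0, 20.0)


@dataclass
class SimulationConfig:
    """Study-condition knobs for one synthetic cohort.

    Effect sizes are expressed in units of the per-ROI noise SD (1.0), so
    ``snp_effect_size=0.8`` means each minor allele shifts the affected QTs
    by 0.8 noise SDs.  ``dx_effect_sizes`` may hold one entry per case class
    (increasing severity); a scalar ``dx_effect_size`` is accepted as a
    single-class shorthand.
    """

    n_subjects: int = 600
    n_rois: int = 116
    n_snps: int = 54
    maf_range: tuple[float, float] = (0.05, 0.5)
    mafs: np.ndarray | None = None  # explicit per-SNP MAFs override maf_range
    causal_snp_indices: tuple[int, ...] = ()
    causal_roi_indices: tuple[int, ...] = ()
    snp_effect_size: float = 0.0
    affected_roi_indices: tuple[int, ...] = ()
    dx_effect_sizes: tuple[float, ...] = (0.0,)
    case_labels: tuple[str, ...] = ("AD",)
    covariate_effects: tuple[float, float, float] = (0.0, 0.0, 0.0)
    liability_weights: np.ndarray | None = None  # default: uniform on causal ROIs
    liability_noise_sd: float = 1.0
    case_fraction: float = 0.45
    missing_genotype_rate: float = 0.0
    qt_baseline: float = 1.2  # SUVR-like offset; no effect on any inference
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_rois < 3 or self.n_snps < 1:
            raise ValidationError("need n_subjects >= 1, n_rois >= 3, n_snps >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValidationError("case_fraction must be strictly between 0 and 1")
        if not 0.0 <= self.missing_genotype_rate < 1.0:
            raise ValidationError("missing_genotype_rate must be in [0, 1)")
        for name, idx, bound in (
            ("causal_snp_indices", self.causal_snp_indices, self.n_snps),
            ("causal_roi_indices", self.causal_roi_indices, self.n_rois),
            ("affected_roi_indices", self.affected_roi_indices, self.n_rois),
        ):
            if any(i < 0 or i >= bound for i in idx):
                raise ValidationError(f"{name} out of bounds [0, {bound})")
        if len(self.dx_effect_sizes) != len(self.case_labels):
            raise ValidationError("dx_effect_sizes and case_labels lengths differ")
        if self.mafs is not None:
            self.mafs = np.asarray(self.mafs, dtype=float)
            if self.mafs.shape != (self.n_snps,):
                raise ValidationError("mafs must have one entry per SNP")
        if self.liability_weights is not None:
            self.liability_weights = np.asarray(self.liability_weights, dtype=float)
            if self.liability_weights.shape != (self.n_rois,):
                raise ValidationError("liability_weights must have one entry per ROI")


@dataclass
class Truth:
    """Record of the planted causal structure of a synthetic cohort."""

    causal_snp_ids: list[str]
    causal_roi_ids: list[str]
    affected_roi_ids: list[str]
    snp_effect_size: float
    dx_effect_sizes: list[float]
    liability_weights: list[float]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


@dataclass
class SyntheticCohort:
    """A complete simulated study: genotypes, QTs, covariates, diagnosis."""

    genotypes: GenotypeMatrix
    qts: QTMatrix
    diagnosis: pd.Series  # subject-indexed labels over {CN, case classes}
    covariates: pd.DataFrame  # subject-indexed age / sex / education
    truth: Truth

    @property
    def subject_ids(self) -> np.ndarray:
        return self.qts.subject_ids

    def contrast(self, case_label: str, control_label: str = CONTROL_LABEL,
                 name: str | None = None) -> Contrast:
        """Build the case/control contrast for one disease stage."""
        labels = self.diagnosis
        mask = labels.isin([case_label, control_label])
        if not mask.any() or labels[mask].nunique() < 2:
            raise ValidationError(
                f"labels {control_label!r}/{case_label!r} do not define a two-class contrast"
            )
        ids = labels.index[mask].to_numpy(dtype=object)
        x = (labels[mask] == case_label).to_numpy(dtype=float)
        return Contrast(
            name=name or f"{control_label}-vs-{case_label}",
            subject_ids=ids,
            x=x,
            covariates=self.covariates.loc[ids],
        )


def simulate_genotypes(
    n_subjects: int,
    mafs: np.ndarray,
    missing_rate: float = 0.0,
    seed: int = 0,
    snp_ids: np.ndarray | None = None,
    subject_ids: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Independent Hardy-Weinberg genotypes at the given minor-allele
    frequencies; each entry counts minor alleles, missing entries flagged."""
    mafs = np.atleast_1d(np.asarray(mafs, dtype=float))
    if ((mafs <= 0.0) | (mafs > 0.5)).any():
        raise ValidationError("each MAF must lie in (0, 0.5]")
    if not 0.0 <= missing_rate < 1.0:
        raise ValidationError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    # two independent allele draws per subject = HWE proportions (q^2, 2pq, p^2)
    g = rng.binomial(2, mafs[None, :], size=(n_subjects, len(mafs))).astype(np.int8)
    if missing_rate > 0:
        g[rng.random(g.shape) < missing_rate] = MISSING
    if snp_ids is None:
        snp_ids = np.asarray([f"snp{j:04d}" for j in range(len(mafs))], dtype=object)
    if subject_ids is None:
        subject_ids = np.asarray([f"S{i:05d}" for i in range(n_subjects)], dtype=object)
    return GenotypeMatrix(g, subject_ids, snp_ids)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full cohort under ``config``; bit-reproducible given the seed.

    The master seed is split into independent streams (genotypes, MAFs,
    covariates, QT noise, liability noise, missingness) so each component is
    reproducible on its own.
    """
    c = config
    streams = np.random.SeedSequence(c.seed).spawn(6)
    rng_maf, rng_cov, rng_noise, rng_liab = (np.random.default_rng(s) for s in streams[:4])

    mafs = c.mafs if c.mafs is not None else rng_maf.uniform(*c.maf_range, size=c.n_snps)
    geno = simulate_genotypes(
        c.n_subjects, mafs, c.missing_genotype_rate,
        seed=streams[4], snp_ids=None, subject_ids=None,
    )
    subject_ids = geno.subject_ids
    roi_ids = np.asarray([f"roi{j:03d}" for j in range(c.n_rois)], dtype=object)

    age = rng_cov.uniform(*AGE_RANGE, size=c.n_subjects)
    sex = rng_cov.integers(0, 2, size=c.n_subjects).astype(float)
    edu = rng_cov.uniform(*EDUCATION_RANGE, size=c.n_subjects)
    cov = pd.DataFrame({"age": age, "sex": sex, "education": edu}, index=subject_ids)

    qt = c.qt_baseline + rng_noise.standard_normal((c.n_subjects, c.n_rois))
    a_cov = np.asarray(c.covariate_effects, dtype=float)
    qt += (cov.to_numpy() @ a_cov)[:, None]
    if c.causal_snp_indices and c.causal_roi_indices and c.snp_effect_size != 0.0:
        # additive per-allele shift; missing genotypes contribute no shift
        gvals = geno.values[:, list(c.causal_snp_indices)].astype(float)
        gvals[gvals == MISSING] = 0.0
        burden = gvals.sum(axis=1)
        qt[:, list(c.causal_roi_indices)] += c.snp_effect_size * burden[:, None]

    # liability threshold on the pre-disease-effect QTs (mediation channel)
    if c.liability_weights is not None:
        w = c.liability_weights
    else:
        w = np.zeros(c.n_rois)
        roi_set = c.causal_roi_indices or c.affected_roi_indices
        if roi_set:
            w[list(roi_set)] = 1.0 / len(roi_set)
    liability = qt @ w + c.liability_noise_sd * rng_liab.standard_normal(c.n_subjects)
    cut = np.quantile(liability, 1.0 - c.case_fraction)
    is_case = liability > cut

    labels = np.full(c.n_subjects, CONTROL_LABEL, dtype=object)
    case_idx = np.flatnonzero(is_case)
    if len(case_idx):
        # split cases into severity tiers by liability rank (most severe = last label)
        order = case_idx[np.argsort(liability[case_idx])]
        tiers = np.array_split(order, len(c.case_labels))
        for tier, label, dx_eff in zip(tiers, c.case_labels, c.dx_effect_sizes):
            labels[tier] = label
            if c.affected_roi_indices and dx_eff != 0.0:
                qt[np.ix_(tier, list(c.affected_roi_indices))] += dx_eff

    truth = Truth(
        causal_snp_ids=[str(geno.snp_ids[i]) for i in c.causal_snp_indices],
        causal_roi_ids=[str(roi_ids[i]) for i in c.causal_roi_indices],
        affected_roi_ids=[str(roi_ids[i]) for i in c.affected_roi_indices],
        snp_effect_size=c.snp_effect_size,
        dx_effect_sizes=list(c.dx_effect_sizes),
        liability_weights=w.tolist(),
    )
    return SyntheticCohort(
        genotypes=geno,
        qts=QTMatrix(qt, subject_ids, roi_ids),
        diagnosis=pd.Series(labels, index=subject_ids, name="diagnosis"),
        covariates=cov,
        truth=truth,
    )


def null_config(seed: int = 0, n_subjects: int = 600, n_rois: int = 116,
                n_snps: int = 54, **overrides) -> SimulationConfig:
    """All-null study conditions: no SNP, diagnosis or covariate effects and
    zero liability weights, so every association test is under its null."""
    kw = dict(
        n_subjects=n_subjects, n_rois=n_rois, n_snps=n_snps,
        snp_effect_size=0.0, dx_effect_sizes=(0.0,),
        liability_weights=np.zeros(n_rois), seed=seed,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


def power_config(seed: int = 0, n_subjects: int = 600, n_rois: int = 116,
                 n_snps: int = 54, n_causal_snps: int = 2, **overrides) -> SimulationConfig:
    """Reference mediation conditions used throughout the test-bench.

    The first ``n_causal_snps`` SNPs each shift 30 ROIs by 0.8 noise SDs per
    minor allele; the same 30 ROIs carry the liability weights and a 0.5-SD
    disease effect.  Liability noise SD 4 keeps the *marginal* SNP-diagnosis
    correlation weak (about 0.1 per causal SNP) while the per-ROI genetic
    maps remain strong — the regime in which endophenotype enrichment pays
    off over direct association tests.
    """
    kw = dict(
        n_subjects=n_subjects, n_rois=n_rois, n_snps=n_snps,
        causal_snp_indices=tuple(range(n_causal_snps)),
        causal_roi_indices=tuple(range(min(30, n_rois))),
        snp_effect_size=0.8,
        affected_roi_indices=tuple(range(min(30, n_rois))),
        dx_effect_sizes=(0.5,),
        liability_noise_sd=4.0,
        seed=seed,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


# ---------------------------------------------------------------------------
# writers


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, Path]:
    """Write a cohort as plain-text files: genotypes as VCF and dosage TSV,
    QTs / covariates / diagnosis as subject-keyed TSVs, truth as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "dosage": outdir / "genotypes.tsv",
        "qts": outdir / "qts.tsv",
        "covariates": outdir / "covariates.tsv",
        "diagnosis": outdir / "diagnosis.tsv",
        "truth": outdir / "truth.json",
    }
    write_vcf(cohort.genotypes, paths["vcf"])
    _write_keyed(cohort.genotypes.to_frame().replace(MISSING, "NA"), paths["dosage"])
    _write_keyed(cohort.qts.to_frame(), paths["qts"])
    _write_keyed(cohort.covariates, paths["covariates"])
    _write_keyed(cohort.diagnosis.to_frame(), paths["diagnosis"])
    cohort.truth.to_json(paths["truth"])
    return paths


def _write_keyed(df: pd.DataFrame, path) -> None:
    df.rename_axis("subject_id").to_csv(path, sep="\t", float_format="%.10g")


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Minimal VCF 4.2 writer: one pseudo-contig, biallelic records, GT only.

    The minor allele is written as ALT, so additive ALT dosage equals the
    package's minor-allele coding.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=sim1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, genotypes.subject_ids)) + "\n")
        for j, snp in enumerate(genotypes.snp_ids):
            gts = "\t".join(_GT_CODE[int(v)] for v in genotypes.values[:, j])
            fh.write(f"sim1\t{j + 1}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")
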