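"""End-to-end orchestration: load inputs, QC, build contrasts, run Steps
1-3 plus the baselines (and optionally the random-SNP null experiment), and
write all tabular outputs.

All numeric TSV output uses fixed ``%.10g`` formatting so reruns with the
same config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._errors import ValidationError
from .association import diagnosis_effect_map, snp_effect_maps, top_rois
from .baselines import run_baselines
from .datatypes import Contrast, GenotypeMatrix, QTMatrix
from .io import common_subjects, read_covariates, read_diagnosis, read_genotypes, read_qts
from .mapcorr import DEFAULT_ALPHA, associations_frame, correlate_maps
from .nullexp import compare_to_reference, run_null_experiment
from .qc import QCThresholds, apply_qc

log = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """File paths and options for one pipeline run.

    ``contrasts`` maps a contrast name to a (control_label, case_label)
    pair; labels must occur in the diagnosis file.
    """

    genotypes: str
    qts: str
    covariates: str
    diagnosis: str
    outdir: str
    contrasts: dict[str, tuple[str, str]] = field(default_factory=dict)
    genotype_format: str | None = None
    qc_thresholds: QCThresholds = field(default_factory=QCThresholds)
    alpha: float = DEFAULT_ALPHA
    family_size: int | None = None  # default: #SNP maps per contrast
    gwas_model: str = "logistic"
    seed: int = 0
    run_baselines: bool = True
    null_experiment: dict | None = None  # {"pool": path, "set_size": int, "n_sets": int}

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a JSON or YAML config file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        qc = raw.pop("qc_thresholds", None)
        if qc is not None:
            raw["qc_thresholds"] = QCThresholds(**qc)
        raw["contrasts"] = {k: tuple(v) for k, v in raw.get("contrasts", {}).items()}
        return cls(**raw)

    def validate(self) -> None:
        if not self.contrasts:
            raise ValidationError("config defines zero contrasts")
        for p in (self.genotypes, self.qts, self.covariates, self.diagnosis):
            if not Path(p).exists():
                raise ValidationError(f"input file not found: {p}")


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def build_contrasts(
    diagnosis: pd.Series, covariates: pd.DataFrame, contrasts: dict[str, tuple[str, str]]
) -> list[Contrast]:
    out = []
    for name, (control, case) in contrasts.items():
        labels = set(diagnosis.unique())
        for lab in (control, case):
            if lab not in labels:
                raise ValidationError(f"contrast {name!r}: label {lab!r} not in diagnosis file")
        mask = diagnosis.isin([control, case])
        ids = diagnosis.index[mask].to_numpy(dtype=object)
        out.append(
            Contrast(
                name=name,
                subject_ids=ids,
                x=(diagnosis[mask] == case).to_numpy(dtype=float),
                covariates=covariates.loc[ids],
            )
        )
    return out


def run_contrast(
    qts: QTMatrix,
    genotypes: GenotypeMatrix,
    contrast: Contrast,
    alpha: float = DEFAULT_ALPHA,
    family_size: int | None = None,
    gwas_model: str = "logistic",
    with_baselines: bool = True,
) -> dict:
    """Steps 1-3 (and baselines) for one contrast; returns a result bundle."""
    dx_map = diagnosis_effect_map(qts, contrast)
    step2 = snp_effect_maps(qts, genotypes, contrast)
    assocs = correlate_maps(dx_map, step2.maps, alpha=alpha, family_size=family_size)
    bundle = {
        "contrast": contrast,
        "dx_map": dx_map,
        "snp_maps": step2,
        "map_associations": assocs,
        "n_significant": sum(a.significant for a in assocs),
    }
    if with_baselines:
        fam = family_size if family_size is not None else len(step2.maps)
        bundle["baselines"] = run_baselines(
            genotypes, contrast, alpha=alpha, family_size=fam, gwas_model=gwas_model
        )
    return bundle


def run_pipeline(config: RunConfig) -> dict:
    """Full run from files per ``config``; writes per-contrast TSVs and a
    summary JSON into ``config.outdir`` and returns the result bundles."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("endomap %s | seed=%d | config=%s", __version__, config.seed, config)

    genotypes = read_genotypes(config.genotypes, config.genotype_format)
    qts = read_qts(config.qts)
    covariates = read_covariates(config.covariates)
    diagnosis = read_diagnosis(config.diagnosis)

    ids = common_subjects(
        qts.subject_ids, genotypes.subject_ids, covariates.index, diagnosis.index
    )
    log.info("%d subjects common to all inputs", len(ids))
    genotypes = genotypes.subset_subjects(ids)
    qts = qts.subset_subjects(ids)
    covariates = covariates.loc[ids]
    diagnosis = diagnosis.loc[ids]

    genotypes, qc_report = apply_qc(genotypes, config.qc_thresholds)
    qc_report.to_tsv(outdir / "qc_report.tsv")

    results = {"qc": qc_report, "contrasts": {}}
    summary = {
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "n_subjects": int(len(ids)),
        "n_snps_post_qc": int(genotypes.n_snps),
        "contrasts": {},
    }
    for contrast in build_contrasts(diagnosis, covariates, config.contrasts):
        tag = contrast.name.replace(" ", "_")
        bundle = run_contrast(
            qts, genotypes, contrast,
            alpha=config.alpha, family_size=config.family_size,
            gwas_model=config.gwas_model, with_baselines=config.run_baselines,
        )
        _write(bundle["dx_map"].to_frame(), outdir / f"{tag}.dx_map.tsv")
        _write(top_rois(bundle["dx_map"]), outdir / f"{tag}.top_rois.tsv")
        _write(bundle["snp_maps"].p_table(), outdir / f"{tag}.snp_roi_p.tsv")
        _write(associations_frame(bundle["map_associations"]),
               outdir / f"{tag}.map_associations.tsv")
        if config.run_baselines:
            _write(bundle["baselines"], outdir / f"{tag}.baselines.tsv")
        results["contrasts"][contrast.name] = bundle
        summary["contrasts"][contrast.name] = {
            "n_cases": contrast.n_cases,
            "n_controls": contrast.n_subjects - contrast.n_cases,
            "n_snp_maps": len(bundle["snp_maps"].maps),
            "n_fits": bundle["snp_maps"].n_fits,
            "n_significant": bundle["n_significant"],
            "significant_snps": [
                a.snp_id for a in bundle["map_associations"] if a.significant
            ],
        }
        log.info("contrast %s: %d/%d SNPs significant at corrected alpha %.3g",
                 contrast.name, bundle["n_significant"],
                 len(bundle["snp_maps"].maps), config.alpha)

    if config.null_experiment:
        ne = dict(config.null_experiment)
        pool = read_genotypes(ne["pool"], ne.get("format"))
        pool = pool.subset_subjects(ids)
        pool, _ = apply_qc(pool, config.qc_thresholds)
        contrast = build_contrasts(diagnosis, covariates, config.contrasts)[0]
        result = run_null_experiment(
            qts, pool, contrast,
            set_size=ne.get("set_size", genotypes.n_snps),
            n_sets=ne.get("n_sets", 1000),
            seed=config.seed, alpha=config.alpha,
        )
        ref = summary["contrasts"][contrast.name]["n_significant"]
        pct = compare_to_reference(result, ref)
        result.histogram().to_csv(outdir / "null_histogram.tsv", sep="\t", index=False)
        result.plot(outdir / "null_histogram.png")
        results["null_experiment"] = result
        summary["null_experiment"] = {
            "n_sets": result.n_sets,
            "set_size": result.set_size,
            "reference_count": ref,
            "percentile_outperformed": pct,
        }

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return results
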