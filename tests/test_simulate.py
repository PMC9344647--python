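"""Synthetic cohort generator: HWE marginals, mediation structure, determinism."""

import numpy as np
import pytest
from scipy import stats

from endomap import (
    SimulationConfig,
    ValidationError,
    hwe_exact_test,
    simulate_cohort,
    simulate_genotypes,
)
from endomap.datatypes import MISSING
from endomap.simulate import null_config, power_config


class TestSimulateGenotypes:
    def test_zero_maf_rejected(self):
        with pytest.raises(ValidationError):
            simulate_genotypes(10, [0.0])
        with pytest.raises(ValidationError):
            simulate_genotypes(10, [0.6])

    def test_empirical_allele_frequency(self):
        gm = simulate_genotypes(5000, [0.3], seed=42)
        freq = gm.values.mean() / 2.0
        assert abs(freq - 0.3) < 0.02

    def test_seeded_determinism(self):
        a = simulate_genotypes(200, [0.2, 0.4], missing_rate=0.05, seed=7)
        b = simulate_genotypes(200, [0.2, 0.4], missing_rate=0.05, seed=7)
        assert (a.values == b.values).all()

    def test_missingness_rate(self):
        gm = simulate_genotypes(2000, [0.3] * 5, missing_rate=0.1, seed=3)
        rate = (gm.values == MISSING).mean()
        assert abs(rate - 0.1) < 3 * np.sqrt(0.1 * 0.9 / gm.values.size)

    def test_hwe_holds_at_generation(self):
        """Exact HWE test rejects at its nominal 5% level across replicates."""
        reps, n = 1000, 300
        gm = simulate_genotypes(n, [0.3] * reps, seed=11)
        rejections = 0
        for j in range(reps):
            g = gm.values[:, j]
            p = hwe_exact_test(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))
            rejections += p < 0.05
        sd = np.sqrt(0.05 * 0.95 / reps)
        # the exact test is conservative (discrete), so the rate may fall below
        assert rejections / reps < 0.05 + 3 * sd


class TestSimulationConfig:
    def test_out_of_bounds_indices_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(n_snps=5, causal_snp_indices=(7,))
        with pytest.raises(ValidationError):
            SimulationConfig(n_rois=10, causal_roi_indices=(10,))

    def test_case_fraction_bounds(self):
        with pytest.raises(ValidationError):
            SimulationConfig(case_fraction=0.0)
        with pytest.raises(ValidationError):
            SimulationConfig(case_fraction=1.0)

    def test_maf_range_bounds(self):
        with pytest.raises(ValidationError):
            SimulationConfig(maf_range=(0.0, 0.4))


class TestSimulateCohort:
    def test_seeded_determinism_bit_for_bit(self):
        cfg = power_config(seed=99, n_subjects=150, n_rois=20, n_snps=8)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert (a.genotypes.values == b.genotypes.values).all()
        assert (a.qts.values == b.qts.values).all()
        assert (a.diagnosis == b.diagnosis).all()
        assert (a.covariates == b.covariates).all().all()

    def test_case_count_matches_fraction(self):
        coh = simulate_cohort(null_config(seed=5, n_subjects=1000, n_rois=10,
                                          n_snps=4, case_fraction=0.5))
        n_cases = int((coh.diagnosis != "CN").sum())
        assert abs(n_cases - 500) <= 3 * np.sqrt(1000 * 0.25)

    def test_truth_record_matches_config(self):
        cfg = power_config(seed=1, n_subjects=100, n_rois=40, n_snps=10)
        coh = simulate_cohort(cfg)
        assert coh.truth.causal_snp_ids == [
            str(coh.genotypes.snp_ids[i]) for i in cfg.causal_snp_indices
        ]
        assert len(coh.truth.causal_roi_ids) == len(cfg.causal_roi_indices)
        assert coh.truth.snp_effect_size == cfg.snp_effect_size

    def test_planted_snp_shifts_causal_rois(self):
        """Regressing a causal ROI's QT on the causal genotype recovers the
        planted per-allele effect."""
        from endomap import fit_linear_effect

        coh = simulate_cohort(power_config(seed=13, n_subjects=2000,
                                           dx_effect_sizes=(0.0,)))
        g = coh.genotypes.values[:, 0].astype(float)
        res = fit_linear_effect(coh.qts.values[:, 0], g)
        assert res.beta == pytest.approx(0.8, abs=0.15)

    def test_multiclass_tiers_follow_severity(self):
        cfg = power_config(seed=3, n_subjects=900,
                           dx_effect_sizes=(0.2, 0.5, 1.0),
                           case_labels=("EMCI", "LMCI", "AD"))
        coh = simulate_cohort(cfg)
        labels = set(coh.diagnosis.unique())
        assert labels == {"CN", "EMCI", "LMCI", "AD"}
        rois = [list(coh.qts.roi_ids).index(r) for r in coh.truth.affected_roi_ids]
        means = [
            coh.qts.values[np.ix_((coh.diagnosis == lab).to_numpy(), rois)].mean()
            for lab in ("CN", "EMCI", "LMCI", "AD")
        ]
        assert means == sorted(means)

    def test_mediation_only_through_qts(self):
        """With snp_effect_size = 0 there is no SNP-diagnosis channel at
        all: the marginal chi-square association test is calibrated."""
        reps = 300
        rejections = 0
        for i in range(reps):
            coh = simulate_cohort(power_config(seed=40_000 + i, n_subjects=200,
                                               n_rois=10, n_snps=1, n_causal_snps=1,
                                               maf_range=(0.3, 0.5),
                                               causal_roi_indices=tuple(range(10)),
                                               affected_roi_indices=tuple(range(10)),
                                               snp_effect_size=0.0))
            g = coh.genotypes.values[:, 0]
            case = (coh.diagnosis != "CN").to_numpy()
            table = np.array([
                [(g[case] == k).sum() for k in (0, 1, 2)],
                [(g[~case] == k).sum() for k in (0, 1, 2)],
            ])
            table = table[:, table.sum(axis=0) > 0]
            p = stats.chi2_contingency(table).pvalue
            rejections += p < 0.05
        sd = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rejections / reps - 0.05) < 3 * sd

    def test_mediation_present_with_planted_effect(self):
        """With the planted channel on, the SNP-diagnosis marginal
        association is real (flows through the QTs)."""
        coh = simulate_cohort(power_config(seed=17, n_subjects=3000,
                                           liability_noise_sd=1.0))
        g = coh.genotypes.values[:, 0].astype(float)
        case = (coh.diagnosis != "CN").to_numpy().astype(float)
        assert stats.pearsonr(g, case).pvalue < 1e-6
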