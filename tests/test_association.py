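"""Steps 1-2: covariate-adjusted OLS association and significance maps."""

import numpy as np
import pytest

from endomap import (
    Contrast,
    DegenerateDesignError,
    QTMatrix,
    ValidationError,
    diagnosis_effect_map,
    fit_linear_effect,
    neglog10,
    snp_effect_maps,
    top_rois,
)
from endomap.association import P_FLOOR
from endomap.datatypes import MISSING, GenotypeMatrix

from oracles import ols_closed_form

TOY_Y = np.array([1.0, 2.1, 2.9, 4.2, 4.8, 6.1])
TOY_X = np.arange(6.0)
# frozen from the normal-equations + t-CDF oracle on the toy input above
TOY_BETA = 0.9971428571428573
TOY_SE = 0.03931384274390542
TOY_P = 1.434882936034274e-05


class TestFitLinearEffect:
    def test_matches_closed_form_on_toy_input(self):
        res = fit_linear_effect(TOY_Y, TOY_X)
        assert res.beta == pytest.approx(TOY_BETA, abs=1e-10)
        assert res.se == pytest.approx(TOY_SE, abs=1e-10)
        assert res.p == pytest.approx(TOY_P, abs=1e-10)
        assert res.n_used == 6

    def test_matches_oracle_on_random_designs(self, rng):
        """100 random small designs (n <= 30, k <= 3 covariates) agree with
        the explicit normal-equations oracle to 1e-8 in beta, se and p."""
        for _ in range(100):
            n = int(rng.integers(8, 31))
            k = int(rng.integers(0, 4))
            x = rng.standard_normal(n)
            Z = rng.standard_normal((n, k)) if k else None
            y = rng.standard_normal(n) + 0.5 * x
            res = fit_linear_effect(y, x, Z)
            X = np.column_stack([np.ones(n), x] + ([Z] if k else []))
            beta, se, _, p = ols_closed_form(y, X)
            assert res.beta == pytest.approx(beta, abs=1e-8)
            assert res.se == pytest.approx(se, abs=1e-8)
            assert res.p == pytest.approx(p, abs=1e-8)

    def test_exact_fit_hits_underflow_floor(self):
        res = fit_linear_effect(TOY_X.copy(), TOY_X)
        assert res.beta == pytest.approx(1.0, abs=1e-12)
        assert res.p == P_FLOOR
        assert neglog10(res.p) == 300.0

    def test_constant_predictor_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_linear_effect(TOY_Y, np.ones(6))

    def test_collinear_covariates_named(self):
        x = np.arange(10.0)
        Z = np.column_stack([x, 2 * x])  # each collinear with predictor
        with pytest.raises(DegenerateDesignError, match="collinear"):
            fit_linear_effect(np.arange(10.0) ** 2, x, Z)

    def test_missing_values_dropped_pairwise(self, rng):
        y = rng.standard_normal(50)
        x = rng.standard_normal(50)
        y_m, x_m = y.copy(), x.copy()
        y_m[3] = np.nan
        x_m[7] = MISSING
        res = fit_linear_effect(y_m, x_m)
        keep = np.ones(50, bool)
        keep[[3, 7]] = False
        ref = fit_linear_effect(y[keep], x[keep])
        assert res.n_used == 48
        assert res.beta == pytest.approx(ref.beta, abs=1e-12)

    def test_covariate_shift_invariance(self, rng):
        """Adding a constant to a covariate changes neither beta nor p."""
        n = 60
        x = rng.standard_normal(n)
        Z = rng.standard_normal((n, 2))
        y = 0.4 * x + Z @ [0.3, -0.2] + rng.standard_normal(n)
        a = fit_linear_effect(y, x, Z)
        b = fit_linear_effect(y, x, Z + np.array([17.0, -3.5]))
        assert a.beta == pytest.approx(b.beta, abs=1e-10)
        assert a.p == pytest.approx(b.p, rel=1e-8)

    def test_frisch_waugh(self, rng):
        """Predictor coefficient equals the slope of residualised y on
        residualised predictor."""
        n = 80
        x = rng.standard_normal(n)
        Z = rng.standard_normal((n, 3))
        y = 0.7 * x + Z @ [1.0, -1.0, 0.5] + rng.standard_normal(n)
        res = fit_linear_effect(y, x, Z)
        C = np.column_stack([np.ones(n), Z])
        Q, _ = np.linalg.qr(C)
        ry = y - Q @ (Q.T @ y)
        rx = x - Q @ (Q.T @ x)
        assert res.beta == pytest.approx((rx @ ry) / (rx @ rx), abs=1e-10)

    def test_type_one_error_calibrated(self, rng):
        """Independent permuted predictor: p uniform, 5% rejection rate."""
        n, reps = 500, 1000
        y = rng.standard_normal(n)
        rejections = 0
        for _ in range(reps):
            x = rng.permutation(n).astype(float)
            rejections += fit_linear_effect(y, x).p < 0.05
        sd = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rejections / reps - 0.05) < 3 * sd


class TestNeglog10:
    @pytest.mark.parametrize("p, expected", [(0.01, 2.0), (1.0, 0.0), (1e-320, 300.0)])
    def test_values(self, p, expected):
        assert neglog10(p) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValidationError):
            neglog10(bad)


def _toy_contrast(rng, n=120, k_cov=3, name="CN-vs-AD"):
    import pandas as pd

    ids = np.array([f"s{i}" for i in range(n)], dtype=object)
    x = np.zeros(n)
    x[: n // 2] = 1.0
    cov = pd.DataFrame(rng.standard_normal((n, k_cov)),
                       columns=["age", "sex", "education"])
    return Contrast(name=name, subject_ids=ids, x=x, covariates=cov)


class TestDiagnosisEffectMap:
    def test_identical_qt_columns_give_identical_map_entries(self, rng):
        con = _toy_contrast(rng)
        col = rng.standard_normal(120)
        qts = QTMatrix(np.tile(col[:, None], (1, 5)), con.subject_ids,
                       [f"r{j}" for j in range(5)])
        m = diagnosis_effect_map(qts, con)
        assert np.allclose(m.values, m.values[0])

    def test_planted_rois_rank_on_top(self):
        """Affected ROIs occupy the top of the map in nearly all replicates."""
        from endomap.simulate import power_config, simulate_cohort

        hits = 0
        reps = 20
        for i in range(reps):
            coh = simulate_cohort(power_config(seed=31_000 + i, n_subjects=400,
                                               dx_effect_sizes=(1.0,)))
            m = diagnosis_effect_map(coh.qts, coh.contrast("AD"))
            top = set(top_rois(m, 30)["roi_id"])
            hits += top == set(coh.truth.affected_roi_ids)
        assert hits >= 0.9 * reps

    def test_null_contrast_stays_below_bonferroni_line(self):
        from endomap.simulate import null_config, simulate_cohort

        exceed = 0
        reps = 40
        bound = -np.log10(0.05 / 116)
        for i in range(reps):
            coh = simulate_cohort(null_config(seed=32_000 + i, n_subjects=250))
            m = diagnosis_effect_map(coh.qts, coh.contrast("AD"))
            exceed += m.values.max() > bound
        assert exceed <= 0.05 * reps + 3 * np.sqrt(reps * 0.05 * 0.95)


class TestSnpEffectMaps:
    def _genotypes(self, rng, con, n_snps=6):
        g = rng.binomial(2, 0.3, size=(con.n_subjects, n_snps)).astype(np.int8)
        return GenotypeMatrix(g, con.subject_ids, [f"v{j}" for j in range(n_snps)])

    def test_fit_count_is_snps_times_rois(self, rng):
        con = _toy_contrast(rng)
        gm = self._genotypes(rng, con)
        qts = QTMatrix(rng.standard_normal((120, 7)), con.subject_ids,
                       [f"r{j}" for j in range(7)])
        res = snp_effect_maps(qts, gm, con)
        assert res.n_fits == 6 * 7
        assert len(res.p_table()) == 6 * 7

    def test_allele_coding_symmetry(self, rng):
        """Recoding g -> 2 - g leaves the significance map unchanged and
        negates the recorded signs."""
        con = _toy_contrast(rng)
        gm = self._genotypes(rng, con, n_snps=1)
        flipped = GenotypeMatrix(2 - gm.values, gm.subject_ids, gm.snp_ids)
        qts = QTMatrix(rng.standard_normal((120, 5)) + 0.3 * gm.values,
                       con.subject_ids, [f"r{j}" for j in range(5)])
        a = snp_effect_maps(qts, gm, con).maps[0]
        b = snp_effect_maps(qts, flipped, con).maps[0]
        assert np.allclose(a.values, b.values, atol=1e-9)
        assert (a.signs == -b.signs).all()

    def test_agrees_with_single_fits(self, rng):
        """The vectorised Frisch-Waugh fast path must reproduce
        fit_linear_effect cell by cell."""
        con = _toy_contrast(rng)
        gm = self._genotypes(rng, con, n_snps=4)
        qts = QTMatrix(rng.standard_normal((120, 5)), con.subject_ids,
                       [f"r{j}" for j in range(5)])
        res = snp_effect_maps(qts, gm, con)
        table = res.p_table()
        for _, row in table.sample(8, random_state=0).iterrows():
            single = fit_linear_effect(
                qts.values[:, list(qts.roi_ids).index(row["roi_id"])],
                gm.column(row["snp_id"]).astype(float),
                con.Z,
            )
            assert row["beta"] == pytest.approx(single.beta, abs=1e-9)
            assert row["p"] == pytest.approx(single.p, rel=1e-6, abs=1e-12)

    def test_missing_genotypes_use_complete_cases(self, rng):
        con = _toy_contrast(rng)
        g = rng.binomial(2, 0.4, size=(120, 1)).astype(np.int8)
        g[::10] = MISSING
        gm = GenotypeMatrix(g, con.subject_ids, ["v0"])
        qts = QTMatrix(rng.standard_normal((120, 4)), con.subject_ids,
                       [f"r{j}" for j in range(4)])
        res = snp_effect_maps(qts, gm, con)
        single = fit_linear_effect(qts.values[:, 0], g[:, 0].astype(float), con.Z)
        assert res.maps[0].values[0] == pytest.approx(-np.log10(single.p), rel=1e-9)

    def test_constant_snp_excluded_with_warning(self, rng, caplog):
        con = _toy_contrast(rng)
        g = np.column_stack([
            np.ones(120, dtype=np.int8),
            rng.binomial(2, 0.3, 120).astype(np.int8),
        ])
        gm = GenotypeMatrix(g, con.subject_ids, ["const", "ok"])
        qts = QTMatrix(rng.standard_normal((120, 4)), con.subject_ids,
                       [f"r{j}" for j in range(4)])
        with caplog.at_level("WARNING"):
            res = snp_effect_maps(qts, gm, con)
        assert res.excluded == ["const"]
        assert [m.predictor_id for m in res.maps] == ["ok"]
        assert "const" in caplog.text

    def test_maps_are_deterministic(self, power_cohort):
        con = power_cohort.contrast("AD")
        a = snp_effect_maps(power_cohort.qts, power_cohort.genotypes, con)
        b = snp_effect_maps(power_cohort.qts, power_cohort.genotypes, con)
        for ma, mb in zip(a.maps, b.maps):
            assert (ma.values == mb.values).all()
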