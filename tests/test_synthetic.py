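"""Synthetic population generator and surrogate prediction equations."""
import numpy as np
import pytest

from mirqc import (
    ContaminationFractions,
    SyntheticConfig,
    SyntheticGenerator,
    TraitSpec,
    build_prediction_equation,
    generate_calibration_set,
    rmsd,
    simulate_internal_prediction,
)
from mirqc.errors import ConfigurationError, FitError

FAT_ONLY = (TraitSpec("fat", 3.93, 1.10),)
FAT_PROTEIN = (TraitSpec("fat", 3.93, 1.10), TraitSpec("protein", 3.41, 0.42))


def noiseless_config(**kw):
    defaults = dict(
        n_wavelengths=120,
        n_latent=6,
        calib_size=300,
        field_size=200,
        traits=FAT_PROTEIN,
        contamination=ContaminationFractions(1.0, 0.0, 0.0, 0.0),
        spectral_noise_sd=0.0,
        trait_noise_sd=0.0,
        instrument_noise_sd=0.0,
        nonlinear_coef=0.0,
        equation_components=6,
        seed=11,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestConfigValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            ContaminationFractions(0.9, 0.2, 0.0, 0.0)

    def test_fractions_must_be_probabilities(self):
        with pytest.raises(ConfigurationError):
            ContaminationFractions(1.5, -0.5, 0.0, 0.0)

    def test_counts_positive(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(calib_size=0)

    def test_noise_nonnegative(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(spectral_noise_sd=-1e-3)

    def test_latent_space_must_exceed_traits(self):
        cfg = SyntheticConfig(n_latent=5, traits=SyntheticConfig().traits)
        with pytest.raises(ConfigurationError):
            SyntheticGenerator(cfg)


class TestCalibrationSet:
    def test_zero_variance_case_returns_mean_curve(self):
        cfg = noiseless_config(loading_scale=0.0, n_latent=1, traits=FAT_ONLY)
        gen = SyntheticGenerator(cfg)
        spectra, _ = gen.calibration_set("fat")
        np.testing.assert_allclose(
            spectra.absorbance, np.tile(gen.mean_curve, (cfg.calib_size, 1))
        )

    def test_determinism_bit_identical(self):
        cfg = SyntheticConfig(seed=42, calib_size=100, field_size=50,
                              n_wavelengths=150, traits=FAT_PROTEIN)
        s1, v1 = generate_calibration_set(cfg, "fat")
        s2, v2 = generate_calibration_set(cfg, "fat")
        np.testing.assert_array_equal(s1.absorbance, s2.absorbance)
        np.testing.assert_array_equal(v1, v2)

    def test_sample_moments_match_configuration(self):
        cfg = SyntheticConfig(
            seed=5, calib_size=2000, n_wavelengths=150,
            traits=(TraitSpec("fat", 3.93, 1.00),),
        )
        _, values = generate_calibration_set(cfg, "fat")
        n = len(values)
        se_mean = 1.00 / np.sqrt(n)
        assert abs(values.mean() - 3.93) < 3 * se_mean
        se_sd = 1.00 / np.sqrt(2 * (n - 1))
        assert abs(values.std(ddof=1) - np.sqrt(1.0 + cfg.trait_noise_sd**2)) < 3 * se_sd


class TestPredictionEquation:
    def test_noiseless_trait_recovered_exactly(self):
        cfg = noiseless_config()
        gen = SyntheticGenerator(cfg)
        calset, values = gen.calibration_set("fat")
        eq = build_prediction_equation(calset, values, "fat", cfg.gap, 6)
        assert eq.insample_rmse <= 1e-8
        np.testing.assert_allclose(eq.predict(calset), values, atol=1e-7)

    def test_constant_trait_gives_zero_coefficients(self):
        cfg = noiseless_config(spectral_noise_sd=1e-4)
        gen = SyntheticGenerator(cfg)
        calset, _ = gen.calibration_set("fat")
        eq = build_prediction_equation(
            calset, np.full(calset.n_samples, 4.2), "fat", cfg.gap, 6
        )
        np.testing.assert_allclose(eq.coefficients, 0.0, atol=1e-12)
        assert eq.intercept == pytest.approx(4.2)

    def test_default_conditions_reach_high_r2(self):
        cfg = SyntheticConfig(seed=7, calib_size=1799, traits=FAT_ONLY)
        gen = SyntheticGenerator(cfg)
        calset, values = gen.calibration_set("fat")
        eq = build_prediction_equation(
            calset, values, "fat", cfg.gap, cfg.equation_components
        )
        assert eq.insample_r2 > 0.97

    def test_rank_deficiency_rejected(self):
        cfg = noiseless_config()  # rank = n_latent = 6 < 8 requested
        gen = SyntheticGenerator(cfg)
        calset, values = gen.calibration_set("fat")
        with pytest.raises(FitError):
            build_prediction_equation(calset, values, "fat", cfg.gap, 8)

    def test_too_few_samples_rejected(self):
        cfg = noiseless_config(calib_size=10)
        gen = SyntheticGenerator(cfg)
        calset, values = gen.calibration_set("fat")
        with pytest.raises(FitError):
            build_prediction_equation(calset, values, "fat", cfg.gap, 9)


class TestInternalPrediction:
    def test_identity(self):
        truth = np.array([3.5, 4.2])
        np.testing.assert_array_equal(
            simulate_internal_prediction(truth, 0.0, 1.0, 0.0), truth
        )

    def test_slope_bias_arithmetic(self):
        out = simulate_internal_prediction(np.array([4.00]), 0.0, 1.02, -0.05)
        assert out[0] == pytest.approx(4.00 * 1.02 - 0.05)

    def test_noise_moment_recovery(self):
        truth = np.zeros(10000)
        slope = 1.02
        out = simulate_internal_prediction(truth, 0.05, slope, -0.1, seed=3)
        resid_sd = np.std(out - slope * truth - (-0.1), ddof=1)
        assert abs(resid_sd - 0.05 * slope) < 0.05 * 0.05 * slope

    def test_negative_noise_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_internal_prediction(np.array([1.0]), -0.1)


class TestFieldRecords:
    def test_all_clean_noiseless_ext_equals_int(self):
        cfg = noiseless_config()
        gen = SyntheticGenerator(cfg)
        eqs = gen.build_equations()
        _, table = gen.field_records(eqs)
        assert rmsd(table.ext_values("fat"), table.int_values("fat")) < 1e-8
        assert (table.data["true_class"] == "clean").all()

    def test_degraded_errors_exceed_clean_errors_paired(self):
        base = dict(
            n_wavelengths=200, n_latent=8, calib_size=400, field_size=300,
            traits=FAT_ONLY, seed=21,
        )
        gen_clean = SyntheticGenerator(
            SyntheticConfig(contamination=ContaminationFractions(1, 0, 0, 0), **base)
        )
        eqs = gen_clean.build_equations()
        _, t_clean = gen_clean.field_records(eqs)
        gen_degr = SyntheticGenerator(
            SyntheticConfig(contamination=ContaminationFractions(0, 0, 1, 0), **base)
        )
        _, t_degr = gen_degr.field_records(eqs)
        err_clean = np.abs(t_clean.residuals("fat")).mean()
        err_degr = np.abs(t_degr.residuals("fat")).mean()
        assert err_degr > err_clean

    def test_class_counts_reproducible(self):
        cfg = SyntheticConfig(
            n_wavelengths=150, calib_size=200, field_size=1000,
            traits=FAT_PROTEIN, seed=9,
            contamination=ContaminationFractions(0.9, 0.05, 0.03, 0.02),
        )
        gen = SyntheticGenerator(cfg)
        eqs = gen.build_equations()
        _, t1 = gen.field_records(eqs)
        _, t2 = SyntheticGenerator(cfg).field_records(eqs)
        c1 = t1.data["true_class"].value_counts().to_dict()
        c2 = t2.data["true_class"].value_counts().to_dict()
        assert c1 == c2
        assert sum(c1.values()) == 1000
        assert 0.85 <= c1["clean"] / 1000 <= 0.95

    def test_field_determinism_bit_identical(self):
        cfg = SyntheticConfig(
            n_wavelengths=150, calib_size=200, field_size=300,
            traits=FAT_PROTEIN, seed=33,
        )
        gen = SyntheticGenerator(cfg)
        eqs = gen.build_equations()
        s1, t1 = gen.field_records(eqs)
        s2, t2 = SyntheticGenerator(cfg).field_records(eqs)
        np.testing.assert_array_equal(s1.absorbance, s2.absorbance)
        assert t1.data.equals(t2.data)

    def test_mismatched_records_get_foreign_spectra(self):
        cfg = SyntheticConfig(
            n_wavelengths=150, calib_size=200, field_size=400,
            traits=FAT_ONLY, seed=13,
            contamination=ContaminationFractions(0.5, 0.0, 0.0, 0.5),
        )
        gen = SyntheticGenerator(cfg)
        eqs = gen.build_equations()
        spectra, table = gen.field_records(eqs)
        mism = table.data["true_class"].to_numpy() == "mismatched"
        # internal predictions follow each record's own truth
        np.testing.assert_allclose(
            table.int_values("fat")[mism],
            table.data["TRUE_fat"].to_numpy()[mism],
            atol=5 * cfg.instrument_noise_sd + 1e-9,
        )
        # external predictions follow the swapped spectra, so they disagree
        resid_mism = np.abs(table.residuals("fat")[mism]).mean()
        resid_clean = np.abs(table.residuals("fat")[~mism]).mean()
        assert resid_mism > 5 * resid_clean

    def test_missing_equation_rejected(self):
        cfg = SyntheticConfig(
            n_wavelengths=150, calib_size=200, field_size=100, traits=FAT_PROTEIN,
            seed=2,
        )
        gen = SyntheticGenerator(cfg)
        with pytest.raises(ConfigurationError):
            gen.field_records({})


class TestClassSeparation:
    def test_extrapolated_gh_and_degraded_errors_separate(self, default_study):
        bt = default_study.base_table
        cls = bt.data["true_class"].to_numpy()
        gh = bt.gh_values("fat")
        assert gh[cls == "extrapolated"].mean() > gh[cls == "clean"].mean()
        resid = np.abs(bt.residuals("fat"))
        assert resid[cls == "degraded"].mean() > resid[cls == "clean"].mean()

    def test_field_moment_recovery_large_clean_population(self):
        cfg = SyntheticConfig(
            n_wavelengths=150, n_latent=8, calib_size=200, field_size=12000,
            traits=FAT_PROTEIN, seed=19,
            contamination=ContaminationFractions(1.0, 0.0, 0.0, 0.0),
        )
        gen = SyntheticGenerator(cfg)
        eqs = gen.build_equations()
        _, table = gen.field_records(eqs)
        for spec in cfg.traits:
            truth = table.data[f"TRUE_{spec.name}"].to_numpy()
            n = len(truth)
            assert abs(truth.mean() - spec.mean) < 3 * spec.sd / np.sqrt(n)
            assert abs(truth.std(ddof=1) - spec.sd) < 3 * spec.sd / np.sqrt(2 * (n - 1))
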