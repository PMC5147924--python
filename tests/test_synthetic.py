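"""Tests of the synthetic cohort / dual-sensor data generator."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import noise_free
from wristpaee.config import GeneratorConfig, TruthCoefficients
from wristpaee.models import ModelSpec, fit_mixed_model
from wristpaee.signals import vector_magnitude
from wristpaee.synthetic import (generate_cohort, generate_dataset,
                                 generate_epoch_series, generate_raw_bout,
                                 invert_quadratic)


class TestCohort:
    def test_two_participants_distinct_ids(self):
        cohort = generate_cohort(dataclasses.replace(
            GeneratorConfig(), n_participants=2, seed=5))
        assert len(cohort) == 2
        assert cohort["participant_id"].nunique() == 2

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_participants=0)
        with pytest.raises(ValueError):
            GeneratorConfig(n_participants=-3)

    def test_determinism(self, small_config):
        a = generate_cohort(small_config)
        b = generate_cohort(small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_bmi_identity_and_covariate_ranges(self, small_dataset):
        cohort, _, _ = small_dataset
        np.testing.assert_allclose(
            cohort["bmi"], cohort["weight_kg"] / cohort["height_m"]**2, rtol=1e-12)
        assert (cohort["age"] > 0).all()
        assert cohort["height_m"].between(1.2, 2.2).all()
        assert (cohort["weight_kg"] > 0).all()

    def test_marginals_match_published_cohort(self):
        """n=1050 sample lands on the published summary statistics."""
        cfg = dataclasses.replace(GeneratorConfig(), n_participants=1050, seed=7)
        cohort = generate_cohort(cfg)
        male = cohort["sex"] == "male"
        assert abs(male.mean() - 0.48) < 0.01
        # tolerances: ~3 standard errors of the sample mean
        assert abs(cohort["age"].mean() - 49.9) < 3 * 7.2 / np.sqrt(1050)
        assert abs(cohort["bmi"].mean() - 26.5) < 3 * 4.5 / np.sqrt(1050)
        for sel, target_h, target_w in ((male, 1.78, 85.85), (~male, 1.63, 69.97)):
            assert abs(cohort.loc[sel, "height_m"].mean() - target_h) < 0.1 * target_h
            assert abs(cohort.loc[sel, "weight_kg"].mean() - target_w) < 0.1 * target_w


class TestEpochSeries:
    def test_six_days_gives_1728_epochs(self):
        cfg = dataclasses.replace(GeneratorConfig(), n_participants=2, days=6, seed=1)
        cohort = generate_cohort(cfg)
        epochs, latent = generate_epoch_series(cohort.iloc[0], cfg)
        assert len(epochs) == 6 * 288 == 1728
        assert len(latent) == 1728

    def test_determinism_byte_identical(self, small_config, small_dataset, tmp_path):
        _, epochs, _ = small_dataset
        _, epochs2 = generate_dataset(small_config)
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        epochs.to_csv(a, index=False)
        epochs2.to_csv(b, index=False)
        assert a.read_bytes() == b.read_bytes()

    def test_noise_free_criterion_equals_truth_mapping(self):
        cfg = noise_free(n_participants=4, days=1, seed=3)
        cohort = generate_cohort(cfg)
        epochs, latent = generate_epoch_series(cohort.iloc[1], cfg)
        t = cfg.truth
        np.testing.assert_allclose(
            epochs["paee_jminkg"], t.paee_from_hpfvm(epochs["hpfvm_mg"]), rtol=1e-9)
        np.testing.assert_allclose(
            epochs["paee_jminkg"], t.paee_from_enmo(epochs["enmo_mg"]), rtol=1e-9)
        np.testing.assert_allclose(epochs["paee_jminkg"], latent["true_intensity"],
                                   rtol=1e-12)

    def test_latent_invariants(self, small_dataset):
        _, _, latent = small_dataset
        assert (latent["true_intensity"] >= 0).all()
        assert (latent["wrist_enmo_true"] >= 0).all()
        # the two gravity-removal strategies order consistently
        assert (latent["wrist_hpfvm_true"] >= latent["wrist_enmo_true"]).all()

    def test_marginal_realism(self, small_dataset, small_config):
        _, epochs, latent = small_dataset
        wear = epochs[epochs["wear_wrist"] & epochs["wear_combined"]]
        assert (wear["paee_jminkg"] >= 0).all()
        assert stats.skew(wear["paee_jminkg"]) > 0.5  # right-skewed
        hours = pd.to_datetime(latent["epoch_start"]).dt.hour
        asleep = (hours >= small_config.sleep_start_hour) | \
                 (hours < small_config.sleep_end_hour)
        sleep_mean = latent.loc[asleep, "true_intensity"].mean()
        waking_mean = latent.loc[~asleep, "true_intensity"].mean()
        assert sleep_mean < 0.05 * waking_mean

    def test_cohort_epoch_means_match_published_targets(self):
        """Grand means of PAEE and wrist metrics land in the published bands."""
        cfg = dataclasses.replace(GeneratorConfig(), n_participants=350, seed=11)
        _, epochs = generate_dataset(cfg)
        wear = epochs[epochs["wear_wrist"] & epochs["wear_combined"]]
        assert abs(wear["paee_jminkg"].mean() - 36.4) < 2.0
        assert abs(wear["enmo_mg"].mean() - 31.7) < 3.0

    def test_nonwear_epochs_flagged_and_zeroed(self):
        cfg = dataclasses.replace(GeneratorConfig(), n_participants=20, days=6,
                                  seed=2, nonwear_rate=0.5)
        _, epochs = generate_dataset(cfg)
        off_wrist = ~epochs["wear_wrist"]
        assert off_wrist.any(), "expected some injected wrist non-wear"
        assert (epochs.loc[off_wrist, "enmo_mg"] == 0).all()
        off_comb = ~epochs["wear_combined"]
        assert (epochs.loc[off_comb, "trunk_acc_ms2"] == 0).all()
        assert epochs.loc[off_comb, "paee_jminkg"].isna().all()
        assert not epochs.loc[off_comb, "hr_valid"].any()


class TestTruthMapping:
    def test_invert_quadratic_roundtrip(self):
        t = TruthCoefficients()
        m = np.linspace(0.0, 1300.0, 50)
        np.testing.assert_allclose(
            invert_quadratic(t.paee_from_hpfvm(m), t.beta1_hpfvm, t.beta2_hpfvm),
            m, atol=1e-8)

    def test_truth_vertices_at_published_maxima(self):
        t = TruthCoefficients()
        assert abs(t.hpfvm_vertex - 1369.0) < 0.5
        assert abs(t.enmo_vertex - 983.0) < 0.5


class TestRawBouts:
    def test_stationary_unit_vm(self):
        bout = generate_raw_bout("stationary", duration=10, sample_rate=60,
                                 noise_sd=0.0, seed=0)
        np.testing.assert_allclose(vector_magnitude(bout.data), 1.0, atol=1e-12)

    def test_sinusoidal_vm_construction(self):
        bout = generate_raw_bout("sinusoidal", duration=10, sample_rate=60,
                                 amplitude=0.1, frequency=1.0,
                                 orientation=(0, 0, 1), noise_sd=0.0, seed=0)
        expected = 1.0 + 0.1 * np.sin(2 * np.pi * 1.0 * bout.times)
        np.testing.assert_allclose(vector_magnitude(bout.data), np.abs(expected),
                                   atol=1e-12)

    def test_offset_shifts_axis_mean(self):
        bout = generate_raw_bout("stationary", duration=30, sample_rate=60,
                                 orientation=(1, 0, 0), noise_sd=0.0,
                                 offset=(0.05, 0.0, 0.0), seed=0)
        assert abs(bout.data[:, 0].mean() - 1.05) < 1e-12

    def test_aliased_frequency_rejected(self):
        with pytest.raises(ValueError, match="alias"):
            generate_raw_bout("sinusoidal", sample_rate=10.0, frequency=6.0)

    def test_mixed_bout_has_many_orientations(self):
        from wristpaee.signals import find_stationary_windows, _count_orientations
        bout = generate_raw_bout("mixed", duration=600, sample_rate=30,
                                 noise_sd=0.001, seed=4)
        points = find_stationary_windows(bout)
        assert _count_orientations(points) >= 6


class TestKnownTruthRecovery:
    def test_quadratic_refit_on_modest_cohort_hits_truth(self):
        """A single modest cohort refit recovers the generating quadratic
        within its robust 95% CI (the full replicate experiment lives in
        the acceptance suite)."""
        cfg = dataclasses.replace(GeneratorConfig(), n_participants=150, seed=33)
        _, epochs = generate_dataset(cfg)
        wear = epochs[epochs["wear_wrist"] & epochs["wear_combined"]]
        mdl = fit_mixed_model(wear, ModelSpec("hpfvm", "quadratic"))
        t = cfg.truth
        assert abs(mdl.beta_linear - t.beta1_hpfvm) < 2.5 * mdl.se_beta_linear
        assert abs(mdl.beta_quadratic - t.beta2_hpfvm) < 2.5 * mdl.se_beta_quadratic
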