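"""Tests of raw-signal processing: VM, ENMO, HPFVM, filtering, calibration,
epoch summarisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from wristpaee.config import FilterConfig
from wristpaee.signals import (CalibrationInfeasibleError, RawTriaxialSignal,
                               apply_calibration, autocalibrate,
                               butterworth_gain, digital_filter_gain,
                               enmo_series, hpfvm_series, lowpass_filter,
                               process_raw_signal, summarise_epochs,
                               vector_magnitude)
from wristpaee.synthetic import generate_raw_bout


class TestVectorMagnitude:
    @pytest.mark.parametrize("xyz, expected", [
        ((0.0, 0.0, 1.0), 1.0),
        ((0.3, 0.4, 0.0), 0.5),
        ((1.0, 1.0, 1.0), np.sqrt(3.0)),
    ])
    def test_known_values(self, xyz, expected):
        assert vector_magnitude(np.array(xyz)) == pytest.approx(expected)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        xyz = rng.normal(size=(20, 3))
        rot = Rotation.random(rng=rng).as_matrix()
        np.testing.assert_allclose(vector_magnitude(xyz @ rot.T),
                                   vector_magnitude(xyz), rtol=1e-10)


class TestEnmo:
    @pytest.mark.parametrize("vm, expected", [
        (1.0, 0.0), (1.25, 0.25), (0.90, 0.0)])
    def test_subtract_one_and_truncate(self, vm, expected):
        assert enmo_series(np.array([vm]))[0] == pytest.approx(expected)


class TestLowpass:
    def test_constant_signal_unchanged(self):
        sig = RawTriaxialSignal(np.full((600, 3), 0.5), 60.0)
        out = lowpass_filter(sig)
        np.testing.assert_allclose(out.data, 0.5, atol=1e-9)

    @pytest.mark.parametrize("freq", [1.0, 5.0])
    def test_passband_amplitude_preserved(self, freq):
        t = np.arange(0, 30, 1 / 60)
        data = np.column_stack([np.sin(2 * np.pi * freq * t)] * 3)
        out = lowpass_filter(RawTriaxialSignal(data, 60.0))
        mid = slice(300, -300)
        amp = np.abs(out.data[mid, 0]).max()
        assert amp == pytest.approx(1.0, rel=0.01)

    @pytest.mark.parametrize("freq", [22.0, 25.0])
    def test_stopband_matches_designed_magnitude_response(self, freq):
        cutoff, order = 20.0, 4
        t = np.arange(0, 30, 1 / 60)
        data = np.column_stack([np.sin(2 * np.pi * freq * t)] * 3)
        out = lowpass_filter(RawTriaxialSignal(data, 60.0),
                             FilterConfig(filter_order=order))
        mid = slice(300, -300)
        measured = np.abs(out.data[mid, 0]).max()
        expected = digital_filter_gain(freq, 60.0, cutoff, order, "lowpass")
        assert measured == pytest.approx(expected, rel=0.02)
        # attenuation at least as strong as the analog prototype predicts
        assert measured < butterworth_gain(freq, cutoff, order, "lowpass")

    def test_cutoff_above_nyquist_rejected(self):
        sig = RawTriaxialSignal(np.zeros((600, 3)), 30.0)
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter(sig, FilterConfig(lowpass_cutoff=20.0))


class TestHpfvm:
    def test_constant_vm_maps_to_zero(self):
        out = hpfvm_series(np.ones(6000), 60.0)
        assert np.all(out < 1e-6)

    def test_sinusoid_epoch_mean_is_rectified_amplitude(self):
        # passband gain ~1 at 1 Hz; mean of |a sin| = 2a/pi
        t = np.arange(0, 300, 1 / 60)
        vm = 1.0 + 0.1 * np.sin(2 * np.pi * 1.0 * t)
        out = hpfvm_series(vm, 60.0)
        assert out.mean() == pytest.approx(0.1 * 2 / np.pi, rel=0.02)

    def test_subcutoff_drift_removed(self):
        t = np.arange(0, 600, 1 / 60)
        vm = 1.0 + 0.1 * np.sin(2 * np.pi * 0.01 * t)
        out = hpfvm_series(vm, 60.0)
        expected_gain = butterworth_gain(0.01, 0.2, 4, "highpass")
        assert out.mean() < 0.1 * max(expected_gain, 1e-4) + 1e-3

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="warm-up"):
            hpfvm_series(np.ones(10), 60.0)

    def test_epoch_mean_hpfvm_at_least_enmo_on_sinusoids(self):
        """When VM never drops below 1 - amplitude, rectified HPFVM epoch
        means dominate ENMO epoch means."""
        t = np.arange(0, 300, 1 / 60)
        for amp in (0.05, 0.1, 0.3):
            vm = 1.0 + amp * np.sin(2 * np.pi * 1.0 * t)
            assert hpfvm_series(vm, 60.0).mean() >= enmo_series(vm).mean()

    def test_amplitude_linearity_in_passband(self):
        t = np.arange(0, 300, 1 / 60)
        base = hpfvm_series(1 + 0.05 * np.sin(2 * np.pi * t), 60.0).mean()
        scaled = hpfvm_series(1 + 0.15 * np.sin(2 * np.pi * t), 60.0).mean()
        assert scaled / base == pytest.approx(3.0, rel=0.02)


class TestMetricRotationInvariance:
    def test_pipeline_metrics_unchanged_by_rotation(self):
        bout = generate_raw_bout("sinusoidal", duration=120, sample_rate=60,
                                 amplitude=0.2, orientation=(0.3, -0.5, 0.81),
                                 noise_sd=0.0, seed=1)
        rot = Rotation.from_euler("xyz", [31, -47, 112], degrees=True).as_matrix()
        vm0 = vector_magnitude(bout.data)
        vm1 = vector_magnitude(bout.data @ rot.T)
        np.testing.assert_allclose(vm0, vm1, atol=1e-10)
        np.testing.assert_allclose(hpfvm_series(vm0, 60.0),
                                   hpfvm_series(vm1, 60.0), atol=1e-9)


class TestAutocalibration:
    def test_identity_on_calibrated_fixture(self):
        bout = generate_raw_bout("mixed", duration=600, sample_rate=30,
                                 noise_sd=0.001, seed=2)
        params = autocalibrate(bout)
        np.testing.assert_allclose(params.offset, 0.0, atol=0.004)
        np.testing.assert_allclose(params.gain, 1.0, atol=0.004)

    def test_recovers_injected_offset_and_gain(self):
        offset = (0.05, -0.03, 0.02)
        gain = (1.02, 0.97, 1.01)
        bout = generate_raw_bout("mixed", duration=900, sample_rate=30,
                                 noise_sd=0.001, offset=offset, gain=gain, seed=3)
        params = autocalibrate(bout)
        np.testing.assert_allclose(params.offset, offset, atol=0.005)
        np.testing.assert_allclose(params.gain, gain, atol=0.005)
        calibrated = apply_calibration(bout, params)
        vm = vector_magnitude(calibrated.data)
        assert abs(np.median(vm) - 1.0) < 0.005

    def test_single_orientation_infeasible(self):
        bout = generate_raw_bout("stationary", duration=300, sample_rate=30,
                                 noise_sd=0.001, seed=4)
        with pytest.raises(CalibrationInfeasibleError):
            autocalibrate(bout)


class TestEpochSummaries:
    def test_constant_enmo_epoch_mean_in_mg(self):
        out = summarise_epochs(np.full(300 * 60, 0.05), 60.0, 300)
        assert len(out) == 1
        assert out["mean_mg"].iloc[0] == pytest.approx(50.0)
        assert bool(out["valid"].iloc[0])

    def test_six_days_gives_1728_epochs(self):
        out = summarise_epochs(np.zeros(6 * 86400), 1.0, 300)
        assert len(out) == 1728
        assert out["valid"].all()

    def test_partial_nonwear_epoch_invalid(self):
        values = np.full(600 * 10, 0.05)
        wear = np.ones(600 * 10, dtype=bool)
        wear[3000:4000] = False  # non-wear inside the second epoch
        out = summarise_epochs(values, 10.0, 300, wear=wear)
        assert bool(out["valid"].iloc[0])
        assert not bool(out["valid"].iloc[1])
        assert np.isnan(out["mean_mg"].iloc[1])

    def test_incomplete_trailing_epoch_invalid(self):
        out = summarise_epochs(np.zeros(450 * 20), 20.0, 300)
        assert len(out) == 2
        assert not bool(out["valid"].iloc[1])

    def test_empty_series(self):
        out = summarise_epochs(np.array([]), 60.0, 300)
        assert len(out) == 0

    def test_invalid_epoch_length_rejected(self):
        with pytest.raises(ValueError):
            summarise_epochs(np.zeros(100), 1.0, 7)


class TestProcessRawSignal:
    def test_end_to_end_sinusoid(self):
        bout = generate_raw_bout("sinusoidal", duration=600, sample_rate=60,
                                 amplitude=0.1, frequency=1.0, noise_sd=0.0, seed=0)
        out = process_raw_signal(bout, calibrate=False)
        assert len(out) == 2
        # rectified sinusoid mean 2a/pi = 63.7 mg; ENMO of half-rectified
        # sinusoid a/pi = 31.8 mg
        assert out["hpfvm_mg"].iloc[0] == pytest.approx(63.7, rel=0.03)
        assert out["enmo_mg"].iloc[0] == pytest.approx(31.8, rel=0.03)
        assert (out["hpfvm_mg"] >= out["enmo_mg"]).all()
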