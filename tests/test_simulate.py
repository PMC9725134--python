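"""Ground-truth checks on the synthetic gait-lab data generators."""

import numpy as np
import pytest

import gaitfatigue as gf
from gaitfatigue.simulate import (
    BASELINE_MF_HZ,
    band_carrier,
    default_burst_envelope,
    generate_cohort,
    sample_feature_frame,
    smooth_cycle_noise,
)


class TestEmgCarrier:
    def test_carrier_median_frequency_matches_center(self, mf_oracle):
        rng = np.random.default_rng(0)
        fs = 2000.0
        x = band_carrier(int(60 * fs), fs, center_hz=100.0, width_hz=25.0, rng=rng)
        assert mf_oracle(x, fs) == pytest.approx(100.0, abs=3.0)

    def test_spectral_compression_scales_mf(self, mf_oracle):
        """Compressing the frequency axis by s multiplies the MF by s."""
        fs = 2000.0
        spec = gf.EmgGenSpec(target_mf_hz=100.0, fatigue_spectral_scale=0.8, seed=5)
        trial = gf.TrialSpec(n_strides_per_leg=60, condition="fatigued", seed=1)
        emg = gf.generate_emg_channel(spec, trial)
        assert emg.meta["true_mf_hz"] == pytest.approx(80.0)
        rng = np.random.default_rng(2)
        x = band_carrier(int(60 * fs), fs, center_hz=80.0, width_hz=20.0, rng=rng)
        assert mf_oracle(x, fs) == pytest.approx(80.0, abs=3.0)

    def test_zero_envelope_leaves_rest_noise(self):
        spec = gf.EmgGenSpec(burst_envelope=np.zeros(101), seed=3)
        trial = gf.TrialSpec(n_strides_per_leg=10, seed=1)
        emg = gf.generate_emg_channel(spec, trial)
        rms = np.sqrt(np.mean(emg.values**2))
        assert rms == pytest.approx(spec.rest_noise_mean_v, rel=0.35)

    def test_seed_reproducibility_bit_identical(self):
        spec = gf.EmgGenSpec(seed=42)
        trial = gf.TrialSpec(n_strides_per_leg=5, seed=9)
        a = gf.generate_emg_channel(spec, trial)
        b = gf.generate_emg_channel(spec, trial)
        assert np.array_equal(a.values, b.values)

    def test_zero_mean(self):
        spec = gf.EmgGenSpec(seed=1)
        emg = gf.generate_emg_channel(spec, gf.TrialSpec(n_strides_per_leg=30, seed=1))
        assert abs(np.mean(emg.values)) < 0.05 * np.std(emg.values)

    @pytest.mark.parametrize("bad", [{"target_mf_hz": 9.0}, {"target_mf_hz": 251.0},
                                     {"fatigue_spectral_scale": 0.0},
                                     {"sampling_rate_hz": 400.0}])
    def test_spec_validation(self, bad):
        with pytest.raises(ValueError):
            gf.EmgGenSpec(**bad)


class TestHeelTrajectory:
    def test_minima_count_and_spacing(self):
        trial = gf.TrialSpec(n_strides_per_leg=125, cadence_hz=1.0, seed=0)
        heel = gf.generate_heel_trajectory(trial, side="left")
        truth = heel.meta["true_strike_indices"]
        assert truth.size == 126
        assert np.all(np.diff(truth) == heel.sampling_rate_hz)  # 1.0 s apart

    def test_left_right_half_period_offset(self):
        trial = gf.TrialSpec(n_strides_per_leg=10, cadence_hz=1.0, seed=0)
        left = gf.generate_heel_trajectory(trial, side="left")
        right = gf.generate_heel_trajectory(trial, side="right")
        dt = (right.meta["true_strike_indices"][0] - left.meta["true_strike_indices"][0])
        assert dt / left.sampling_rate_hz == pytest.approx(0.5)

    def test_detection_recovers_truth_exactly(self):
        from gaitfatigue.preprocess import detect_heel_strikes

        trial = gf.TrialSpec(n_strides_per_leg=40, cadence_hz=1.1, seed=0)
        heel = gf.generate_heel_trajectory(trial, side="right")
        found = detect_heel_strikes(heel)
        truth = heel.meta["true_strike_indices"]
        assert found.size == truth.size
        assert np.max(np.abs(found - truth)) <= 1


class TestKinematics:
    def test_null_offset_differences_center_on_zero(self):
        waveforms = gf.generate_paired_waveforms(30, offset_deg=0.0, seed=4)
        d = waveforms.differences()
        assert np.abs(d.mean()) < 0.5  # SEM over 30*101 correlated nodes

    def test_offset_restricted_to_window(self):
        """A +1.3 deg shift on 40-47.5% of the cycle elevates only that band."""
        base = gf.generate_paired_waveforms(40, offset_deg=0.0, seed=7)
        shifted = gf.generate_paired_waveforms(
            40, offset_deg=1.3, offset_window_pct=(40.0, 47.5), seed=7
        )
        # same seed: noise cancels; differences are a-b, so a +1.3 shift of
        # the fatigued curves lowers d by 1.3 inside the window only
        delta = base.differences().mean(axis=0) - shifted.differences().mean(axis=0)
        p = np.linspace(0, 100, 101)
        window = (p >= 40.0) & (p <= 47.5)
        assert np.allclose(delta[window], 1.3, atol=1e-9)
        assert np.allclose(delta[~window], 0.0, atol=1e-9)

    def test_per_cycle_curves_shape_and_smoothness(self):
        trial = gf.TrialSpec(n_strides_per_leg=12, seed=3)
        curves = gf.generate_kinematic_waveform(trial, "knee")
        assert curves.shape == (12, 101)
        # smooth low-order noise: adjacent-node steps stay small
        assert np.max(np.abs(np.diff(curves, axis=1))) < 8.0

    def test_noise_sd_calibrated(self):
        rng = np.random.default_rng(0)
        draws = np.array([smooth_cycle_noise(rng, 1.0) for _ in range(4000)])
        node_sd = draws.std(axis=0)
        assert node_sd.mean() == pytest.approx(1.0, abs=0.05)

    def test_unknown_joint(self):
        with pytest.raises(ValueError):
            gf.generate_kinematic_waveform(gf.TrialSpec(seed=0), "elbow")


class TestCohort:
    def test_cohort_structure(self):
        cohort = generate_cohort(n_subjects=6, seed=1)
        assert len(cohort.subjects) == 6
        for subj in cohort.subjects:
            assert set(subj.missing_channels) <= {
                (m, s) for m in subj.muscles for s in ("left", "right")
            }

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            generate_cohort(n_subjects=1)

    def test_feature_frame_cells_unique(self):
        cohort = generate_cohort(n_subjects=5, seed=2)
        frame = sample_feature_frame(cohort, seed=0)
        assert not frame.duplicated(["subject", "muscle", "leg", "condition"]).any()
        assert set(frame["condition"]) == {"comfortable", "fatigued"}

    def test_noiseless_frame_returns_constructed_values(self):
        cohort = generate_cohort(
            n_subjects=2, effect_mf_hz=-10.0, subject_sd_hz=0.0, residual_sd_hz=0.0,
            with_missing_channels=False, seed=3,
        )
        frame = sample_feature_frame(cohort, seed=0)
        for muscle, grp in frame.groupby("muscle"):
            comf = grp.loc[grp.condition == "comfortable", "mf_hz"]
            fat = grp.loc[grp.condition == "fatigued", "mf_hz"]
            assert np.allclose(comf, BASELINE_MF_HZ[muscle])
            assert np.allclose(fat, BASELINE_MF_HZ[muscle] - 10.0)


class TestSubjectSpec:
    def test_missing_channels_must_be_declared(self):
        with pytest.raises(ValueError):
            gf.SubjectSpec(subject_id="X", muscles=("TibA",),
                           missing_channels=(("GasM", "left"),))

    def test_envelope_validation(self):
        with pytest.raises(ValueError):
            gf.EmgGenSpec(burst_envelope=np.ones(50))


def test_default_envelope_in_unit_range():
    env = default_burst_envelope()
    assert env.shape == (101,)
    assert env.min() >= 0 and env.max() == pytest.approx(1.0)
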