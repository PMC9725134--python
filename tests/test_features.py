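"""Median frequency, RMS envelope, activation threshold and SNR gating."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import gaitfatigue as gf
from gaitfatigue import SignalChannel
from gaitfatigue.features import (
    GateDecision,
    RestingStats,
    active_phase_rms,
    cycle_median_frequency,
    extract_channel_features,
    resting_stats,
    rms_envelope,
    snr_gate,
    time_normalize,
    trial_median_frequency,
)
from gaitfatigue.preprocess import segment_cycles
from gaitfatigue.simulate import flat_band_carrier

FS = 2000.0


class TestCycleMedianFrequency:
    def test_pure_tone(self):
        t = np.arange(int(FS)) / FS  # 1 s cycle -> 1 Hz bins
        x = np.sin(2 * np.pi * 50.0 * t)
        assert cycle_median_frequency(x, FS) == pytest.approx(50.0, abs=1.0)

    def test_flat_band_noise_centers_on_130(self):
        """Flat power on 10-250 Hz puts the median at the band midpoint."""
        rng = np.random.default_rng(0)
        mfs = [
            cycle_median_frequency(flat_band_carrier(int(FS), FS, rng), FS)
            for _ in range(100)
        ]
        assert np.median(mfs) == pytest.approx(130.0, abs=5.0)

    def test_time_compression_doubles_mf(self):
        """Playing the same samples at twice the rate doubles the MF."""
        t = np.arange(int(FS)) / FS
        x = np.sin(2 * np.pi * 50.0 * t)
        assert cycle_median_frequency(x, 2 * FS) == pytest.approx(
            2 * cycle_median_frequency(x, FS), rel=0.02
        )

    def test_all_zero_cycle_is_missing(self):
        assert np.isnan(cycle_median_frequency(np.zeros(2000), FS))


class TestTrialMedianFrequency:
    def test_odd_count(self):
        assert trial_median_frequency([80.0, 90.0, 100.0]) == 90.0

    def test_even_count_midpoint(self):
        assert trial_median_frequency([80.0, 100.0]) == 90.0

    def test_nan_cycles_dropped(self):
        assert trial_median_frequency([80.0, np.nan, 100.0]) == 90.0
        assert np.isnan(trial_median_frequency([np.nan]))

    @given(st.permutations([62.0, 75.5, 88.0, 91.0, 120.0]))
    def test_permutation_invariant(self, mfs):
        assert trial_median_frequency(mfs) == 88.0

    def test_robust_to_minority_outliers(self):
        clean = [80.0] * 5
        assert trial_median_frequency(clean + [249.0, 11.0]) == 80.0


class TestRmsEnvelope:
    def test_constant_signal(self):
        ch = SignalChannel(np.full(2000, 0.3), FS, label="RecF")
        assert np.allclose(rms_envelope(ch).values, 0.3)

    def test_sine_gives_a_over_sqrt2(self):
        # window of 101 ms at 2 kHz is ~202 samples; use a 100 Hz tone so
        # the window spans ~10 periods
        t = np.arange(int(2 * FS)) / FS
        ch = SignalChannel(0.8 * np.sin(2 * np.pi * 100.0 * t), FS, label="RecF")
        env = rms_envelope(ch).values
        interior = env[500:-500]
        assert np.allclose(interior, 0.8 / np.sqrt(2), rtol=0.01)

    @given(st.floats(0.1, 10.0))
    def test_homogeneity(self, k):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(1500)
        ch = SignalChannel(x, FS, label="RecF")
        assert np.allclose(
            rms_envelope(ch.with_values(k * x)).values, k * rms_envelope(ch).values
        )

    def test_window_longer_than_signal_rejected(self):
        ch = SignalChannel(np.zeros(100), FS, label="RecF")
        with pytest.raises(ValueError):
            rms_envelope(ch, window_ms=101.0)


class TestTimeNormalize:
    def test_linear_ramp_preserved(self):
        y = np.linspace(2.0, 7.0, 57)
        out = time_normalize(y)
        assert out.size == 101
        assert out[0] == 2.0 and out[-1] == 7.0
        assert np.allclose(out, np.linspace(2.0, 7.0, 101))

    def test_identity_on_101_samples(self):
        y = np.random.default_rng(0).standard_normal(101)
        assert np.allclose(time_normalize(y), y)

    def test_average_of_identical_cycles_is_the_cycle(self):
        y = np.sin(np.linspace(0, 2 * np.pi, 88))
        stack = np.vstack([time_normalize(y)] * 5)
        assert np.allclose(stack.mean(axis=0), time_normalize(y))

    def test_too_short(self):
        with pytest.raises(ValueError):
            time_normalize(np.array([1.0]))


class TestRestingStats:
    def test_threshold_formula(self):
        rest = RestingStats(mean_rms_v=0.010, sd_rms_v=0.002)
        assert rest.threshold_v == pytest.approx(0.014)

    def test_constant_envelope_threshold_equals_mean(self):
        rest = RestingStats(mean_rms_v=0.010, sd_rms_v=0.0)
        assert rest.threshold_v == pytest.approx(0.010)

    def test_scaling_homogeneity(self):
        spec = gf.EmgGenSpec(seed=8)
        ch = gf.generate_resting_channel(spec, duration_s=4.0)
        r1 = resting_stats(ch)
        r2 = resting_stats(ch.with_values(3.0 * ch.values))
        assert r2.threshold_v == pytest.approx(3.0 * r1.threshold_v, rel=1e-9)

    def test_too_short_recording_rejected(self):
        ch = SignalChannel(np.random.default_rng(0).standard_normal(1000), FS, label="RecF")
        with pytest.raises(ValueError):
            resting_stats(ch)  # 0.5 s < 2 s


class TestActivePhaseRms:
    def test_uniform_waveform_above_threshold(self):
        rest = RestingStats(0.01, 0.001)
        wf = np.full(101, rest.threshold_v + 0.02)
        assert active_phase_rms(wf, rest) == pytest.approx(rest.threshold_v + 0.02)

    def test_only_active_samples_averaged(self):
        rest = RestingStats(0.01, 0.0)
        wf = np.zeros(101)
        wf[:50] = 2 * rest.threshold_v
        assert active_phase_rms(wf, rest) == pytest.approx(2 * rest.threshold_v)

    def test_no_active_phase_is_missing(self, caplog):
        rest = RestingStats(0.01, 0.001)
        with caplog.at_level("INFO"):
            out = active_phase_rms(np.zeros(101), rest)
        assert np.isnan(out)
        assert any("no active phase" in rec.message for rec in caplog.records)


class TestSnrGate:
    def test_boundary_inclusive(self):
        rest = RestingStats(0.01, 0.0)
        assert snr_gate(0.05, rest).included  # SNR exactly 5
        assert snr_gate(0.05, rest).snr == pytest.approx(5.0)

    def test_below_threshold_excluded(self):
        rest = RestingStats(0.01, 0.0)
        decision = snr_gate(0.049, rest)
        assert not decision.included and "SNR" in decision.reason

    def test_zero_rest_mean_included_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            decision = snr_gate(0.05, RestingStats(0.0, 0.0))
        assert decision.included and np.isinf(decision.snr)

    def test_injected_low_amplitude_channels_all_gated(self):
        """Channels built below the SNR floor are excluded, strong ones kept."""
        trial = gf.TrialSpec(n_strides_per_leg=10, seed=1)
        heel = gf.generate_heel_trajectory(trial, side="left", sampling_rate_hz=100.0)
        strikes = heel.meta["true_strike_indices"]
        excluded = 0
        for amp, seed in ((0.05, 1), (0.006, 2), (0.007, 3)):
            spec = gf.EmgGenSpec(
                sampling_rate_hz=1000.0, amplitude_v=amp, rest_noise_mean_v=0.004,
                rest_noise_sd_v=0.0008, seed=seed,
            )
            emg = gf.generate_emg_channel(spec, trial)
            rest = resting_stats(gf.generate_resting_channel(spec, 4.0))
            emg_strikes = np.round(strikes / 100.0 * 1000.0).astype(int)
            feat = extract_channel_features(
                emg, segment_cycles(emg_strikes, 1000.0), rest, "comfortable"
            )
            excluded += int(not feat.included)
        assert excluded == 2


@pytest.fixture(scope="module")
def channel_setup():
    trial = gf.TrialSpec(n_strides_per_leg=20, seed=1)
    heel = gf.generate_heel_trajectory(trial, side="left", sampling_rate_hz=100.0)
    strikes = np.round(heel.meta["true_strike_indices"] / 100.0 * 1000.0).astype(int)
    spec = gf.EmgGenSpec(sampling_rate_hz=1000.0, target_mf_hz=90.0, seed=6)
    emg = gf.generate_emg_channel(spec, trial, muscle="TibA", side="left")
    rest = resting_stats(gf.generate_resting_channel(spec, 4.0, "TibA", "left"))
    return emg, segment_cycles(strikes, 1000.0), rest


class TestFeatureExtraction:
    def test_mf_invariant_rms_linear_under_amplitude_scaling(self, channel_setup):
        """Rescaling signal and resting reference together scales the RMS
        linearly and leaves the MF untouched."""
        emg, cycles, rest = channel_setup
        f1 = extract_channel_features(emg, cycles, rest, "comfortable")
        scaled_rest = RestingStats(2.5 * rest.mean_rms_v, 2.5 * rest.sd_rms_v)
        f2 = extract_channel_features(
            emg.with_values(2.5 * emg.values), cycles, scaled_rest, "comfortable"
        )
        assert abs(f2.mf_hz - f1.mf_hz) / f1.mf_hz < 1e-9
        assert f2.rms_v == pytest.approx(2.5 * f1.rms_v, rel=1e-9)
        assert f2.snr == pytest.approx(f1.snr, rel=1e-9)

    def test_extraction_is_pure(self, channel_setup):
        emg, cycles, rest = channel_setup
        f1 = extract_channel_features(emg, cycles, rest, "comfortable")
        f2 = extract_channel_features(emg, cycles, rest, "comfortable")
        assert f1.mf_hz == f2.mf_hz and f1.rms_v == f2.rms_v and f1.snr == f2.snr

    def test_no_resting_recording_keeps_channel_with_nan_snr(self, channel_setup):
        emg, cycles, _ = channel_setup
        feat = extract_channel_features(emg, cycles, None, "comfortable")
        assert feat.included and np.isnan(feat.snr) and np.isnan(feat.rms_v)
        assert np.isfinite(feat.mf_hz)
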