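"""Synthetic session generator: ground truth, conservation, calibration."""

import dataclasses

import numpy as np
import pytest
import scipy.signal

from opmtools.core import Recording
from opmtools.forward import build_array_geometry
from opmtools.synth import (
    AEFConfig,
    InterferenceSpec,
    LineSpec,
    TappingConfig,
    aef_event_onsets,
    inject_physiological_artifacts,
    simulate_evoked_session,
    simulate_interference,
    simulate_motion_trajectory,
    simulate_tapping_session,
    tapping_event_onsets,
    write_session,
)
from opmtools.temporal import welch_asd


class TestMotionTrajectory:
    def test_still_for_whole_duration_is_zero(self):
        m = simulate_motion_trajectory(10.0, 120.0, still_until=9.9999, seed=0)
        # the mask never ramps up within the record
        assert np.max(np.abs(m.pose[: int(9.9 * 120)])) == 0.0

    def test_translation_range_is_exact(self):
        m = simulate_motion_trajectory(30.0, 120.0, still_until=2.0, translation_range=1.0, seed=1)
        rng = m.translation.max(axis=0) - m.translation.min(axis=0)
        np.testing.assert_allclose(rng, 1.0, atol=1e-9)

    def test_band_limited_below_2hz(self):
        m = simulate_motion_trajectory(60.0, 120.0, still_until=0.0, seed=2)
        f, p = scipy.signal.welch(m.translation[:, 0], fs=120.0, nperseg=4096)
        assert p[f > 2.0].sum() < 0.01 * p.sum()

    def test_still_period_respected(self):
        m = simulate_motion_trajectory(20.0, 120.0, still_until=5.0, seed=3)
        assert np.max(np.abs(m.pose[m.time < 5.0])) == 0.0

    def test_negative_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_motion_trajectory(10.0, 120.0, 0.0, translation_range=-1.0)


class TestInterference:
    def test_homogeneous_term_is_rank_three(self, small_geom, reference_channels):
        spec = InterferenceSpec(lines=(), gradient_scale=0.0, static_field=0.0, sensor_noise_asd=0.0)
        comps, _ = simulate_interference(small_geom, spec, None, 10.0, 250.0, seed=0,
                                         reference_channels=reference_channels)
        h = comps["homogeneous"]
        assert np.linalg.matrix_rank(h, tol=np.linalg.norm(h) * 1e-10) == 3

    def test_white_noise_calibration(self, small_geom):
        fs = 1000.0
        spec = InterferenceSpec(homogeneous_peak=0.0, static_field=0.0, gradient_scale=0.0,
                                lines=(), sensor_noise_asd=15.0)
        comps, _ = simulate_interference(small_geom, spec, None, 60.0, fs, seed=1)
        noise = comps["sensor_noise"]
        sigma_expected = 15e-15 * np.sqrt(fs / 2)
        assert noise.std() == pytest.approx(sigma_expected, rel=0.01)
        rec = Recording(list(small_geom.channels), noise, fs)
        psd = welch_asd(rec, 10.0)
        band = (psd.freqs >= 10) & (psd.freqs <= 100)
        assert np.median(psd.asd[:, band]) == pytest.approx(15.0, rel=0.05)

    def test_gradient_term_zero_when_still(self, small_geom):
        m = simulate_motion_trajectory(10.0, 250.0, still_until=9.999, seed=0)
        spec = InterferenceSpec(lines=(), sensor_noise_asd=0.0, homogeneous_peak=0.0)
        comps, _ = simulate_interference(small_geom, spec, m, 9.5, 250.0, seed=0)
        assert np.max(np.abs(comps["gradient_motion"])) == 0.0

    def test_line_visibility_flag_controls_reference_coupling(self, small_geom, reference_channels):
        lines = (LineSpec(50.0, 1e-12, 0.0, reference_visible=True),
                 LineSpec(21.0, 1e-12, 0.0, reference_visible=False))
        spec = InterferenceSpec(homogeneous_peak=0.0, static_field=0.0, gradient_scale=0.0,
                                lines=lines, sensor_noise_asd=0.0)
        comps, info = simulate_interference(small_geom, spec, None, 10.0, 250.0, seed=2,
                                            reference_channels=reference_channels)
        c50, c21 = info["lines"][0]["coupling"], info["lines"][1]["coupling"]
        n_scalp = small_geom.n_channels
        assert np.any(np.abs(c50[n_scalp:]) > 0.05)
        assert np.all(c21[n_scalp:] == 0.0)


class TestEvokedSession:
    def test_noiseless_peak_latency_and_amplitude(self, quiet_aef_session):
        rec, truth = quiet_aef_session
        rows = rec.picks("scalp")
        avg = np.zeros((rows.size, 500))
        for o in truth.events.onset_sample:
            avg += rec.data[rows, o : o + 500]
        avg /= len(truth.events)
        ch, t = np.unravel_index(np.argmax(np.abs(avg)), avg.shape)
        assert t == 100  # 100 ms at 1000 Hz
        assert abs(avg[ch, t]) == pytest.approx(220e-15, abs=1e-21)

    def test_default_preset_has_570_onsets(self):
        onsets = aef_event_onsets(AEFConfig())
        assert onsets.size == 570
        assert np.all(np.diff(onsets) == 500)  # 0.5 s ISI at 1000 Hz

    def test_truth_components_sum_exactly(self, aef_session_small):
        rec, truth = aef_session_small
        assert np.max(np.abs(rec.data - truth.sum_components())) == 0.0

    def test_same_seed_bitwise_reproducible(self):
        cfg = dataclasses.replace(AEFConfig(), n_trials=5, still_until=1.0)
        a, _ = simulate_evoked_session(cfg, seed=9)
        b, _ = simulate_evoked_session(cfg, seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_session_round_trip_on_disk(self, tmp_path):
        cfg = dataclasses.replace(AEFConfig(), n_trials=4, still_until=1.0, n_sensors=5)
        rec, truth = simulate_evoked_session(cfg, seed=0)
        out = write_session(rec, truth, tmp_path, stem="aef")
        from opmtools.core import read_events, read_recording

        back = read_recording(out / "aef")
        np.testing.assert_array_equal(back.data, rec.data)
        assert len(read_events(out / "aef_events.tsv")) == 4


class TestTappingSession:
    def test_default_preset_has_100_trials(self):
        onsets = tapping_event_onsets(TappingConfig(), np.random.default_rng(0))
        assert onsets.size == 100
        itis = np.diff(onsets) / 1000.0
        assert np.all((itis >= 7.0 - 1e-9) & (itis <= 8.0 + 1e-9))

    def test_beta_power_ratio_matches_erd_squared(self):
        # power of the modulated source in the flat part of the tapping
        # window vs baseline, against the envelope-squared prediction
        cfg = dataclasses.replace(TappingConfig(), n_sensors=4, n_trials=40,
                                  blink_rate=0.0, heart_rate=0.0)
        _, truth = simulate_tapping_session(cfg, seed=12)
        src = truth.sources["beta_source"]
        fs = cfg.fs
        task_p, base_p = [], []
        for o in truth.events.onset_sample:
            task = src[o + int(0.2 * fs) : o + int(2.4 * fs)]
            base = src[o - int(1.6 * fs) : o - int(0.1 * fs)]
            task_p.append(np.mean(task**2))
            base_p.append(np.mean(base**2))
        ratio = np.mean(task_p) / np.mean(base_p)
        assert ratio == pytest.approx(cfg.erd_factor**2, rel=0.02)

    def test_pmbr_window_power_exceeds_baseline_noiselessly(self):
        cfg = dataclasses.replace(TappingConfig(), n_sensors=4, n_trials=12,
                                  blink_rate=0.0, heart_rate=0.0)
        _, truth = simulate_tapping_session(cfg, seed=5)
        src = truth.sources["beta_source"]
        fs = cfg.fs
        wins = 0
        for o in truth.events.onset_sample:
            pmbr = np.mean(src[o + int(2.9 * fs) : o + int(3.9 * fs)] ** 2)
            base = np.mean(src[o - int(1.6 * fs) : o - int(0.1 * fs)] ** 2)
            wins += pmbr > base
        assert wins == len(truth.events)

    def test_negative_erd_rejected(self):
        with pytest.raises(ValueError):
            dataclasses.replace(TappingConfig(), erd_factor=-0.1)


class TestPhysiologicalArtifacts:
    def test_zero_rates_leave_recording_unchanged(self, small_geom):
        rng = np.random.default_rng(0)
        rec = Recording(list(small_geom.channels), 1e-13 * rng.standard_normal((24, 2500)), 250.0)
        out, truth = inject_physiological_artifacts(rec, small_geom, 0.0, 0.0, seed=0)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_cardiac_interval_matches_heart_rate(self, small_geom):
        rec = Recording(list(small_geom.channels), np.zeros((24, 60 * 250)), 250.0)
        _, truth = inject_physiological_artifacts(rec, small_geom, 0.0, 66.0, seed=1)
        intervals = np.diff(truth["cardiac_peak_times"])
        assert np.mean(intervals) == pytest.approx(60.0 / 66.0, rel=0.03)
        assert np.all(np.abs(intervals - 60.0 / 66.0) <= 0.03 * 60.0 / 66.0 + 1e-9)

    def test_blink_durations_in_range(self, small_geom):
        rec = Recording(list(small_geom.channels), np.zeros((24, 120 * 250)), 250.0)
        _, truth = inject_physiological_artifacts(rec, small_geom, 15.0, 0.0, seed=2)
        d = truth["blink_durations"]
        assert d.size > 5
        assert np.all((d >= 0.2) & (d <= 0.5))
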