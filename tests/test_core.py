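"""Recording container, motion I/O, channel selection and resampling."""

import json

import numpy as np
import pytest

from opmtools.core import (
    ChannelInfo,
    MotionTrace,
    Recording,
    read_motion_csv,
    read_recording,
    resample,
    select_channels,
    sync_and_upsample_motion,
    write_motion_csv,
    write_recording,
)
from opmtools.synth import simulate_motion_trajectory

from conftest import make_recording


class TestRecordingContainer:
    def test_round_trip_identity(self, tmp_path):
        rec = make_recording(n_channels=4, n_samples=100, with_trigger=True)
        rec.history.append({"step": "unit_test", "k": 1})
        stem = write_recording(rec, tmp_path / "sess")
        back = read_recording(stem)
        np.testing.assert_array_equal(back.data, rec.data)
        assert back.fs == rec.fs
        assert back.channel_names == rec.channel_names
        assert [c.kind for c in back.channels] == [c.kind for c in rec.channels]
        assert back.history == rec.history

    def test_history_preserved_in_order(self, tmp_path):
        rec = make_recording()
        for step in ("a", "b", "c"):
            rec = rec.with_data(rec.data, step)
        stem = write_recording(rec, tmp_path / "s")
        meta = json.loads((tmp_path / "s_meta.json").read_text())
        assert [h["step"] for h in meta["history"]] == ["a", "b", "c"]

    def test_channel_count_mismatch_rejected(self, tmp_path):
        rec = make_recording(n_channels=4)
        write_recording(rec, tmp_path / "s")
        meta_path = tmp_path / "s_meta.json"
        meta = json.loads(meta_path.read_text())
        meta["n_channels"] = 5
        meta_path.write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="channel"):
            read_recording(tmp_path / "s")

    def test_femtotesla_sidecar_unit_converted(self, tmp_path):
        rec = make_recording(n_channels=4, n_samples=10)
        rec.data[:] = 220.0  # stored values are fT in this container
        write_recording(rec, tmp_path / "s")
        meta_path = tmp_path / "s_meta.json"
        meta = json.loads(meta_path.read_text())
        meta["unit"] = "fT"
        meta_path.write_text(json.dumps(meta))
        back = read_recording(tmp_path / "s")
        np.testing.assert_allclose(back.data, 2.2e-13)

    def test_empty_recording_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="2-D|channels"):
            Recording(make_recording().channels, np.zeros((4,)), 250.0)
        rec = make_recording(n_samples=1)
        rec.data = rec.data[:, :0]
        with pytest.raises(ValueError):
            write_recording(Recording(rec.channels, np.zeros((4, 0)), 250.0), tmp_path / "e")

    def test_nonfinite_samples_rejected(self):
        rec = make_recording()
        data = rec.data.copy()
        data[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            Recording(rec.channels, data, rec.fs)


class TestMotionCSV:
    def test_blank_row_interpolated_to_midpoint(self, tmp_path):
        path = tmp_path / "m.csv"
        lines = ["time_s,tx,ty,tz,rx,ry,rz"]
        for i, row in enumerate([[0.0] * 6, [2.0] * 6, None, [6.0] * 6, [8.0] * 6]):
            vals = "," * 6 if row is None else "," + ",".join(map(str, row))
            lines.append(f"{i * 0.1:.1f}{vals}")
        path.write_text("\n".join(lines))
        m = read_motion_csv(path)
        np.testing.assert_allclose(m.pose[2], 4.0)  # mean of rows 2 and 4

    def test_constant_pose_has_zero_range(self, tmp_path):
        path = tmp_path / "m.csv"
        rows = "\n".join(f"{i/120:.6f},0.1,0.2,0.3,1,2,3" for i in range(50))
        path.write_text("time_s,tx,ty,tz,rx,ry,rz\n" + rows)
        m = read_motion_csv(path)
        assert np.all(m.translation.max(axis=0) - m.translation.min(axis=0) == 0)

    def test_simulated_trajectory_round_trip(self, tmp_path):
        m = simulate_motion_trajectory(5.0, 120.0, 1.0, 0.4, seed=2)
        write_motion_csv(m, tmp_path / "m.csv")
        back = read_motion_csv(tmp_path / "m.csv")
        assert np.max(np.abs(back.pose - m.pose)) < 1e-9
        assert np.max(np.abs(back.time - m.time)) < 1e-9

    def test_too_few_rows_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("time_s,tx,ty,tz,rx,ry,rz\n0.0,1,1,1,1,1,1\n")
        with pytest.raises(ValueError, match="2 rows"):
            read_motion_csv(path)


class TestMotionSync:
    def _rec_with_pulse(self, n=5000, fs=1000.0, pulse=1000):
        rec = make_recording(n_channels=4, n_samples=n, fs=fs, with_trigger=True)
        rec.data[-1, pulse : pulse + 10] = 1.0
        return rec

    def test_linear_ramp_upsampled_exactly(self):
        rec = self._rec_with_pulse(pulse=0)
        t = np.arange(0, 4.0, 1 / 120.0)
        m = MotionTrace(t, np.outer(t, [1.0, 2.0, 3.0]), np.outer(t, [4.0, 5.0, 6.0]))
        out = sync_and_upsample_motion(m, rec, "TRIG")
        assert out.time.size == rec.n_samples
        t_rec = np.arange(rec.n_samples) / rec.fs
        inside = t_rec <= t[-1]
        np.testing.assert_allclose(out.translation[inside, 0], t_rec[inside], atol=1e-9)

    def test_pulse_sample_anchors_motion_zero(self):
        rec = self._rec_with_pulse(pulse=1000)
        t = np.arange(0, 3.0, 1 / 120.0)
        m = MotionTrace(t, np.outer(t, [1.0, 0, 0]), np.zeros((t.size, 3)))
        out = sync_and_upsample_motion(m, rec, "TRIG")
        # motion t=0 (tx=0) lands at recording sample 1000
        assert abs(out.translation[1000, 0]) < 1e-12
        assert out.translation[999, 0] < 0  # extrapolated before the pulse

    def test_smooth_trajectory_recovered_within_one_percent(self):
        fs = 1000.0
        dense = simulate_motion_trajectory(5.0, fs, 0.5, 0.5, seed=4)
        sub = MotionTrace(dense.time[::8] + 0.0, dense.translation[::8], dense.rotation[::8])
        rec = self._rec_with_pulse(n=5000, pulse=0)
        out = sync_and_upsample_motion(sub, rec, "TRIG")
        err = np.sqrt(np.mean((out.translation - dense.translation) ** 2, axis=0))
        rng = dense.translation.max(axis=0) - dense.translation.min(axis=0)
        assert np.all(err < 0.01 * rng)

    def test_missing_pulse_rejected(self):
        rec = make_recording(n_channels=4, n_samples=100, with_trigger=True)
        t = np.arange(0, 0.3, 1 / 120.0)
        m = MotionTrace(t, np.zeros((t.size, 3)), np.zeros((t.size, 3)))
        with pytest.raises(ValueError, match="pulse"):
            sync_and_upsample_motion(m, rec, "TRIG")


class TestSelectChannels:
    def test_drop_named_channels(self, aef_session_small):
        rec, _ = aef_session_small
        scalp = [c.name for c in rec.channels if c.kind == "scalp"]
        assert len(scalp) == 86
        out = select_channels(rec, lambda c: c.name not in {"S00-RAD", "S00-TAN"})
        assert sum(c.kind == "scalp" for c in out.channels) == 84
        assert len(out.history) == len(rec.history) + 1

    def test_keep_scalp_kind(self, aef_session_small):
        rec, _ = aef_session_small
        out = select_channels(rec, lambda c: c.kind == "scalp")
        assert out.n_channels == 86

    def test_conjunction_equals_sequential_selection(self):
        rec = make_recording(n_channels=8)
        p1 = lambda c: c.axis == "RAD"
        p2 = lambda c: not c.name.startswith("S01")
        seq = select_channels(select_channels(rec, p1), p2)
        joint = select_channels(rec, lambda c: p1(c) and p2(c))
        assert seq.channel_names == joint.channel_names
        np.testing.assert_array_equal(seq.data, joint.data)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="no channels"):
            select_channels(make_recording(), lambda c: False)


class TestResample:
    def test_sine_amplitude_preserved(self):
        fs, f0 = 6000.0, 10.0
        t = np.arange(int(fs * 4)) / fs
        rec = make_recording(n_channels=4, n_samples=t.size, fs=fs)
        rec.data[:] = 1e-12 * np.sin(2 * np.pi * f0 * t)
        out = resample(rec, 1000.0)
        assert out.fs == 1000.0
        mid = out.data[0, 500:3500]
        amp = (mid.max() - mid.min()) / 2
        assert abs(amp - 1e-12) < 0.01e-12

    def test_dc_channel_unchanged(self):
        rec = make_recording(n_channels=4, n_samples=6000, fs=6000.0)
        rec.data[:] = 3e-12
        out = resample(rec, 1000.0)
        np.testing.assert_allclose(out.data, 3e-12, rtol=1e-6)

    def test_trigger_onset_reindexed(self):
        rec = make_recording(n_channels=4, n_samples=12000, fs=6000.0, with_trigger=True)
        rec.data[-1, 6000:6030] = 2.0  # pulse at t = 1.0 s
        out = resample(rec, 1000.0)
        onsets = np.flatnonzero(out.data[-1] > 0)
        assert onsets[0] == 1000
        assert out.data[-1, 1000] == 2.0

    @pytest.mark.parametrize("fs_new", [6000.0, 7000.0, 0.0, -5.0])
    def test_invalid_rates_rejected(self, fs_new):
        rec = make_recording(fs=6000.0)
        with pytest.raises(ValueError):
            resample(rec, fs_new)
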