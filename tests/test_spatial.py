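"""Spatial filtering: HFC, SSP, ICA and artifact detectors."""

import dataclasses

import numpy as np
import pytest

from opmtools.core import ChannelInfo, Recording
from opmtools.forward import build_array_geometry
from opmtools.spatial import (
    apply_hfc,
    apply_projector,
    detect_artifact_segments,
    detect_bad_channels,
    hfc_projector,
    ica_denoise,
    ssp_from_noise,
)
from opmtools.synth import InterferenceSpec, TappingConfig, simulate_tapping_session
from opmtools.temporal import butter_zerophase

from conftest import make_recording


def gram_schmidt_projector(N):
    """Independent construction: orthonormalise N's columns explicitly."""
    Q = []
    for j in range(N.shape[1]):
        v = N[:, j].astype(float)
        for q in Q:
            v -= q * (q @ v)
        Q.append(v / np.linalg.norm(v))
    Q = np.stack(Q, axis=1)
    return np.eye(N.shape[0]) - Q @ Q.T


class TestHFCProjector:
    def test_homogeneous_fields_in_null_space(self, small_geom):
        proj = hfc_projector(small_geom.channels)
        N = small_geom.orientations
        rng = np.random.default_rng(0)
        for _ in range(5):
            b = rng.standard_normal(3)
            out = proj.matrix @ (N @ b)
            assert np.max(np.abs(out)) < 1e-12 * np.max(np.abs(N @ b))

    def test_rank_reduced_by_three(self, small_geom):
        proj = hfc_projector(small_geom.channels)
        n = len(proj.channel_names)
        assert np.linalg.matrix_rank(proj.matrix, tol=1e-8) == n - 3

    def test_matches_gram_schmidt_oracle(self, small_geom):
        proj = hfc_projector(small_geom.channels)
        oracle = gram_schmidt_projector(small_geom.orientations)
        assert np.max(np.abs(proj.matrix - oracle)) < 1e-10

    def test_coplanar_axes_rejected(self):
        chans = [
            ChannelInfo(f"C{i}", "scalp", "RAD", np.array([0.1 * i + 0.1, 0, 0]), np.array([0.0, 0, 1.0]))
            for i in range(6)
        ]
        with pytest.raises(ValueError, match="rank"):
            hfc_projector(chans)


class TestApplyHFC:
    def test_idempotent_on_data(self, aef_session_small):
        rec, _ = aef_session_small
        once = apply_hfc(rec)
        twice = apply_hfc(once)
        assert np.max(np.abs(twice.data - once.data)) < 1e-8 * np.max(np.abs(once.data))

    def test_commutes_with_temporal_filter(self, aef_session_small):
        rec, _ = aef_session_small
        a = butter_zerophase(apply_hfc(rec), "highpass", 2.0, 5)
        b = apply_hfc(butter_zerophase(rec, "highpass", 2.0, 5))
        assert np.max(np.abs(a.data - b.data)) < 1e-8 * np.max(np.abs(a.data))

    def test_homogeneous_truth_annihilated(self, aef_session_small):
        rec, truth = aef_session_small
        rows = rec.picks("scalp")
        P = hfc_projector([rec.channels[i] for i in rows]).matrix
        hom = truth.components["homogeneous"][rows]
        att_db = 10 * np.log10(np.sum(hom**2) / max(np.sum((P @ hom) ** 2), 1e-300))
        assert att_db >= 120.0


class TestSSP:
    def test_rank_two_noise_annihilated(self):
        rng = np.random.default_rng(1)
        rec = make_recording(n_channels=10, n_samples=5000, fs=250.0)
        patterns = rng.standard_normal((10, 2))
        noise_src = rng.standard_normal((2, 5000))
        noise = Recording(rec.channels, patterns @ noise_src * 1e-12, 250.0)
        proj = ssp_from_noise(noise, 2)
        resid = proj.matrix @ noise.data
        assert np.max(np.abs(resid)) < 1e-10 * np.max(np.abs(noise.data))

    def test_zero_components_is_identity(self):
        noise = make_recording(n_channels=6, n_samples=1000)
        proj = ssp_from_noise(noise, 0)
        np.testing.assert_array_equal(proj.matrix, np.eye(6))

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        noise = make_recording(n_channels=8, n_samples=20000, fs=250.0, seed=3)
        noise.data += 5e-12 * np.outer(rng.standard_normal(8), rng.standard_normal(20000))
        proj = ssp_from_noise(noise, 1)
        X = noise.data - noise.data.mean(axis=1, keepdims=True)
        vals, vecs = np.linalg.eigh(X @ X.T)
        u = vecs[:, -1]
        # subspace angle between the removed direction and the top eigenvector
        removed = np.eye(8) - proj.matrix
        angle = np.arccos(np.clip(np.abs(u @ removed @ u), 0, 1))
        assert angle < 1e-6

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            ssp_from_noise(make_recording(n_channels=4), 4)


class TestICA:
    def test_no_flags_is_identity(self):
        rec = make_recording(n_channels=12, n_samples=20000, fs=250.0, seed=4)
        out, report = ica_denoise(rec, n_components=6, seed=0, flag_rules={})
        assert report.flagged == []
        assert np.max(np.abs(out.data - rec.data)) < 1e-8 * np.max(np.abs(rec.data))

    def test_three_source_mixture_recovered(self):
        # classic blind-source-separation check: three independent
        # non-gaussian sources, recovered up to permutation and sign
        rng = np.random.default_rng(5)
        n = 40000
        s = np.stack([
            np.sign(np.sin(2 * np.pi * 3.1 * np.arange(n) / 1000.0)),
            rng.laplace(size=n),
            np.sin(2 * np.pi * 7.7 * np.arange(n) / 1000.0) ** 3,
        ])
        A = rng.standard_normal((12, 3))
        rec = make_recording(n_channels=12, n_samples=n, fs=1000.0)
        rec.data[:] = 1e-12 * (A @ s) + 1e-14 * rng.standard_normal((12, n))
        _, report = ica_denoise(rec, n_components=3, seed=1, flag_rules={})
        corrs = []
        for src in s:
            c = max(abs(np.corrcoef(src, comp)[0, 1]) for comp in report.sources)
            corrs.append(c)
        assert np.mean(corrs) > 0.95

    def test_cardiac_component_found_and_removed(self):
        spec = InterferenceSpec(homogeneous_peak=0.0, lines=(), gradient_scale=0.0, static_field=0.0)
        cfg = dataclasses.replace(TappingConfig(), n_trials=10, interference=spec)
        rec, truth = simulate_tapping_session(cfg, seed=6)
        proc = butter_zerophase(rec, "highpass", 2.0, 5)
        proc = butter_zerophase(proc, "lowpass", 80.0, 6)
        tmpl = truth.sources["cardiac_source"]
        out, report = ica_denoise(proc, 30, seed=454, flag_rules={"templates": {"cardiac": tmpl}})
        assert any("cardiac" in r for r in report.flag_reasons.values())
        # matched-bandwidth correlation of the best component with the truth
        tmpl_rec = Recording([rec.channels[0]], tmpl[None, :] * 1e-12, rec.fs)
        tmpl_f = butter_zerophase(butter_zerophase(tmpl_rec, "highpass", 2.0, 5), "lowpass", 80.0, 6).data[0]
        best = max(abs(np.corrcoef(tmpl_f, c)[0, 1]) for c in report.sources)
        assert best > 0.9
        card = truth.components["cardiac"][rec.picks("scalp")]
        resid = report.removal_operator() @ card
        att = 10 * np.log10(np.sum(card**2) / np.sum(resid**2))
        assert att >= 15.0

    def test_flagging_all_components_warns(self):
        rec = make_recording(n_channels=8, n_samples=10000, fs=250.0, seed=7)
        with pytest.warns(UserWarning, match="all ICA components"):
            out, _ = ica_denoise(rec, 8, seed=0, flag_rules={"indices": list(range(8))})
        # output collapses to the channel means
        assert out.data.std(axis=1).max() < 0.05 * rec.data.std(axis=1).min()

    def test_more_components_than_channels_rejected(self):
        with pytest.raises(ValueError):
            ica_denoise(make_recording(n_channels=4, n_samples=1000), 10, seed=0)


class TestDetectBadChannels:
    def test_railing_plateau_flagged(self):
        rec = make_recording(n_channels=8, n_samples=5000, fs=250.0, seed=8)
        rec.data[3, 1000:1400] = rec.data[3, 1000]  # 1.6 s constant run
        assert rec.channel_names[3] in detect_bad_channels(rec)

    def test_noisy_channel_flagged(self):
        rec = make_recording(n_channels=8, n_samples=5000, fs=250.0, seed=9)
        rec.data[5] *= 10.0
        assert rec.channel_names[5] in detect_bad_channels(rec)

    def test_clean_session_has_no_bad_channels(self, aef_session_small):
        rec, _ = aef_session_small
        assert detect_bad_channels(rec) == []


class TestDetectArtifactSegments:
    def test_global_step_detected(self):
        rec = make_recording(n_channels=8, n_samples=60000, fs=1000.0, seed=10)
        rec.data *= 0.1
        rec.data[:, 30000:30050] += 8e-12  # 8 pT, 50 ms, all channels
        segs = detect_artifact_segments(rec)
        assert len(segs) == 1
        assert segs[0][0] <= 30.0 <= segs[0][1]

    def test_clean_preprocessed_session_has_no_segments(self, aef_session_small):
        # artifact marking happens after motion regression, HFC and the
        # 2 Hz high-pass (mobile raw data legitimately drifts far more
        # than 5 pT per 100 ms)
        from opmtools.regression import regress_motion

        rec, truth = aef_session_small
        proc, _ = regress_motion(rec, truth.motion)
        proc = apply_hfc(proc)
        proc = butter_zerophase(proc, "highpass", 2.0, 5)
        assert detect_artifact_segments(proc) == []

    def test_infinite_threshold_finds_nothing(self):
        rec = make_recording(n_channels=8, n_samples=10000, fs=1000.0, seed=11)
        assert detect_artifact_segments(rec, jump_threshold=np.inf) == []


class TestProjectorContract:
    def test_projectors_are_symmetric_idempotent(self, small_geom):
        proj = hfc_projector(small_geom.channels)
        P = proj.matrix
        assert np.max(np.abs(P - P.T)) < 1e-10
        assert np.max(np.abs(P @ P - P)) < 1e-8

    def test_apply_projector_matches_manual_multiplication(self, small_geom):
        rec = Recording(list(small_geom.channels),
                        1e-12 * np.random.default_rng(0).standard_normal((24, 1000)), 250.0)
        proj = hfc_projector(small_geom.channels)
        out = apply_projector(rec, proj)
        np.testing.assert_allclose(out.data, proj.matrix @ rec.data, atol=1e-25)
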