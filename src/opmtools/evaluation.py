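"""End-to-end validation scenarios on synthetic sessions.

Each function simulates a session whose ground truth isolates one claim
about the pipeline -- HFC exactness, motion-regression gain, gradiometry
selectivity, spectral-interpolation accuracy, the two preset pipelines,
and estimator calibration -- runs the package on it, and returns the
measured quantities.  The test suite asserts on these numbers; the
acceptance script reports them.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import regression, sensorstats, source, spatial, temporal
from .core import Recording
from .forward import AUDITORY_SOURCES, ArrayGeometry, SphereModel, dual_source_leadfield
from .synth import (
    AEFConfig,
    InterferenceSpec,
    LineSpec,
    TappingConfig,
    simulate_evoked_session,
    simulate_tapping_session,
)

__all__ = [
    "hfc_metrics",
    "motion_regression_metrics",
    "gradiometry_metrics",
    "spectral_interpolation_metrics",
    "aef_pipeline_metrics",
    "tapping_pipeline_metrics",
    "calibration_metrics",
]


def _power_db(before: np.ndarray, after: np.ndarray) -> float:
    denom = max(np.sum(after**2), 1e-300)
    return float(10.0 * np.log10(np.sum(before**2) / denom))


def hfc_metrics(seed: int = 2, n_trials: int = 80) -> dict:
    """Homogeneous-field and brain-signal attenuation of HFC on an
    86-channel dual-axis session carrying a homogeneous drift."""
    cfg = dataclasses.replace(AEFConfig(), n_trials=n_trials, still_until=5.0,
                              interference=InterferenceSpec(lines=()))
    rec, truth = simulate_evoked_session(cfg, seed=seed)
    rows = rec.picks("scalp")
    P = spatial.hfc_projector([rec.channels[i] for i in rows]).matrix
    hom = truth.components["homogeneous"][rows]
    brain = truth.components["brain"][rows]
    return {
        "homogeneous_attenuation_db": _power_db(hom, P @ hom),
        "brain_attenuation_db": _power_db(brain, P @ brain),
        "n_channels": int(rows.size),
    }


def motion_regression_metrics(seed: int = 3, n_trials: int = 80) -> dict:
    """Channel-mean ASD gain below 2 Hz from 6-DOF pose regression on a
    session dominated by movement through the remnant field gradient."""
    spec = InterferenceSpec(homogeneous_peak=5e-12, lines=())
    cfg = dataclasses.replace(AEFConfig(), n_trials=n_trials, still_until=5.0, interference=spec)
    rec, truth = simulate_evoked_session(cfg, seed=seed)
    cleaned, _ = regression.regress_motion(rec, truth.motion)
    rows = rec.picks("scalp")
    p_b = temporal.welch_asd(rec, 10.0)
    p_a = temporal.welch_asd(cleaned, 10.0)
    sel = p_b.freqs < 2.0
    gain = 20.0 * np.log10(p_b.asd[rows][:, sel].mean() / p_a.asd[rows][:, sel].mean())
    return {"gain_below_2hz_db": float(gain), "n_samples": rec.n_samples}


def gradiometry_metrics(seed: int = 4, n_trials: int = 20) -> dict:
    """Selectivity of reference regression: a uniform-field 50 Hz line the
    references see vs a scalp-only 21 Hz line they cannot."""
    lines = (
        LineSpec(21.0, 400e-15, 0.2, reference_visible=False),
        LineSpec(50.0, 1500e-15, 0.1, reference_visible=True, direction=(0.3, 0.7, 0.65)),
    )
    spec = InterferenceSpec(homogeneous_peak=200e-12, lines=lines,
                            gradient_scale=0.0, static_field=0.0)
    cfg = dataclasses.replace(TappingConfig(), n_trials=n_trials, interference=spec,
                              translation_range=0.0005, rotation_range=0.05,
                              blink_rate=0.0, heart_rate=0.0)
    rec, truth = simulate_tapping_session(cfg, seed=seed)
    cleaned, report = regression.synthetic_gradiometry(rec)
    rows, refrows = rec.picks("scalp"), rec.picks("reference")

    # truth accounting for the reference-visible line at its Welch bin
    ln = truth.components["lines"]
    resid = report.apply(ln[rows], regression.gradiometry_regressors(ln, refrows, rec.fs))

    def asd_at(mat: np.ndarray, f: float) -> float:
        r = Recording([rec.channels[i] for i in rows], mat, rec.fs)
        p = temporal.welch_asd(r, 10.0)
        return float(p.asd[:, np.argmin(np.abs(p.freqs - f))].mean())

    att50 = 20.0 * np.log10(asd_at(ln[rows], 50.0) / asd_at(resid, 50.0))
    p_b = temporal.welch_asd(rec, 10.0)
    p_a = temporal.welch_asd(cleaned, 10.0)
    i21 = np.argmin(np.abs(p_b.freqs - 21.0))
    change21 = 20.0 * np.log10(p_b.asd[rows, i21].mean() / p_a.asd[rows, i21].mean())
    return {
        "visible_line_attenuation_db": float(att50),
        "invisible_line_change_db": float(change21),
        "n_samples": rec.n_samples,
    }


def spectral_interpolation_metrics(seed: int = 0) -> dict:
    """50 Hz line suppression to the flanking level with an untouched
    10 Hz probe sine."""
    from .core import ChannelInfo

    rng = np.random.default_rng(seed)
    fs, duration = 1000.0, 60.0
    n = int(fs * duration)
    t = np.arange(n) / fs
    chans = [ChannelInfo(f"C{i}", "scalp", "RAD", np.array([0.1, 0, 0]), np.array([1.0, 0, 0]))
             for i in range(4)]
    data = (2e-12 * np.sin(2 * np.pi * 50.0 * t) + 1e-12 * np.sin(2 * np.pi * 10.0 * t)
            + 335e-15 * rng.standard_normal((4, n)))
    rec = Recording(chans, data, fs)
    out = temporal.spectral_interpolate(rec, [50.0])
    psd = temporal.welch_asd(out, 10.0)
    i50 = np.argmin(np.abs(psd.freqs - 50.0))
    flank = ((psd.freqs >= 48.5) & (psd.freqs < 49.5)) | ((psd.freqs > 50.5) & (psd.freqs <= 51.5))
    ratio = float(psd.asd[:, i50].mean() / psd.asd[:, flank].mean())

    f = np.fft.rfftfreq(n, 1 / fs)
    i10 = np.argmin(np.abs(f - 10.0))
    amp = lambda r: np.abs(np.fft.rfft(r.data, axis=1))[:, i10].mean() * 2 / n
    probe_change_pct = float(100.0 * abs(amp(out) - amp(rec)) / amp(rec))
    return {"line_to_flank_ratio": ratio, "probe_change_pct": probe_change_pct, "n_samples": n}


def aef_pipeline_metrics(seed: int = 5, n_trials: int = 250) -> dict:
    """Full mobile evoked-field pipeline: motion regression, HFC, spectral
    interpolation, 2-40 Hz filtering, epoching, t-statistics, dual-source
    beamforming."""
    cfg = dataclasses.replace(AEFConfig(), n_trials=n_trials, still_until=10.0)
    rec, truth = simulate_evoked_session(cfg, seed=seed)
    events = truth.events

    ep_raw = sensorstats.epoch_by_trigger(rec, events, 0.2, 0.5)
    t_raw, _ = sensorstats.evoked_tstats(ep_raw)

    proc, _ = regression.regress_motion(rec, truth.motion)
    proc = spatial.apply_hfc(proc)
    proc = temporal.spectral_interpolate(proc, [50.0, 100.0, 106.0, 120.0])
    proc = temporal.butter_zerophase(proc, "highpass", 2.0, 5)
    segments = spatial.detect_artifact_segments(proc)
    proc = temporal.butter_zerophase(proc, "lowpass", 40.0, 6)
    ep = sensorstats.epoch_by_trigger(proc, events, 0.2, 0.5)
    ep = sensorstats.reject_artifact_trials(ep, segments)
    t_proc, _ = sensorstats.evoked_tstats(ep)

    peak = np.unravel_index(np.nanargmax(np.abs(t_proc)), t_proc.shape)
    latency_ms = float(ep.times[peak[1]] * 1000.0)
    snr_gain = sensorstats.snr_gain_db(t_raw, t_proc, ep.times, (0.08, 0.12))

    geom = ArrayGeometry([c for c in proc.channels if c.kind == "scalp"])
    L = dual_source_leadfield(geom, SphereModel(), list(AUDITORY_SOURCES))
    cov, rank = source.epoch_covariance(ep, (0.0, 0.5))
    w = source.lcmv_weights(L, cov, 0.001, ep.channel_names, rank)
    vc = source.virtual_channel(w, ep, 0, sign_window=(0.05, 0.15)).mean(axis=0)
    wave = truth.sources["evoked_waveform"]
    target = np.zeros_like(ep.times)
    idx = (ep.times >= 0) & (ep.times < 0.4)
    target[idx] = wave[: idx.sum()]
    corr = float(abs(np.corrcoef(vc, target)[0, 1]))
    return {
        "evoked_peak_latency_ms": latency_ms,
        "snr_gain_db": float(snr_gain),
        "dual_source_corr": corr,
        "n_trials": ep.n_trials,
    }


def tapping_pipeline_metrics(seed: int = 3, n_trials: int = 20) -> dict:
    """Full finger-tapping pipeline: spectral interpolation, 2-80 Hz
    filtering, synthetic gradiometry, HFC, ICA, TFR with dB baseline."""
    cfg = dataclasses.replace(TappingConfig(), n_trials=n_trials)
    rec, truth = simulate_tapping_session(cfg, seed=seed)
    proc = temporal.spectral_interpolate(rec, [21.0, 83.0, 100.0])
    proc = temporal.butter_zerophase(proc, "highpass", 2.0, 5)
    proc = temporal.butter_zerophase(proc, "lowpass", 80.0, 6)
    proc, _ = regression.synthetic_gradiometry(proc)
    proc = spatial.apply_hfc(proc)
    tmpl = truth.sources["cardiac_source"]
    proc, ica_report = spatial.ica_denoise(
        proc, 50, 454, {"low_freq": True, "templates": {"cardiac": tmpl}}
    )

    rows = rec.picks("scalp")
    P = spatial.hfc_projector([rec.channels[i] for i in rows]).matrix
    cardiac = P @ truth.components["cardiac"][rows]
    ica_att = _power_db(cardiac, ica_report.removal_operator() @ cardiac)

    ep = sensorstats.epoch_by_trigger(proc, truth.events, 2.0, 6.0)
    tfr = sensorstats.tfr_hanning(ep)
    tfr_db = sensorstats.baseline_db(tfr, (-1.5, 0.0))
    beta = (tfr.freqs >= 13.0) & (tfr.freqs <= 30.0)
    erd_w = (tfr.times >= 0.0) & (tfr.times <= 2.5)
    pmbr_w = (tfr.times >= 2.8) & (tfr.times <= 4.0)
    mod = tfr_db.power[:, beta, :][:, :, erd_w].mean(axis=(1, 2))
    left = [i for i, nm in enumerate(ep.channel_names)
            if rec.channels[rec.index_of(nm)].position[0] < 0]
    best = left[int(np.argmin(mod[left]))]
    erd_db = float(tfr_db.power[best][beta][:, erd_w].mean())
    pmbr_db = float(tfr_db.power[best][beta][:, pmbr_w].mean())
    return {
        "erd_db": erd_db,
        "pmbr_db": pmbr_db,
        "ica_cardiac_attenuation_db": float(ica_att),
        "best_sensor": ep.channel_names[best],
        "n_trials": ep.n_trials,
    }


def calibration_metrics(seed: int = 1) -> dict:
    """Estimator calibration: the white-noise ASD identity and the
    two-sided 5% exceedance of null-trial t-statistics."""
    from .forward import build_array_geometry
    from .synth import simulate_interference

    geom = build_array_geometry(12, "dual")
    spec = InterferenceSpec(homogeneous_peak=0.0, static_field=0.0, gradient_scale=0.0,
                            lines=(), sensor_noise_asd=15.0)
    comps, _ = simulate_interference(geom, spec, None, 60.0, 1000.0, seed=seed)
    rec = Recording(list(geom.channels), comps["sensor_noise"], 1000.0)
    psd = temporal.welch_asd(rec, 10.0)
    band = (psd.freqs >= 10.0) & (psd.freqs <= 100.0)
    measured_asd = float(np.median(psd.asd[:, band]))

    rng = np.random.default_rng(seed + 1000)
    n_trials, n_ch, n_t = 100, 100, 1000  # 1e5 channel x time points
    data = rng.standard_normal((n_trials, n_ch, n_t))
    times = np.arange(n_t) / 1000.0
    ep = sensorstats.Epochs(data=data, times=times, channel_names=[f"c{i}" for i in range(n_ch)],
                            fs=1000.0, codes=["x"] * n_trials, onsets=np.arange(n_trials) * n_t)
    t, _ = sensorstats.evoked_tstats(ep, baseline=None)
    exceedance_pct = float(100.0 * np.mean(np.abs(t) > 1.96))
    return {
        "white_noise_asd_ft": measured_asd,
        "null_t_exceedance_pct": exceedance_pct,
        "n_points": n_ch * n_t,
    }
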