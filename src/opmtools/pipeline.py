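"""Config-driven pipeline orchestration with per-stage snapshots.

A pipeline is an ordered list of named stages with parameters (YAML or
dict).  After every stage that changes the recording, the channel-mean
amplitude spectral density and the per-second maximum field change are
written to the run directory, so the gradual removal of interference can
be tabulated stage by stage (ASD gains in dB between consecutive stages).

Manual study choices -- bad channels, artifact spans, ICA component
indices -- are representable as explicit config lists, so a pipeline can
either run the automated detectors or inject curated selections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core, regression, sensorstats, source, spatial, temporal
from .core import EventTable, MotionTrace, Recording
from .forward import AUDITORY_SOURCES, SphereModel, ArrayGeometry, dual_source_leadfield

__all__ = ["PipelineConfig", "run_pipeline", "stage_report", "STAGE_REGISTRY"]


@dataclass
class PipelineContext:
    recording: Recording
    motion: MotionTrace | None = None
    events: EventTable | None = None
    epochs: sensorstats.Epochs | None = None
    segments: list[tuple[float, float]] = field(default_factory=list)
    tstats: np.ndarray | None = None
    evoked: np.ndarray | None = None
    tfr: sensorstats.TFR | None = None
    virtual: np.ndarray | None = None
    extras: dict = field(default_factory=dict)
    seed: int = 0


# --- stage implementations -------------------------------------------------

def _st_resample(ctx: PipelineContext, fs_new: float) -> None:
    fs_old = ctx.recording.fs
    ctx.recording = core.resample(ctx.recording, fs_new)
    if ctx.events is not None:
        onsets = np.round(ctx.events.onset_sample * fs_new / fs_old).astype(int)
        ctx.events = EventTable(onsets, list(ctx.events.code))


def _st_sync_motion(ctx: PipelineContext, trigger_channel: str = "FluxZ-A") -> None:
    if ctx.motion is None:
        raise ValueError("no motion trace loaded")
    ctx.motion = core.sync_and_upsample_motion(ctx.motion, ctx.recording, trigger_channel)


def _st_condition_motion(ctx: PipelineContext, lowpass: float = 2.0, order: int = 4) -> None:
    """Low-pass the pose trajectories bidirectionally (marker jitter guard)."""
    import scipy.signal

    if ctx.motion is None:
        raise ValueError("no motion trace loaded")
    fs = 1.0 / np.median(np.diff(ctx.motion.time))
    sos = scipy.signal.butter(order, lowpass, "lowpass", fs=fs, output="sos")
    pose = scipy.signal.sosfiltfilt(sos, ctx.motion.pose, axis=0)
    ctx.motion = MotionTrace(ctx.motion.time, pose[:, :3], pose[:, 3:], ctx.motion.euler_order)


def _st_regress_motion(ctx: PipelineContext, window_s: float = 10.0, overlap: float = 0.5) -> None:
    if ctx.motion is None:
        raise ValueError("no motion trace loaded")
    ctx.recording, report = regression.regress_motion(ctx.recording, ctx.motion, window_s, overlap)
    ctx.extras["motion_regression"] = report


def _st_hfc(ctx: PipelineContext, scope: str = "scalp_only") -> None:
    ctx.recording = spatial.apply_hfc(ctx.recording, scope)


def _st_drop_bad_channels(ctx: PipelineContext, names: list[str] | None = None, **detector_kw) -> None:
    bad = list(names) if names else spatial.detect_bad_channels(ctx.recording, **detector_kw)
    ctx.extras["bad_channels"] = bad
    if bad:
        ctx.recording = core.drop_channels(ctx.recording, bad)


def _st_spectral_interpolate(ctx: PipelineContext, targets: list[float], halfwidth: float = 0.5,
                             neighbour_width: float = 1.0) -> None:
    ctx.recording = temporal.spectral_interpolate(ctx.recording, targets, halfwidth, neighbour_width)


def _st_highpass(ctx: PipelineContext, cutoff: float = 2.0, order: int = 5) -> None:
    ctx.recording = temporal.butter_zerophase(ctx.recording, "highpass", cutoff, order)


def _st_lowpass(ctx: PipelineContext, cutoff: float = 40.0, order: int = 6) -> None:
    ctx.recording = temporal.butter_zerophase(ctx.recording, "lowpass", cutoff, order)


def _st_detrend(ctx: PipelineContext, **kw) -> None:
    ctx.recording = temporal.detrend_windowed(ctx.recording, **kw)


def _st_artifact_segments(ctx: PipelineContext, segments: list | None = None, **detector_kw) -> None:
    if segments is not None:
        ctx.segments = [tuple(s) for s in segments]
    else:
        ctx.segments = spatial.detect_artifact_segments(ctx.recording, **detector_kw)


def _st_gradiometry(ctx: PipelineContext, reference_names: list[str] | None = None,
                    bands: list = [(2.0, 20.0), (20.0, 80.0)], window_s: float = 100.0,
                    overlap: float = 0.5) -> None:
    bands = [tuple(b) for b in bands]
    ctx.recording, report = regression.synthetic_gradiometry(
        ctx.recording, reference_names, bands, window_s, overlap
    )
    ctx.extras["gradiometry"] = report


def _st_ica(ctx: PipelineContext, n_components: int = 50, seed: int | None = None,
            flag_rules: dict | None = None) -> None:
    ctx.recording, report = spatial.ica_denoise(
        ctx.recording, n_components, seed if seed is not None else 454, flag_rules
    )
    ctx.extras["ica"] = report


def _st_epoch(ctx: PipelineContext, t_pre: float, t_post: float) -> None:
    if ctx.events is None:
        raise ValueError("no events loaded")
    ctx.epochs = sensorstats.epoch_by_trigger(ctx.recording, ctx.events, t_pre, t_post)


def _st_reject_trials(ctx: PipelineContext) -> None:
    if ctx.epochs is None:
        raise ValueError("epoch before rejecting trials")
    ctx.epochs = sensorstats.reject_artifact_trials(ctx.epochs, ctx.segments)


def _st_evoked_tstats(ctx: PipelineContext, baseline: tuple = (-0.1, 0.0)) -> None:
    if ctx.epochs is None:
        raise ValueError("epoch before evoked statistics")
    ctx.tstats, ctx.evoked = sensorstats.evoked_tstats(ctx.epochs, tuple(baseline))


def _st_beamform(ctx: PipelineContext, sources: str | list = "preset_auditory",
                 lambda_fraction: float = 0.001, cov_window: tuple = (0.0, 0.5),
                 source_index: int = 0, sign_window: tuple = (0.05, 0.15)) -> None:
    if ctx.epochs is None:
        raise ValueError("epoch before beamforming")
    if sources == "preset_auditory":
        positions = list(AUDITORY_SOURCES)
    else:
        positions = [np.asarray(p, dtype=float) for p in sources]
    chans = [c for c in ctx.recording.channels if c.name in set(ctx.epochs.channel_names)]
    geom = ArrayGeometry([c for c in chans if c.kind == "scalp"])
    L = dual_source_leadfield(geom, SphereModel(), positions)
    cov, rank = source.epoch_covariance(ctx.epochs, tuple(cov_window))
    w = source.lcmv_weights(L, cov, lambda_fraction, ctx.epochs.channel_names, rank)
    ctx.virtual = source.virtual_channel(w, ctx.epochs, source_index, sign_window=tuple(sign_window))
    ctx.extras["beamformer"] = w


def _st_tfr(ctx: PipelineContext, f_lo: float = 1.0, f_hi: float = 41.0, f_step: float = 2.0,
            window_s: float = 0.5, trim_s: float = 0.5) -> None:
    if ctx.epochs is None:
        raise ValueError("epoch before TFR")
    ctx.tfr = sensorstats.tfr_hanning(ctx.epochs, np.arange(f_lo, f_hi + 1e-9, f_step),
                                      window_s=window_s, trim_s=trim_s)


def _st_baseline_db(ctx: PipelineContext, baseline: tuple = (-1.5, 0.0)) -> None:
    if ctx.tfr is None:
        raise ValueError("compute a TFR before baseline correction")
    ctx.tfr = sensorstats.baseline_db(ctx.tfr, tuple(baseline))


STAGE_REGISTRY = {
    "resample": _st_resample,
    "sync_motion": _st_sync_motion,
    "condition_motion": _st_condition_motion,
    "regress_motion": _st_regress_motion,
    "hfc": _st_hfc,
    "drop_bad_channels": _st_drop_bad_channels,
    "spectral_interpolate": _st_spectral_interpolate,
    "highpass": _st_highpass,
    "lowpass": _st_lowpass,
    "detrend": _st_detrend,
    "artifact_segments": _st_artifact_segments,
    "synthetic_gradiometry": _st_gradiometry,
    "ica": _st_ica,
    "epoch": _st_epoch,
    "reject_trials": _st_reject_trials,
    "evoked_tstats": _st_evoked_tstats,
    "beamform": _st_beamform,
    "tfr": _st_tfr,
    "baseline_db": _st_baseline_db,
}

# stages after which the continuous recording is snapshot-compared
_RECORDING_STAGES = {
    "resample", "regress_motion", "hfc", "drop_bad_channels", "spectral_interpolate",
    "highpass", "lowpass", "detrend", "synthetic_gradiometry", "ica",
}


@dataclass
class PipelineConfig:
    stages: list[dict]
    seed: int = 0
    snapshots: bool = True
    recording_path: str | None = None
    motion_path: str | None = None
    events_path: str | None = None

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("pipeline has no stages")
        for st in self.stages:
            if "name" not in st:
                raise ValueError(f"stage entry without a name: {st}")
            if st["name"] not in STAGE_REGISTRY:
                raise ValueError(f"unknown stage {st['name']!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


def _snapshot(ctx: PipelineContext, out_dir: Path, idx: int, name: str, save_recording: bool) -> dict:
    rec = ctx.recording
    window = min(10.0, rec.duration / 2)
    psd = temporal.welch_asd(rec, window_s=window)
    mfc = temporal.max_field_change(rec) if rec.duration >= 1.0 else np.array([])
    tag = f"{idx:02d}_{name}"
    pd.DataFrame({"freq_hz": psd.freqs, "mean_asd_ft_sqrthz": psd.channel_mean()}).to_csv(
        out_dir / f"asd_{tag}.tsv", sep="\t", index=False
    )
    pd.DataFrame({"chunk_s": np.arange(mfc.size), "max_field_change_pt": mfc}).to_csv(
        out_dir / f"mfc_{tag}.tsv", sep="\t", index=False
    )
    if save_recording:
        core.write_recording(rec, out_dir / f"recording_{tag}")
    return {"stage": name, "index": idx, "psd": psd, "mfc": mfc}


def run_pipeline(
    config: PipelineConfig | dict | str | Path,
    out_dir: str | Path,
    recording: Recording | None = None,
    motion: MotionTrace | None = None,
    events: EventTable | None = None,
    save_recordings: bool = False,
) -> Path:
    """Execute the configured stages in order; returns the run directory.

    Inputs may be given as in-memory objects or as paths in the config.
    The run directory receives per-stage ASD / max-field-change tables, a
    ``report.tsv`` with stage-over-stage gains, and a JSON log.
    """
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig(**config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if recording is None:
        if not config.recording_path:
            raise ValueError("no recording provided")
        recording = core.read_recording(config.recording_path)
    if motion is None and config.motion_path:
        motion = core.read_motion_csv(config.motion_path)
    if events is None and config.events_path:
        events = core.read_events(config.events_path)

    ctx = PipelineContext(recording=recording, motion=motion, events=events, seed=config.seed)
    log: list[dict] = []
    snaps = []
    if config.snapshots:
        snaps.append(_snapshot(ctx, out, 0, "raw", save_recordings))
    for idx, stage in enumerate(config.stages, start=1):
        name = stage["name"]
        params = {k: v for k, v in stage.items() if k != "name"}
        try:
            STAGE_REGISTRY[name](ctx, **params)
        except Exception as err:
            raise RuntimeError(f"stage {idx} ({name}) failed: {err}") from err
        log.append({"index": idx, "stage": name, "params": params})
        if config.snapshots and name in _RECORDING_STAGES:
            snaps.append(_snapshot(ctx, out, idx, name, save_recordings))

    # stage-over-stage report
    rows = []
    for prev, cur in zip(snaps, snaps[1:]):
        if prev["psd"].asd.shape != cur["psd"].asd.shape:
            rows.append({"stage": cur["stage"], "mean_gain_db": np.nan,
                         "median_mfc_pt": float(np.median(cur["mfc"])) if cur["mfc"].size else np.nan})
            continue
        g = temporal.gain_db(prev["psd"], cur["psd"])
        rows.append({
            "stage": cur["stage"],
            "mean_gain_db": float(np.nanmean(g[np.isfinite(g)])),
            "median_mfc_pt": float(np.median(cur["mfc"])) if cur["mfc"].size else np.nan,
        })
    pd.DataFrame(rows).to_csv(out / "report.tsv", sep="\t", index=False)

    results: dict = {"seed": config.seed, "stages": log}
    if ctx.extras.get("bad_channels") is not None:
        results["bad_channels"] = ctx.extras["bad_channels"]
    if ctx.epochs is not None:
        results["n_trials"] = ctx.epochs.n_trials
        results["n_trials_rejected"] = len(ctx.epochs.rejected)
    (out / "log.json").write_text(json.dumps(results, indent=1, default=str))

    if ctx.tstats is not None:
        np.savetxt(out / "tstats.tsv", ctx.tstats, delimiter="\t")
    if ctx.virtual is not None:
        np.savetxt(out / "virtual_channel.tsv", np.atleast_2d(ctx.virtual), delimiter="\t")
    ctx.extras["snapshots"] = snaps
    run_pipeline.last_context = ctx  # inspection hook for library callers
    return out


def stage_report(run_dir: str | Path) -> pd.DataFrame:
    """Read back the per-stage gain/field-change table of a completed run."""
    path = Path(run_dir) / "report.tsv"
    if not path.exists():
        raise FileNotFoundError(f"no report.tsv under {run_dir} (incomplete run?)")
    return pd.read_csv(path, sep="\t")
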