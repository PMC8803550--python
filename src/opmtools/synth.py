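"""Synthetic OPM-MEG sessions with exact per-component ground truth.

The simulator emulates the interference structure of wearable OPM
recordings in a shielded room:

* a spatially homogeneous low-frequency field drift ``B0(t)`` seen
  identically (through each sensitive axis) by scalp and reference sensors;
* movement-coupled artifacts from the rigid head+array moving through a
  static remnant field ``B_c + G·r`` (references stay fixed in the room);
* narrow-band interferers (mains harmonics, camera LEDs, unknown sources)
  with slow amplitude drift, each with a fixed spatial coupling that is
  either a uniform field (visible to references) or scalp-only (invisible);
* white sensor noise at the magnetometer noise floor (15 fT/rtHz);
* optional blink and cardiac artifact trains;
* dipolar brain sources: a bilateral correlated auditory evoked response
  (M100-like, ~220 fT at the sensors) or a left sensorimotor beta-band
  oscillation with movement-related suppression and post-movement rebound.

Every component is stored channel-by-sample in a :class:`SimulationTruth`
sidecar, and the emitted recording is exactly (bitwise) the sum of the
stored components, which makes per-stage attenuation accounting exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import scipy.signal
from scipy.spatial.transform import Rotation

from .core import ChannelInfo, EventTable, MotionTrace, Recording, write_events, write_motion_csv, write_recording
from .forward import (
    AUDITORY_SOURCES,
    SENSORIMOTOR_SOURCE,
    ArrayGeometry,
    SphereModel,
    build_array_geometry,
    default_reference_channels,
    sarvas_leadfield,
)

__all__ = [
    "LineSpec",
    "InterferenceSpec",
    "SimulationTruth",
    "AEFConfig",
    "TappingConfig",
    "simulate_motion_trajectory",
    "simulate_interference",
    "simulate_evoked_session",
    "simulate_tapping_session",
    "inject_physiological_artifacts",
    "aef_event_onsets",
    "tapping_event_onsets",
    "write_session",
]


@dataclass(frozen=True)
class LineSpec:
    """One narrow-band interferer.

    ``amplitude`` is the peak field in tesla at the best-coupled channel;
    ``drift`` is the fractional slow amplitude modulation.  A
    ``reference_visible`` line couples as a spatially uniform field (so the
    off-head references see it); otherwise the coupling is a fixed random
    scalp-only vector.
    """

    freq: float
    amplitude: float
    drift: float = 0.1
    reference_visible: bool = True
    direction: tuple[float, float, float] | None = None  # fix the field direction of a visible line


@dataclass(frozen=True)
class InterferenceSpec:
    homogeneous_peak: float = 500e-12  # peak |B0(t)|, tesla
    homogeneous_cutoff: float = 5.0  # Hz; B0 band limit
    static_field: float = 2e-9  # |B_c| of the remnant field, tesla
    gradient_scale: float = 1.5e-9  # remnant gradient ||G||, tesla/metre
    lines: tuple[LineSpec, ...] = ()
    sensor_noise_asd: float = 15.0  # fT/rtHz

    def __post_init__(self):
        if min(self.homogeneous_peak, self.static_field, self.gradient_scale, self.sensor_noise_asd, 0.0) < 0:
            raise ValueError("interference amplitudes must be non-negative")


AEF_LINES = (
    LineSpec(21.0, 400e-15, 0.2, reference_visible=False),
    LineSpec(50.0, 1500e-15, 0.1, reference_visible=True),
    LineSpec(100.0, 400e-15, 0.1, reference_visible=True),
    LineSpec(106.0, 250e-15, 0.2, reference_visible=False),
    LineSpec(120.0, 500e-15, 0.2, reference_visible=False),
)

TAPPING_LINES = (
    LineSpec(21.0, 400e-15, 0.2, reference_visible=False),
    LineSpec(41.5, 250e-15, 0.2, reference_visible=False),
    LineSpec(50.0, 1500e-15, 0.1, reference_visible=True),
    LineSpec(83.0, 250e-15, 0.2, reference_visible=False),
    LineSpec(100.0, 400e-15, 0.1, reference_visible=True),
)


@dataclass
class SimulationTruth:
    """Per-component ground truth; components sum exactly to the data."""

    components: dict[str, np.ndarray]
    sources: dict[str, np.ndarray] = dfield(default_factory=dict)
    motion: MotionTrace | None = None
    events: EventTable | None = None
    meta: dict = dfield(default_factory=dict)

    def sum_components(self) -> np.ndarray:
        names = list(self.components)
        total = np.zeros_like(self.components[names[0]])
        for name in names:
            total = total + self.components[name]
        return total


# ---------------------------------------------------------------------------
# Motion
# ---------------------------------------------------------------------------

def _smooth_random_walk(n: int, fs: float, cutoff: float, rng: np.random.Generator, n_comp: int = 24) -> np.ndarray:
    """Zero-mean band-limited (< cutoff) random trace with 1/f weighting."""
    t = np.arange(n) / fs
    freqs = rng.uniform(0.03, cutoff * 0.75, n_comp)
    phases = rng.uniform(0, 2 * np.pi, n_comp)
    amps = 1.0 / (freqs + 0.05)
    amps *= rng.uniform(0.5, 1.0, n_comp)
    x = (amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])).sum(axis=0)
    return x - x[0]


def simulate_motion_trajectory(
    duration: float,
    fs: float,
    still_until: float = 0.0,
    translation_range: float = 1.0,
    rotation_range: float = 8.0,
    seed: int | np.random.Generator = 0,
) -> MotionTrace:
    """Smooth random 6-DOF head path, still before ``still_until``.

    The path is band-limited below 2 Hz; each translation axis is rescaled
    so its max-min range equals ``translation_range`` metres (rotations
    likewise to ``rotation_range`` degrees).
    """
    if translation_range < 0 or rotation_range < 0:
        raise ValueError("ranges must be non-negative")
    if not duration > still_until >= 0:
        raise ValueError("need duration > still_until >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    # smooth onset mask: zero while still, raised-cosine ramp over 2 s
    ramp = 2.0
    mask = np.clip((t - still_until) / ramp, 0.0, 1.0)
    mask = 0.5 - 0.5 * np.cos(np.pi * mask)
    pose = np.zeros((n, 6))
    targets = [translation_range] * 3 + [rotation_range] * 3
    for j in range(6):
        x = _smooth_random_walk(n, fs, 2.0, rng) * mask
        ptp = x.max() - x.min()
        if ptp > 0:
            x *= targets[j] / ptp
        pose[:, j] = x
    return MotionTrace(t, pose[:, :3], pose[:, 3:])


def _pose_on_grid(motion: MotionTrace, n: int, fs: float) -> np.ndarray:
    t = np.arange(n) / fs
    if motion.time[-1] < t[-1] - 1e-9:
        raise ValueError("motion trace shorter than requested duration")
    return np.column_stack([np.interp(t, motion.time, motion.pose[:, j]) for j in range(6)])


# ---------------------------------------------------------------------------
# Interference
# ---------------------------------------------------------------------------

def _random_traceless_symmetric(rng: np.random.Generator) -> np.ndarray:
    a = rng.standard_normal((3, 3))
    g = (a + a.T) / 2.0
    g -= np.trace(g) / 3.0 * np.eye(3)
    return g / np.linalg.norm(g)


def simulate_interference(
    geom: ArrayGeometry,
    spec: InterferenceSpec,
    motion: MotionTrace | None,
    duration: float,
    fs: float,
    seed: int | np.random.Generator = 0,
    reference_channels: list[ChannelInfo] | None = None,
) -> tuple[dict[str, np.ndarray], dict]:
    """Generate the interference components over scalp + reference channels.

    Returns ``(components, info)`` where components maps
    ``homogeneous / gradient_motion / lines / sensor_noise`` to
    (n_channels x n_samples) matrices (reference rows appended after scalp
    rows) and ``info`` carries the underlying field parameters.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    refs = reference_channels or []
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    all_ori = np.vstack([geom.orientations, np.stack([c.orientation for c in refs])]) if refs else geom.orientations
    n_scalp = geom.n_channels
    n_ch = n_scalp + len(refs)

    # (a) homogeneous drift: identical field vector everywhere
    b0 = np.stack([_smooth_random_walk(n, fs, spec.homogeneous_cutoff, rng) for _ in range(3)])
    norm = np.linalg.norm(b0, axis=0)
    if norm.max() > 0:
        b0 *= spec.homogeneous_peak / norm.max()
    homogeneous = all_ori @ b0

    # (b) rigid-body motion through the static remnant field B_c + G r
    gradient_motion = np.zeros((n_ch, n))
    bc_dir = rng.standard_normal(3)
    bc = spec.static_field * bc_dir / np.linalg.norm(bc_dir)
    G = spec.gradient_scale * _random_traceless_symmetric(rng)
    if motion is not None:
        pose = _pose_on_grid(motion, n, fs)
        if np.any(pose != 0.0):
            rot = Rotation.from_euler("ZYX", pose[:, 3:], degrees=True)
            trans = pose[:, :3]
            for i in range(n_scalp):
                p, o = geom.positions[i], geom.orientations[i]
                o_t = rot.apply(o)  # (n, 3)
                r_t = rot.apply(p) + trans
                field = bc[None, :] + r_t @ G.T
                sig = np.einsum("ij,ij->i", o_t, field)
                gradient_motion[i] = sig - (o @ (bc + G @ p))

    # (c) narrow-band interferers with slow amplitude drift
    lines = np.zeros((n_ch, n))
    line_info = []
    for line in spec.lines:
        phase = rng.uniform(0, 2 * np.pi)
        drift = 1.0 + line.drift * _smooth_random_walk(n, fs, 0.2, rng) / 3.0
        carrier = np.sin(2 * np.pi * line.freq * t + phase) * drift
        if line.reference_visible:
            d = np.asarray(line.direction, float) if line.direction is not None else rng.standard_normal(3)
            d = d / np.linalg.norm(d)
            coupling = all_ori @ d
        else:
            coupling = np.zeros(n_ch)
            c = rng.standard_normal(n_scalp)
            coupling[:n_scalp] = c / np.max(np.abs(c))
        lines += line.amplitude * coupling[:, None] * carrier[None, :]
        line_info.append({"freq": line.freq, "coupling": coupling, "visible": line.reference_visible})

    # (d) white sensor noise, independent per channel
    sigma = spec.sensor_noise_asd * 1e-15 * np.sqrt(fs / 2.0)
    sensor_noise = sigma * rng.standard_normal((n_ch, n))

    components = {
        "homogeneous": homogeneous,
        "gradient_motion": gradient_motion,
        "lines": lines,
        "sensor_noise": sensor_noise,
    }
    info = {"b0": b0, "bc": bc, "G": G, "lines": line_info}
    return components, info


# ---------------------------------------------------------------------------
# Session presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AEFConfig:
    """Mobile auditory-evoked-field session (participant moving freely)."""

    n_sensors: int = 43
    axes: str = "dual"
    fs: float = 1000.0
    n_trials: int = 570
    isi: float = 0.5
    still_until: float = 34.0
    tail: float = 1.0
    amplitude_target: float = 220e-15  # peak evoked sensor field, tesla
    translation_range: float = 1.0
    rotation_range: float = 8.0
    interference: InterferenceSpec = InterferenceSpec(lines=AEF_LINES)
    include_references: bool = True

    @property
    def duration(self) -> float:
        return self.still_until + self.n_trials * self.isi + self.tail


@dataclass(frozen=True)
class TappingConfig:
    """Stationary finger-tapping session with beta-band modulation."""

    n_sensors: int = 39
    axes: str = "dual"
    fs: float = 1000.0
    n_trials: int = 100
    iti_range: tuple[float, float] = (7.0, 8.0)
    lead_in: float = 5.0
    tail: float = 6.5
    erd_factor: float = 0.5
    pmbr_factor: float = 1.5
    tap_duration: float = 2.5
    pmbr_window: tuple[float, float] = (2.8, 4.0)
    beta_sensor_amplitude: float = 60e-15  # baseline beta sigma at best channel
    translation_range: float = 0.002  # residual involuntary motion, metres
    rotation_range: float = 0.2  # degrees
    interference: InterferenceSpec = InterferenceSpec(lines=TAPPING_LINES)
    include_references: bool = True
    blink_rate: float = 10.0  # per minute
    heart_rate: float = 66.0  # bpm

    def __post_init__(self):
        if self.erd_factor < 0:
            raise ValueError("erd_factor must be non-negative")


def aef_event_onsets(config: AEFConfig) -> np.ndarray:
    """Tone-onset samples: fixed inter-stimulus interval after the still period."""
    if config.n_trials < 1:
        raise ValueError("need at least one trial")
    onsets = config.still_until + config.isi * np.arange(config.n_trials)
    return np.round(onsets * config.fs).astype(int)


def tapping_event_onsets(config: TappingConfig, rng: np.random.Generator) -> np.ndarray:
    """Cue-onset samples with a uniformly jittered 7-8 s inter-trial interval."""
    if config.n_trials < 1:
        raise ValueError("need at least one trial")
    itis = rng.uniform(*config.iti_range, size=config.n_trials - 1)
    onsets = config.lead_in + np.concatenate([[0.0], np.cumsum(itis)])
    return np.round(onsets * config.fs).astype(int)


def _evoked_waveform(fs: float, peak_t: float = 0.100, trough_t: float = 0.180) -> np.ndarray:
    """Biphasic M100-like waveform on [0, 0.4] s, unit peak at ``peak_t``."""
    t = np.arange(int(round(0.4 * fs))) / fs
    w = np.exp(-((t - peak_t) ** 2) / (2 * 0.015**2)) - 0.6 * np.exp(-((t - trough_t) ** 2) / (2 * 0.03**2))
    return w / np.max(np.abs(w))


def _session_channels(geom: ArrayGeometry, refs: list[ChannelInfo], triggers: list[str]) -> list[ChannelInfo]:
    chans = list(geom.channels) + list(refs)
    chans += [ChannelInfo(name, "trigger") for name in triggers]
    return chans


def _tangential_moment(source: np.ndarray, sphere: SphereModel) -> np.ndarray:
    """Unit dipole moment: the tangential direction closest to superior
    (+z), the typical orientation of auditory/sensorimotor sources."""
    r0 = source - sphere.centre
    m = np.cross(np.cross(r0, [0.0, 0.0, 1.0]), r0)
    if np.linalg.norm(m) < 1e-12:  # source on the z axis
        m = np.cross(np.cross(r0, [1.0, 0.0, 0.0]), r0)
    return m / np.linalg.norm(m)


def _pulse_train(n: int, onsets: np.ndarray, fs: float, width_s: float = 0.01, amp: float = 1.0) -> np.ndarray:
    x = np.zeros(n)
    w = max(1, int(round(width_s * fs)))
    for o in onsets:
        x[o : min(n, o + w)] = amp
    return x


def _assemble(
    channels: list[ChannelInfo],
    components: dict[str, np.ndarray],
    fs: float,
    step: str,
    params: dict,
) -> Recording:
    names = list(components)
    data = np.zeros_like(components[names[0]])
    for name in names:
        data = data + components[name]
    return Recording(channels, data, fs, history=[{"step": step, **params}])


def simulate_evoked_session(
    config: AEFConfig = AEFConfig(), seed: int = 0
) -> tuple[Recording, SimulationTruth]:
    """Simulate the mobile auditory-evoked-field session.

    Bilateral correlated dipoles emit an M100-like biphasic response to
    each tone; the participant is still during the lead-in and then moves
    continuously; interference follows ``config.interference``.  Trigger
    channels: ``NI-TRIG`` (tone onsets) and ``FluxZ-A`` (motion sync pulse
    at t=0).
    """
    if config.amplitude_target <= 0:
        raise ValueError("amplitude_target must be positive")
    rng = np.random.default_rng(seed)
    geom = build_array_geometry(config.n_sensors, config.axes)
    sphere = SphereModel()
    refs = default_reference_channels() if config.include_references else []
    channels = _session_channels(geom, refs, ["NI-TRIG", "FluxZ-A"])
    n_ch = len(channels)
    n = int(round(config.duration * config.fs))
    n_scalp_ref = geom.n_channels + len(refs)

    motion = simulate_motion_trajectory(
        config.duration, config.fs, config.still_until, config.translation_range, config.rotation_range, rng
    )
    interference, info = simulate_interference(
        geom, config.interference, motion, config.duration, config.fs, rng, refs
    )

    onsets = aef_event_onsets(config)
    events = EventTable(onsets, ["tone"] * len(onsets))

    # brain: both auditory dipoles driven by the same waveform (correlated)
    wave = _evoked_waveform(config.fs)
    session_wave = np.zeros(n)
    for o in onsets:
        stop = min(n, o + wave.size)
        session_wave[o:stop] += wave[: stop - o]
    pattern = np.zeros(geom.n_channels)
    for src in AUDITORY_SOURCES:
        L = sarvas_leadfield(geom, sphere, src).matrix
        pattern = pattern + L @ _tangential_moment(src, sphere)
    scale = config.amplitude_target / np.max(np.abs(pattern))
    pattern = pattern * scale
    brain = np.zeros((n_ch, n))
    brain[: geom.n_channels] = pattern[:, None] * session_wave[None, :]

    components: dict[str, np.ndarray] = {"brain": brain}
    for name, comp in interference.items():
        full = np.zeros((n_ch, n))
        full[:n_scalp_ref] = comp
        components[name] = full
    trig = np.zeros((n_ch, n))
    trig[-2] = _pulse_train(n, onsets, config.fs, amp=1.0)
    trig[-1] = _pulse_train(n, np.array([0]), config.fs, amp=1.0)
    components["trigger"] = trig

    rec = _assemble(channels, components, config.fs, "simulate_evoked_session", {"seed": seed})
    truth = SimulationTruth(
        components=components,
        sources={"evoked_waveform": wave, "session_waveform": session_wave, "sensor_pattern": pattern},
        motion=motion,
        events=events,
        meta={"config": config, "interference": info, "sphere": sphere},
    )
    return rec, truth


def _beta_envelope(n: int, fs: float, onsets: np.ndarray, config: TappingConfig) -> np.ndarray:
    """Trial envelope: 1 at baseline, erd_factor while tapping, pmbr_factor
    in the rebound window; 0.2 s raised-cosine transitions."""
    t = np.arange(n) / fs
    env = np.ones(n)

    def blend(target: float, start: float, stop: float) -> None:
        # raised-cosine edges of 0.2 s centred on start/stop
        half = 0.1
        lo, hi = start - half, stop + half
        seg = (t >= lo) & (t <= hi)
        ts = t[seg]
        w = np.ones_like(ts)
        rise = ts < start + half
        w[rise] = 0.5 - 0.5 * np.cos(np.pi * (ts[rise] - lo) / (2 * half))
        fall = ts > stop - half
        w[fall] = 0.5 - 0.5 * np.cos(np.pi * (hi - ts[fall]) / (2 * half))
        env[seg] += (target - 1.0) * w

    for o in onsets:
        t0 = o / fs
        blend(config.erd_factor, t0, t0 + config.tap_duration)
        blend(config.pmbr_factor, t0 + config.pmbr_window[0], t0 + config.pmbr_window[1])
    return env


def simulate_tapping_session(
    config: TappingConfig = TappingConfig(), seed: int = 0
) -> tuple[Recording, SimulationTruth]:
    """Simulate the stationary finger-tapping session.

    A left-sensorimotor dipole carries a 13-30 Hz band-limited oscillation
    whose envelope drops to ``erd_factor`` while tapping and rebounds to
    ``pmbr_factor`` afterwards.  Physiological (blink + cardiac) artifacts
    are injected at the configured rates.
    """
    rng = np.random.default_rng(seed)
    geom = build_array_geometry(config.n_sensors, config.axes)
    sphere = SphereModel()
    refs = default_reference_channels() if config.include_references else []
    channels = _session_channels(geom, refs, ["NI-TRIG"])
    n_ch = len(channels)

    onsets = tapping_event_onsets(config, rng)
    duration = onsets[-1] / config.fs + config.tail
    n = int(round(duration * config.fs))
    n_scalp_ref = geom.n_channels + len(refs)
    events = EventTable(onsets, ["tap"] * len(onsets))

    motion = simulate_motion_trajectory(
        duration, config.fs, 0.5, config.translation_range, config.rotation_range, rng
    )
    interference, info = simulate_interference(
        geom, config.interference, motion, duration, config.fs, rng, refs
    )

    # beta carrier: band-limited unit-variance noise times the task envelope
    sos = scipy.signal.butter(4, [13.0, 30.0], "bandpass", fs=config.fs, output="sos")
    carrier = scipy.signal.sosfiltfilt(sos, rng.standard_normal(n))
    carrier /= np.std(carrier)
    envelope = _beta_envelope(n, config.fs, onsets, config)
    source_tc = carrier * envelope

    L = sarvas_leadfield(geom, sphere, SENSORIMOTOR_SOURCE).matrix
    pattern = L @ _tangential_moment(SENSORIMOTOR_SOURCE, sphere)
    pattern = pattern * (config.beta_sensor_amplitude / np.max(np.abs(pattern)))
    brain = np.zeros((n_ch, n))
    brain[: geom.n_channels] = pattern[:, None] * source_tc[None, :]

    components: dict[str, np.ndarray] = {"brain": brain}
    for name, comp in interference.items():
        full = np.zeros((n_ch, n))
        full[:n_scalp_ref] = comp
        components[name] = full

    blink, cardiac, physio_info = _physiological_components(
        geom, n_ch, n, config.fs, config.blink_rate, config.heart_rate, rng
    )
    components["blink"] = blink
    components["cardiac"] = cardiac

    trig = np.zeros((n_ch, n))
    trig[-1] = _pulse_train(n, onsets, config.fs, amp=1.0)
    components["trigger"] = trig

    rec = _assemble(channels, components, config.fs, "simulate_tapping_session", {"seed": seed})
    truth = SimulationTruth(
        components=components,
        sources={"beta_carrier": carrier, "beta_envelope": envelope, "beta_source": source_tc,
                 "sensor_pattern": pattern, "cardiac_source": physio_info["cardiac_source"],
                 "blink_source": physio_info["blink_source"]},
        motion=motion,
        events=events,
        meta={"config": config, "interference": info, "physio": physio_info, "sphere": sphere},
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Physiological artifacts
# ---------------------------------------------------------------------------

def _gaussian_coupling(geom: ArrayGeometry, centre: np.ndarray, width: float) -> np.ndarray:
    d = np.linalg.norm(geom.positions - centre[None, :], axis=1)
    w = np.exp(-(d**2) / (2 * width**2))
    return w / np.max(w)


def _physiological_components(
    geom: ArrayGeometry,
    n_ch: int,
    n: int,
    fs: float,
    blink_rate: float,
    heart_rate: float,
    rng: np.random.Generator,
    blink_amplitude: float = 3e-12,
    cardiac_amplitude: float = 2e-12,
) -> tuple[np.ndarray, np.ndarray, dict]:
    if blink_rate < 0 or heart_rate < 0:
        raise ValueError("rates must be non-negative")
    t = np.arange(n) / fs
    duration = n / fs

    # blinks: sporadic biphasic transients, 0.2-0.5 s, frontal coupling
    blink_src = np.zeros(n)
    blink_times = []
    blink_durations = []
    if blink_rate > 0:
        n_blinks = rng.poisson(blink_rate * duration / 60.0)
        starts = np.sort(rng.uniform(0, max(duration - 0.6, 0.1), n_blinks))
        for s in starts:
            d = rng.uniform(0.2, 0.5)
            i0, i1 = int(s * fs), min(n, int((s + d) * fs))
            tt = np.linspace(0, 1, i1 - i0)
            blink_src[i0:i1] += np.sin(2 * np.pi * tt) * np.sin(np.pi * tt) ** 2
            blink_times.append(s)
            blink_durations.append(d)
    blink_coupling = np.zeros(n_ch)
    blink_coupling[: geom.n_channels] = _gaussian_coupling(geom, np.array([0.0, 0.10, 0.01]), 0.05)
    blink = blink_amplitude * blink_coupling[:, None] * blink_src[None, :]

    # cardiac: quasi-periodic QRS-like wavelet train, lateral coupling
    cardiac_src = np.zeros(n)
    peak_times = []
    if heart_rate > 0:
        period = 60.0 / heart_rate
        tk = rng.uniform(0, period)
        while tk < duration:
            peak_times.append(tk)
            tk += period * (1.0 + 0.03 * rng.uniform(-1, 1))
        qrs_w = int(0.024 * fs) * 2 + 1
        # Mexican-hat wavelet as a QRS-like biphasic spike
        x = (np.arange(qrs_w) - qrs_w // 2) / (qrs_w / 10.0)
        qrs = (1.0 - x**2) * np.exp(-(x**2) / 2.0)
        qrs = qrs / np.max(np.abs(qrs))
        for pk in peak_times:
            c = int(pk * fs)
            lo, hi = c - qrs_w // 2, c + qrs_w // 2 + 1
            a, b = max(lo, 0), min(hi, n)
            cardiac_src[a:b] += qrs[a - lo : (a - lo) + (b - a)]
    cardiac_coupling = np.zeros(n_ch)
    cardiac_coupling[: geom.n_channels] = _gaussian_coupling(geom, np.array([-0.10, -0.02, 0.01]), 0.06)
    cardiac = cardiac_amplitude * cardiac_coupling[:, None] * cardiac_src[None, :]

    info = {
        "blink_times": np.array(blink_times),
        "blink_durations": np.array(blink_durations),
        "cardiac_peak_times": np.array(peak_times),
        "blink_source": blink_src,
        "cardiac_source": cardiac_src,
        "blink_coupling": blink_coupling,
        "cardiac_coupling": cardiac_coupling,
    }
    return blink, cardiac, info


def inject_physiological_artifacts(
    rec: Recording,
    geom: ArrayGeometry,
    blink_rate: float = 10.0,
    heart_rate: float = 66.0,
    seed: int = 0,
) -> tuple[Recording, dict]:
    """Add blink and cardiac artifact trains to an existing recording.

    Returns the augmented recording and the truth components
    (``blink``/``cardiac`` matrices plus event times).
    """
    rng = np.random.default_rng(seed)
    blink, cardiac, info = _physiological_components(
        geom, rec.n_channels, rec.n_samples, rec.fs, blink_rate, heart_rate, rng
    )
    out = rec.with_data(rec.data + blink + cardiac, "inject_physiological_artifacts",
                        blink_rate=blink_rate, heart_rate=heart_rate, seed=seed)
    return out, {"blink": blink, "cardiac": cardiac, **info}


# ---------------------------------------------------------------------------
# On-disk session
# ---------------------------------------------------------------------------

def write_session(rec: Recording, truth: SimulationTruth, out_dir: str | Path, stem: str = "session") -> Path:
    """Write the recording container, motion CSV, events TSV and truth
    component store (one .bin per component + JSON index)."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_recording(rec, out / stem)
    if truth.motion is not None:
        # motion CSV written at 120 Hz, the usual camera rate
        m = truth.motion
        step = max(1, int(round((1.0 / 120.0) / (m.time[1] - m.time[0]))))
        write_motion_csv(MotionTrace(m.time[::step], m.translation[::step], m.rotation[::step]), out / f"{stem}_motion.csv")
    if truth.events is not None:
        write_events(truth.events, out / f"{stem}_events.tsv")
    index = {}
    for name, comp in truth.components.items():
        fname = f"{stem}_truth_{name}.bin"
        comp.astype("<f8").tofile(out / fname)
        index[name] = {"file": fname, "shape": list(comp.shape), "dtype": "float64", "byte_order": "little"}
    (out / f"{stem}_truth_index.json").write_text(json.dumps(index, indent=1))
    return out
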