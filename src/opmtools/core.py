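"""Core containers and I/O for OPM-MEG recordings.

The universal data currency is a :class:`Recording`: an ordered channel table
plus a (channels x samples) float64 matrix in tesla at a stated sampling
rate.  Recordings are immutable per processing step -- every operation
returns a new object and appends exactly one entry to ``history``.

On-disk container (bit-exact, language-agnostic):

* ``<stem>_channels.tsv`` -- name, kind, axis, pos_x..ori_z
* ``<stem>_meta.json``    -- fs_hz, unit, n_channels, n_samples, dtype,
  byte_order, history
* ``<stem>_data.bin``     -- row-major channels x samples float64
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.signal

__all__ = [
    "ChannelInfo",
    "Recording",
    "MotionTrace",
    "EventTable",
    "read_recording",
    "write_recording",
    "read_motion_csv",
    "write_motion_csv",
    "sync_and_upsample_motion",
    "select_channels",
    "resample",
    "read_events",
    "write_events",
]

_UNIT_TO_TESLA = {"T": 1.0, "mT": 1e-3, "uT": 1e-6, "nT": 1e-9, "pT": 1e-12, "fT": 1e-15}

CHANNEL_KINDS = ("scalp", "reference", "trigger")
CHANNEL_AXES = ("RAD", "TAN", "TAN2", "X", "Y", "Z", "NA")


@dataclass(frozen=True)
class ChannelInfo:
    """Metadata for one channel.

    ``position`` (metres, head frame) and ``orientation`` (unit vector along
    the sensitive axis) are ``None`` for trigger channels.
    """

    name: str
    kind: str
    axis: str = "NA"
    position: np.ndarray | None = None
    orientation: np.ndarray | None = None
    unit: str = "T"

    def __post_init__(self) -> None:
        if self.kind not in CHANNEL_KINDS:
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if self.axis not in CHANNEL_AXES:
            raise ValueError(f"unknown channel axis {self.axis!r}")
        if self.kind in ("scalp", "reference"):
            if self.orientation is None or self.position is None:
                raise ValueError(f"channel {self.name}: scalp/reference channels need position and orientation")
            ori = np.asarray(self.orientation, dtype=float)
            if abs(np.linalg.norm(ori) - 1.0) > 1e-9:
                raise ValueError(f"channel {self.name}: orientation must be a unit vector")
            object.__setattr__(self, "orientation", ori)
            object.__setattr__(self, "position", np.asarray(self.position, dtype=float))


@dataclass
class Recording:
    """Multi-channel magnetometer recording in tesla."""

    channels: list[ChannelInfo]
    data: np.ndarray
    fs: float
    t0: float = 0.0
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but {len(self.channels)} channels are declared"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")

    # -- convenience -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def index_of(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None

    def picks(self, kind: str) -> np.ndarray:
        """Row indices of channels of the given kind."""
        return np.array([i for i, c in enumerate(self.channels) if c.kind == kind], dtype=int)

    def orientation_matrix(self, kind: str = "scalp") -> np.ndarray:
        """(n x 3) sensitive-axis unit normals for channels of ``kind``."""
        return np.stack([self.channels[i].orientation for i in self.picks(kind)])

    def with_data(self, data: np.ndarray, step: str, **params) -> "Recording":
        """New Recording with replaced samples and one appended history entry."""
        entry = {"step": step, **params}
        return Recording(
            channels=list(self.channels),
            data=np.asarray(data, dtype=float),
            fs=self.fs,
            t0=self.t0,
            history=self.history + [entry],
        )

    def copy(self) -> "Recording":
        return Recording(list(self.channels), self.data.copy(), self.fs, self.t0, list(self.history))


@dataclass
class MotionTrace:
    """Time-stamped 6-DOF rigid-body pose.

    ``rotation`` holds Euler angles in degrees; the axis convention is
    carried in ``euler_order`` (default intrinsic z-y-x: yaw, pitch, roll).
    """

    time: np.ndarray
    translation: np.ndarray  # (n, 3) metres
    rotation: np.ndarray  # (n, 3) degrees
    euler_order: str = "ZYX"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        if self.time.ndim != 1 or np.any(np.diff(self.time) <= 0):
            raise ValueError("motion time must be strictly increasing")
        for arr, label in ((self.translation, "translation"), (self.rotation, "rotation")):
            if arr.shape != (self.time.size, 3):
                raise ValueError(f"{label} must be (n, 3)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{label} contains non-finite values")

    @property
    def pose(self) -> np.ndarray:
        """(n, 6) matrix: tx, ty, tz, rx, ry, rz."""
        return np.hstack([self.translation, self.rotation])


@dataclass
class EventTable:
    onset_sample: np.ndarray
    code: list[str]

    def __post_init__(self) -> None:
        self.onset_sample = np.asarray(self.onset_sample, dtype=int)
        if np.any(np.diff(self.onset_sample) <= 0):
            raise ValueError("event onsets must be strictly increasing")
        if len(self.code) != self.onset_sample.size:
            raise ValueError("codes and onsets differ in length")

    def __len__(self) -> int:
        return self.onset_sample.size


# ---------------------------------------------------------------------------
# Recording container I/O
# ---------------------------------------------------------------------------

def _stem(path: str | Path) -> Path:
    p = Path(path)
    for suffix in ("_meta.json", "_channels.tsv", "_data.bin"):
        if p.name.endswith(suffix):
            return p.with_name(p.name[: -len(suffix)])
    return p


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write the three-file container; returns the stem path."""
    if rec.n_samples == 0:
        raise ValueError("refusing to write an empty (0-sample) recording")
    stem = _stem(path)
    stem.parent.mkdir(parents=True, exist_ok=True)

    rows = []
    for c in rec.channels:
        pos = c.position if c.position is not None else [np.nan] * 3
        ori = c.orientation if c.orientation is not None else [np.nan] * 3
        rows.append([c.name, c.kind, c.axis, *np.asarray(pos, float), *np.asarray(ori, float)])
    table = pd.DataFrame(
        rows, columns=["name", "kind", "axis", "pos_x", "pos_y", "pos_z", "ori_x", "ori_y", "ori_z"]
    )
    table.to_csv(stem.parent / f"{stem.name}_channels.tsv", sep="\t", index=False)

    meta = {
        "fs_hz": rec.fs,
        "t0_s": rec.t0,
        "unit": "T",
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "byte_order": "little",
        "dtype": "float64",
        "history": rec.history,
    }
    (stem.parent / f"{stem.name}_meta.json").write_text(json.dumps(meta, indent=1))
    rec.data.astype("<f8").tofile(stem.parent / f"{stem.name}_data.bin")
    return stem


def read_recording(path: str | Path) -> Recording:
    stem = _stem(path)
    meta_path = stem.parent / f"{stem.name}_meta.json"
    tsv_path = stem.parent / f"{stem.name}_channels.tsv"
    bin_path = stem.parent / f"{stem.name}_data.bin"
    for p in (meta_path, tsv_path, bin_path):
        if not p.exists():
            raise FileNotFoundError(f"recording container incomplete: missing {p.name}")
    meta = json.loads(meta_path.read_text())
    for key in ("fs_hz", "unit", "n_channels", "n_samples"):
        if key not in meta:
            raise ValueError(f"sidecar {meta_path.name} is missing required field {key!r}")
    unit = meta["unit"]
    if unit not in _UNIT_TO_TESLA:
        raise ValueError(f"sidecar declares unknown unit {unit!r}")

    table = pd.read_csv(tsv_path, sep="\t")
    if len(table) != int(meta["n_channels"]):
        raise ValueError(
            f"sidecar declares {meta['n_channels']} channels but table has {len(table)}"
        )
    channels = []
    for _, row in table.iterrows():
        pos = np.array([row.pos_x, row.pos_y, row.pos_z], dtype=float)
        ori = np.array([row.ori_x, row.ori_y, row.ori_z], dtype=float)
        if np.any(~np.isfinite(pos)):
            pos = None
        if np.any(~np.isfinite(ori)):
            ori = None
        axis = str(row.axis)
        if axis in ("nan", ""):  # trigger channels have no sensitive axis
            axis = "NA"
        channels.append(ChannelInfo(str(row["name"]), str(row.kind), axis, pos, ori))

    data = np.fromfile(bin_path, dtype="<f8")
    n_ch, n_s = int(meta["n_channels"]), int(meta["n_samples"])
    if data.size != n_ch * n_s:
        raise ValueError(
            f"data block holds {data.size} values, expected {n_ch * n_s} (channel-count mismatch?)"
        )
    data = data.reshape(n_ch, n_s) * _UNIT_TO_TESLA[unit]
    if not np.all(np.isfinite(data)):
        raise ValueError("data block contains non-finite samples")
    history = meta.get("history") or [{"step": "read_recording", "source": str(stem)}]
    return Recording(channels, data, float(meta["fs_hz"]), float(meta.get("t0_s", 0.0)), history)


# ---------------------------------------------------------------------------
# Motion CSV
# ---------------------------------------------------------------------------

MOTION_COLUMNS = ["time_s", "tx", "ty", "tz", "rx", "ry", "rz"]


def read_motion_csv(path: str | Path, axis_order: str = "ZYX") -> MotionTrace:
    """Read a solved 6-DOF rigid-body trace; blank cells are interpolated.

    The file mirrors the layout of motion-capture exports: a header row and
    columns time_s, tx, ty, tz (metres), rx, ry, rz (degrees).
    """
    df = pd.read_csv(path)
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"motion CSV missing columns {missing}")
    df = df[MOTION_COLUMNS].astype(float)
    time = df["time_s"].to_numpy()
    if np.any(~np.isfinite(time)):
        raise ValueError("motion CSV has missing time stamps")
    if time.size < 2:
        raise ValueError("motion CSV needs at least 2 rows")
    if np.any(np.diff(time) <= 0):
        raise ValueError("motion CSV time stamps are not strictly increasing")
    pose = df[MOTION_COLUMNS[1:]].to_numpy()
    for j in range(6):
        col = pose[:, j]
        bad = ~np.isfinite(col)
        if bad.all():
            raise ValueError(f"motion CSV column {MOTION_COLUMNS[1 + j]} has no valid rows")
        if bad.any():
            pose[:, j] = np.interp(time, time[~bad], col[~bad])
    return MotionTrace(time, pose[:, :3], pose[:, 3:], euler_order=axis_order)


def write_motion_csv(motion: MotionTrace, path: str | Path) -> Path:
    df = pd.DataFrame(
        np.column_stack([motion.time, motion.translation, motion.rotation]),
        columns=MOTION_COLUMNS,
    )
    df.to_csv(path, index=False)
    return Path(path)


def _interp_extrap(x_new: np.ndarray, x: np.ndarray, y: np.ndarray, clamp_after: float) -> np.ndarray:
    """Linear interpolation with linear extrapolation, clamped to the edge
    value beyond ``clamp_after`` seconds outside the observed span."""
    out = np.interp(x_new, x, y)
    if x.size >= 2:
        lo, hi = x[0], x[-1]
        sl_lo = (y[1] - y[0]) / (x[1] - x[0])
        sl_hi = (y[-1] - y[-2]) / (x[-1] - x[-2])
        before = x_new < lo
        after = x_new > hi
        out[before] = y[0] + sl_lo * (x_new[before] - lo)
        out[after] = y[-1] + sl_hi * (x_new[after] - hi)
        out[x_new < lo - clamp_after] = y[0]
        out[x_new > hi + clamp_after] = y[-1]
    return out


def sync_and_upsample_motion(
    motion: MotionTrace, rec: Recording, trigger_channel: str, clamp_after: float = 0.5
) -> MotionTrace:
    """Align a motion trace to a recording and resample it on the recording's
    time base.

    The first crossing of half the trigger channel's maximum marks motion
    t=0.  Pose is linearly interpolated inside the observed span, linearly
    extrapolated just outside it, and clamped to the first/last observed
    pose beyond ``clamp_after`` seconds outside the span.
    """
    trig = rec.data[rec.index_of(trigger_channel)]
    peak = np.max(np.abs(trig))
    if peak <= 0:
        raise ValueError(f"no sync pulse found on {trigger_channel!r}")
    thresh = peak / 2.0
    above = np.abs(trig) >= thresh
    crossings = np.flatnonzero(above & ~np.roll(above, 1))
    if above[0]:
        crossings = np.concatenate([[0], crossings[crossings != 0]])
    if crossings.size == 0:
        raise ValueError(f"no sync pulse found on {trigger_channel!r}")
    if crossings.size > 1:
        warnings.warn(
            f"{crossings.size} pulses found on {trigger_channel!r}; using the first", stacklevel=2
        )
    pulse = int(crossings[0])

    t_rec = (np.arange(rec.n_samples) - pulse) / rec.fs  # recording time in motion clock
    t_src = motion.time - motion.time[0]
    pose = motion.pose
    out = np.empty((rec.n_samples, 6))
    for j in range(6):
        out[:, j] = _interp_extrap(t_rec, t_src, pose[:, j], clamp_after)
    return MotionTrace(
        rec.t0 + np.arange(rec.n_samples) / rec.fs + 1e-12 * 0,  # recording time base
        out[:, :3],
        out[:, 3:],
        euler_order=motion.euler_order,
    )


# ---------------------------------------------------------------------------
# Channel selection and resampling
# ---------------------------------------------------------------------------

def select_channels(rec: Recording, predicate: Callable[[ChannelInfo], bool] | Sequence[str]) -> Recording:
    """Keep channels satisfying ``predicate`` (or listed by name)."""
    if callable(predicate):
        keep = [i for i, c in enumerate(rec.channels) if predicate(c)]
        desc = getattr(predicate, "__name__", "predicate")
    else:
        names = set(predicate)
        keep = [i for i, c in enumerate(rec.channels) if c.name in names]
        desc = f"names={sorted(names)}"
    if not keep:
        raise ValueError("channel selection keeps no channels")
    return Recording(
        [rec.channels[i] for i in keep],
        rec.data[keep],
        rec.fs,
        rec.t0,
        rec.history + [{"step": "select_channels", "kept": len(keep), "rule": desc}],
    )


def drop_channels(rec: Recording, names: Iterable[str]) -> Recording:
    names = set(names)
    return select_channels(rec, lambda c: c.name not in names)


def find_trigger_onsets(trig: np.ndarray) -> np.ndarray:
    """Rising-edge onsets of a pulse channel at half its maximum."""
    peak = np.max(np.abs(trig))
    if peak <= 0:
        return np.array([], dtype=int)
    above = np.abs(trig) >= peak / 2.0
    onsets = np.flatnonzero(above & ~np.roll(above, 1))
    if above[0]:
        onsets = np.concatenate([[0], onsets[onsets != 0]])
    return onsets.astype(int)


def resample(rec: Recording, fs_new: float) -> Recording:
    """Polyphase down-sampling with anti-alias filtering.

    Trigger channels are not low-pass filtered: their pulse onsets are
    re-indexed onto the new time base instead.
    """
    if fs_new <= 0:
        raise ValueError("fs_new must be positive")
    if fs_new >= rec.fs:
        raise ValueError("resample only reduces the rate (fs_new < fs)")
    frac = Fraction(fs_new / rec.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    n_new = int(np.floor(rec.n_samples * up / down))

    out = np.empty((rec.n_channels, n_new))
    trig_rows = set(rec.picks("trigger").tolist())
    cont = [i for i in range(rec.n_channels) if i not in trig_rows]
    if cont:
        res = scipy.signal.resample_poly(rec.data[cont], up, down, axis=1, padtype="line")
        out[cont] = res[:, :n_new]
    for i in trig_rows:
        row = np.zeros(n_new)
        onsets = find_trigger_onsets(rec.data[i])
        amp = np.max(np.abs(rec.data[i])) if onsets.size else 0.0
        new_onsets = np.clip(np.round(onsets * up / down).astype(int), 0, n_new - 1)
        row[new_onsets] = amp
        out[i] = row
    return Recording(
        list(rec.channels),
        out,
        float(fs_new),
        rec.t0,
        rec.history + [{"step": "resample", "fs_new": float(fs_new)}],
    )


# ---------------------------------------------------------------------------
# Events TSV
# ---------------------------------------------------------------------------

def write_events(events: EventTable, path: str | Path) -> Path:
    pd.DataFrame({"onset_sample": events.onset_sample, "code": events.code}).to_csv(
        path, sep="\t", index=False
    )
    return Path(path)


def read_events(path: str | Path) -> EventTable:
    df = pd.read_csv(path, sep="\t")
    return EventTable(df["onset_sample"].to_numpy(int), [str(c) for c in df["code"]])
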