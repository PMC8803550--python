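"""Epoching, trial rejection, evoked t-statistics and Hanning-taper
time-frequency analysis.

Evoked responses are assessed with a per-timepoint one-sample t-test
across trials (against zero, after per-trial baseline correction); the
pipeline-level SNR gain is the ratio of peak |t| in an analysis window
before vs after preprocessing, in dB.  Time-frequency representations use
a single sliding Hann taper on single trials and average the power, so
they contain both phase-locked (evoked) and non-phase-locked (induced)
activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EventTable, Recording

__all__ = [
    "Epochs",
    "TFR",
    "epoch_by_trigger",
    "reject_artifact_trials",
    "evoked_tstats",
    "snr_gain_db",
    "tfr_hanning",
    "baseline_db",
]


@dataclass
class Epochs:
    """(n_trials x n_channels x n_times) trial data in tesla."""

    data: np.ndarray
    times: np.ndarray  # seconds relative to the event
    channel_names: list[str]
    fs: float
    codes: list[str]
    onsets: np.ndarray  # onset sample of each retained trial, recording time
    rejected: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (trials, channels, times)")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time vector does not match trial length")
        if not (self.times.min() <= 0.0 <= self.times.max()):
            raise ValueError("time vector must include 0")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def time_index(self, t: float) -> int:
        return int(np.argmin(np.abs(self.times - t)))

    def average(self) -> np.ndarray:
        return self.data.mean(axis=0)


def epoch_by_trigger(
    rec: Recording, events: EventTable, t_pre: float, t_post: float, picks: str = "scalp"
) -> Epochs:
    """Cut trials of [-t_pre, t_post] s around each event onset.

    Events whose window leaves the record are dropped and logged.
    """
    if len(events) == 0:
        raise ValueError("no events to epoch")
    n_pre = int(round(t_pre * rec.fs))
    n_post = int(round(t_post * rec.fs))
    rows = rec.picks(picks)
    times = np.arange(-n_pre, n_post + 1) / rec.fs
    trials, codes, onsets, rejected = [], [], [], []
    for onset, code in zip(events.onset_sample, events.code):
        lo, hi = onset - n_pre, onset + n_post + 1
        if lo < 0 or hi > rec.n_samples:
            rejected.append({"onset_sample": int(onset), "reason": "outside record"})
            continue
        trials.append(rec.data[rows, lo:hi])
        codes.append(code)
        onsets.append(onset)
    if not trials:
        raise ValueError("all events fall outside the record")
    return Epochs(
        data=np.stack(trials),
        times=times,
        channel_names=[rec.channels[i].name for i in rows],
        fs=rec.fs,
        codes=codes,
        onsets=np.asarray(onsets, dtype=int),
        rejected=rejected,
    )


def reject_artifact_trials(epochs: Epochs, segments: list[tuple[float, float]], fs: float | None = None) -> Epochs:
    """Remove trials whose span intersects any artifactual segment
    (segment times are in recording time, seconds)."""
    fs = fs or epochs.fs
    keep = []
    rejected = list(epochs.rejected)
    for k in range(epochs.n_trials):
        lo = epochs.onsets[k] / fs + epochs.times[0]
        hi = epochs.onsets[k] / fs + epochs.times[-1]
        hit = next((seg for seg in segments if seg[0] < hi and seg[1] > lo), None)
        if hit is None:
            keep.append(k)
        else:
            rejected.append({"onset_sample": int(epochs.onsets[k]), "reason": f"artifact {hit}"})
    if not keep:
        raise ValueError("all trials rejected")
    return Epochs(
        data=epochs.data[keep],
        times=epochs.times,
        channel_names=epochs.channel_names,
        fs=epochs.fs,
        codes=[epochs.codes[k] for k in keep],
        onsets=epochs.onsets[keep],
        rejected=rejected,
    )


def baseline_correct(epochs: Epochs, baseline: tuple[float, float]) -> Epochs:
    i0, i1 = epochs.time_index(baseline[0]), epochs.time_index(baseline[1])
    if i1 <= i0:
        raise ValueError("empty baseline window")
    bl = epochs.data[:, :, i0 : i1 + 1].mean(axis=2, keepdims=True)
    return Epochs(epochs.data - bl, epochs.times, epochs.channel_names, epochs.fs,
                  list(epochs.codes), epochs.onsets, list(epochs.rejected))


def evoked_tstats(
    epochs: Epochs, baseline: tuple[float, float] | None = (-0.1, 0.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel, per-time one-sample t-values across trials (null: 0).

    Each trial is baseline-corrected first (mean over ``baseline``
    subtracted).  Returns ``(t, mean_waveform)``; points with zero
    across-trial variance yield signed infinities (NaN where the mean is
    also zero), which callers should treat as flagged.
    """
    if epochs.n_trials < 3:
        raise ValueError("need at least 3 trials")
    ep = baseline_correct(epochs, baseline) if baseline is not None else epochs
    mean = ep.data.mean(axis=0)
    sd = ep.data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(ep.n_trials))
    return t, mean


def snr_gain_db(
    t_before: np.ndarray, t_after: np.ndarray, times: np.ndarray, window: tuple[float, float]
) -> float:
    """20*log10 of the ratio of max |t| over channels x window, after vs
    before preprocessing."""
    if t_before.shape != t_after.shape:
        raise ValueError("t matrices differ in shape")
    sel = (times >= window[0]) & (times <= window[1])
    peak_before = np.nanmax(np.abs(t_before[:, sel]))
    peak_after = np.nanmax(np.abs(t_after[:, sel]))
    if peak_before == 0:
        raise ValueError("zero peak t before preprocessing")
    return float(20.0 * np.log10(peak_after / peak_before))


# ---------------------------------------------------------------------------
# Time-frequency
# ---------------------------------------------------------------------------

@dataclass
class TFR:
    freqs: np.ndarray
    times: np.ndarray
    power: np.ndarray  # (n_channels, n_freqs, n_times); T^2 or dB
    channel_names: list[str]
    taper: str = "hann"
    is_db: bool = False


def tfr_hanning(
    epochs: Epochs,
    freqs: np.ndarray | None = None,
    window_s: float = 0.5,
    step_s: float = 0.05,
    trim_s: float = 0.5,
) -> TFR:
    """Sliding-window Hann-taper power, averaged over trials.

    Defaults follow common practice for beta-band motor paradigms:
    1-41 Hz in 2 Hz steps, 500 ms window, and the first/last 500 ms of each
    trial discarded as filter-edge territory.
    """
    if freqs is None:
        freqs = np.arange(1.0, 41.1, 2.0)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs > epochs.fs / 2):
        raise ValueError("requested frequency above Nyquist")
    win = int(round(window_s * epochs.fs))
    if epochs.times[-1] - epochs.times[0] <= 2 * trim_s + window_s:
        raise ValueError("trials too short for the window and trim")
    taper = np.hanning(win)
    # complex exponentials, Hann-tapered; normalised so a unit-amplitude
    # sinusoid at a bin frequency gives power 1/2 (amplitude^2/2)
    t_win = np.arange(win) / epochs.fs
    basis = taper[None, :] * np.exp(-2j * np.pi * freqs[:, None] * t_win[None, :])
    norm = 2.0 / taper.sum()

    t_lo, t_hi = epochs.times[0] + trim_s, epochs.times[-1] - trim_s
    centers = []
    c = t_lo + window_s / 2
    while c <= t_hi - window_s / 2 + 1e-9:
        centers.append(c)
        c += step_s
    centers = np.asarray(centers)
    n_tr, n_ch, _ = epochs.data.shape
    power = np.zeros((n_ch, freqs.size, centers.size))
    for j, c in enumerate(centers):
        i0 = int(round((c - window_s / 2 - epochs.times[0]) * epochs.fs))
        seg = epochs.data[:, :, i0 : i0 + win]  # (trials, channels, win)
        coef = norm * np.tensordot(seg, basis, axes=([2], [1]))  # (trials, channels, freqs)
        power[:, :, j] = (np.abs(coef) ** 2 / 2.0).mean(axis=0)
    return TFR(freqs=freqs, times=centers, power=power, channel_names=list(epochs.channel_names))


def baseline_db(tfr: TFR, baseline: tuple[float, float]) -> TFR:
    """Convert power to dB relative to the mean power in ``baseline``."""
    if tfr.is_db:
        raise ValueError("TFR already in dB")
    sel = (tfr.times >= baseline[0]) & (tfr.times <= baseline[1])
    if not sel.any():
        raise ValueError("baseline window outside TFR times")
    ref = tfr.power[:, :, sel].mean(axis=2, keepdims=True)
    if np.any(ref <= 0):
        raise ValueError("zero baseline power")
    return TFR(tfr.freqs, tfr.times, 10.0 * np.log10(tfr.power / ref),
               list(tfr.channel_names), tfr.taper, is_db=True)
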