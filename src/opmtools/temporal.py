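"""Temporal filtering, spectral interpolation, detrending and the scalar
interference metrics (amplitude spectral density, dB gain, max field change).

All operations act on continuous (non-epoched) recordings -- filtering
epoched trials invites edge artifacts, so the API simply does not accept
epochs.  Trigger channels pass through every operation untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .core import Recording

__all__ = [
    "PSDResult",
    "butter_zerophase",
    "spectral_interpolate",
    "detrend_windowed",
    "welch_asd",
    "gain_db",
    "max_field_change",
]


@dataclass
class PSDResult:
    """One-sided Welch amplitude spectral density in fT/rtHz."""

    freqs: np.ndarray
    asd: np.ndarray  # (n_channels, n_freqs)
    window_s: float
    channel_names: list[str]

    def channel_mean(self) -> np.ndarray:
        return self.asd.mean(axis=0)

    def at(self, freq: float) -> np.ndarray:
        """Per-channel ASD at the bin nearest ``freq``."""
        return self.asd[:, int(np.argmin(np.abs(self.freqs - freq)))]

    def band_mean(self, lo: float, hi: float) -> np.ndarray:
        sel = (self.freqs >= lo) & (self.freqs <= hi)
        return self.asd[:, sel].mean(axis=1)


def _continuous_rows(rec: Recording) -> np.ndarray:
    trig = set(rec.picks("trigger").tolist())
    return np.array([i for i in range(rec.n_channels) if i not in trig], dtype=int)


def butter_zerophase(rec: Recording, kind: str, cutoff: float | tuple[float, float], order: int = 5) -> Recording:
    """Bidirectional (zero-phase) Butterworth filter on continuous data.

    ``kind`` is ``highpass``/``lowpass``/``bandpass``; reflective padding of
    at least 3x the filter's impulse-response scale suppresses edge
    transients.  The effective magnitude response is the square of the
    single-pass filter.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    nyq = rec.fs / 2.0
    cut = np.atleast_1d(np.asarray(cutoff, dtype=float))
    if kind in ("highpass", "lowpass"):
        if cut.size != 1:
            raise ValueError(f"{kind} needs a single cutoff")
        if not 0 < cut[0] < nyq:
            raise ValueError(f"cutoff must be in (0, {nyq}) Hz")
        wn = cut[0]
    elif kind == "bandpass":
        if cut.size != 2 or not 0 < cut[0] < cut[1] < nyq:
            raise ValueError("bandpass needs (lo, hi) inside (0, Nyquist)")
        wn = cut
    else:
        raise ValueError(f"unknown filter kind {kind!r}")
    sos = scipy.signal.butter(order, wn, btype=kind, fs=rec.fs, output="sos")
    # impulse-response scale ~ fs / lowest corner frequency
    f_low = cut[0]
    padlen = min(rec.n_samples - 1, max(3 * int(rec.fs / f_low), 3 * order * 10))
    rows = _continuous_rows(rec)
    out = rec.data.copy()
    out[rows] = scipy.signal.sosfiltfilt(sos, rec.data[rows], axis=1, padtype="even", padlen=padlen)
    return rec.with_data(out, "butter_zerophase", kind=kind, cutoff=cut.tolist(), order=order)


def spectral_interpolate(
    rec: Recording,
    targets: list[float],
    halfwidth: float = 0.5,
    neighbour_width: float = 1.0,
) -> Recording:
    """Replace narrow-band amplitude with the mean of flanking frequencies.

    For each target f, full-record DFT bins within f +/- ``halfwidth`` get
    their amplitude set to the mean amplitude over the flanking bands
    [f-halfwidth-neighbour_width, f-halfwidth) and (f+halfwidth,
    f+halfwidth+neighbour_width]; phase is preserved.  This suits
    interference whose amplitude drifts too much for a parametric sine fit,
    while leaving out-of-band content untouched.
    """
    nyq = rec.fs / 2.0
    spans = []
    for f in targets:
        lo, hi = f - halfwidth - neighbour_width, f + halfwidth + neighbour_width
        if lo <= 0 or hi >= nyq:
            raise ValueError(f"target {f} Hz: interpolation band [{lo}, {hi}] outside (0, Nyquist)")
        spans.append((f - halfwidth, f + halfwidth))
    spans.sort()
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 - neighbour_width < a1 + neighbour_width:
            raise ValueError(
                f"interpolation bands around {a0 + halfwidth:g} Hz and {b0 + halfwidth:g} Hz overlap"
            )

    n = rec.n_samples
    freqs = np.fft.rfftfreq(n, 1.0 / rec.fs)
    rows = _continuous_rows(rec)
    spec = np.fft.rfft(rec.data[rows], axis=1)
    amp = np.abs(spec)
    for f in targets:
        target_bins = np.abs(freqs - f) <= halfwidth
        flank = (
            ((freqs >= f - halfwidth - neighbour_width) & (freqs < f - halfwidth))
            | ((freqs > f + halfwidth) & (freqs <= f + halfwidth + neighbour_width))
        )
        if not target_bins.any() or not flank.any():
            continue
        replacement = amp[:, flank].mean(axis=1)
        phase = np.angle(spec[:, target_bins])
        spec[:, target_bins] = replacement[:, None] * np.exp(1j * phase)
    out = rec.data.copy()
    out[rows] = np.fft.irfft(spec, n=n, axis=1)
    return rec.with_data(
        out, "spectral_interpolate", targets=list(map(float, targets)),
        halfwidth=halfwidth, neighbour_width=neighbour_width,
    )


def _window_starts(n: int, win: int, hop: int) -> list[int]:
    starts = list(range(0, max(n - win, 0) + 1, hop))
    if starts[-1] + win < n:
        starts.append(n - win)
    return starts


def _blend_weights(win: int) -> np.ndarray:
    # raised cosine; endpoints kept > 0 so weights always sum > 0
    w = 0.5 - 0.5 * np.cos(2 * np.pi * (np.arange(win) + 0.5) / win)
    return w + 1e-6


def detrend_windowed(
    rec: Recording,
    poly_order: int = 1,
    window_s: float = 10.0,
    overlap: float = 0.5,
    robust: bool = False,
    n_iter: int = 3,
) -> Recording:
    """Subtract a per-window least-squares polynomial from each channel.

    Overlapping windows are blended with a raised-cosine cross-fade.  With
    ``robust=True`` the fit is iteratively reweighted (Tukey biweight), so
    glitches and railing plateaus do not drag the baseline.
    """
    if poly_order < 0:
        raise ValueError("poly_order must be >= 0")
    win = int(round(window_s * rec.fs))
    if win > rec.n_samples:
        raise ValueError("window longer than the record")
    if win <= poly_order + 1:
        raise ValueError("window too short for the polynomial order")
    hop = max(1, int(round(win * (1.0 - overlap))))
    rows = _continuous_rows(rec)
    x = rec.data[rows]
    out_num = np.zeros_like(x)
    out_den = np.zeros(x.shape[1])
    wts = _blend_weights(win)
    tloc = np.linspace(-1.0, 1.0, win)
    V = np.polynomial.polynomial.polyvander(tloc, poly_order)  # (win, p+1)
    pinv = np.linalg.pinv(V)
    for s in _window_starts(x.shape[1], win, hop):
        seg = x[:, s : s + win]
        coef = seg @ pinv.T
        if robust:
            for _ in range(n_iter):
                resid = seg - coef @ V.T
                scale = np.median(np.abs(resid), axis=1, keepdims=True) * 1.4826 + 1e-30
                u = resid / (4.685 * scale)
                w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
                coef = np.stack(
                    [np.linalg.lstsq(V * w[i][:, None], seg[i] * w[i], rcond=None)[0] for i in range(seg.shape[0])]
                )
        resid = seg - coef @ V.T
        out_num[:, s : s + win] += resid * wts
        out_den[s : s + win] += wts
    out = rec.data.copy()
    out[rows] = out_num / out_den
    return rec.with_data(out, "detrend_windowed", poly_order=poly_order, window_s=window_s,
                         overlap=overlap, robust=robust)


def welch_asd(rec: Recording, window_s: float = 10.0) -> PSDResult:
    """Per-channel Welch amplitude spectral density (Hann taper, 50%
    overlap, one-sided), returned in fT/rtHz."""
    nperseg = int(round(window_s * rec.fs))
    if nperseg > rec.n_samples:
        raise ValueError("record shorter than one window")
    freqs, psd = scipy.signal.welch(
        rec.data, fs=rec.fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2, axis=1
    )
    return PSDResult(freqs=freqs, asd=np.sqrt(psd) * 1e15, window_s=window_s,
                     channel_names=rec.channel_names)


def gain_db(psd_before: PSDResult, psd_after: PSDResult) -> np.ndarray:
    """Shielding factor 20*log10(ASD_before / ASD_after), per channel and
    frequency.  Zero denominators map to +inf."""
    if psd_before.channel_names != psd_after.channel_names:
        raise ValueError("channel sets differ")
    if psd_before.freqs.shape != psd_after.freqs.shape or not np.allclose(psd_before.freqs, psd_after.freqs):
        raise ValueError("frequency axes differ")
    with np.errstate(divide="ignore", invalid="ignore"):
        return 20.0 * np.log10(psd_before.asd / psd_after.asd)


def max_field_change(rec: Recording, chunk_s: float = 1.0) -> np.ndarray:
    """Per non-overlapping chunk: max over scalp channels of the in-chunk
    peak-to-peak field, in pT."""
    chunk = int(round(chunk_s * rec.fs))
    n_chunks = rec.n_samples // chunk
    if n_chunks < 1:
        raise ValueError("record shorter than one chunk")
    rows = rec.picks("scalp")
    x = rec.data[rows, : n_chunks * chunk].reshape(rows.size, n_chunks, chunk)
    ptp = x.max(axis=2) - x.min(axis=2)
    return ptp.max(axis=0) * 1e12
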