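"""Overlapping-window multiple linear regression against nuisance
regressors: motion-capture pose and off-head reference channels.

Interference coupling is non-stationary (sensors move through the remnant
field; line-noise amplitude drifts), so ordinary whole-record regression
underfits.  The regression is therefore run in overlapping windows whose
residuals are blended with a raised-cosine cross-fade, keeping the output
continuous.  Regressors are demeaned per window and an intercept is always
included, so within each window the residual is numerically orthogonal to
every regressor and the fit can only remove variance.

The fitted per-window coefficients define a linear operator; a
:class:`RegressionReport` can re-apply that operator to any other matrix
(e.g. a simulator ground-truth component) via :meth:`RegressionReport.apply`,
which is what makes exact attenuation accounting possible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .core import MotionTrace, Recording
from .temporal import _blend_weights, _window_starts

__all__ = ["RegressionReport", "windowed_regress", "regress_motion", "synthetic_gradiometry"]


@dataclass
class RegressionReport:
    windows: list[tuple[int, int]]
    coefficients: np.ndarray  # (n_windows, n_regressors + 1, n_targets); row 0 = intercept
    variance_explained: np.ndarray  # (n_windows, n_targets)
    ranks: np.ndarray  # design rank per window
    target_rows: np.ndarray
    target_names: list[str]
    n_samples: int

    def apply(
        self, data: np.ndarray, regressors: np.ndarray, include_intercept: bool = False
    ) -> np.ndarray:
        """Apply the stored per-window subtraction to another matrix.

        ``data`` has one row per target channel; ``regressors`` must have
        the same row count as the fitted regressor set.  Regressors are
        demeaned per window with their own means (the operation is linear),
        and the fitted slopes are subtracted.  By default the intercept is
        excluded so that component-wise applications sum to the total.
        """
        data = np.asarray(data, dtype=float)
        if data.shape != (len(self.target_rows), self.n_samples):
            raise ValueError("data shape does not match the fitted targets")
        out_num = np.zeros_like(data)
        out_den = np.zeros(self.n_samples)
        for w, (s, e) in enumerate(self.windows):
            wts = _blend_weights(e - s)
            R = regressors[:, s:e].T
            R = R - R.mean(axis=0, keepdims=True)
            fitted = R @ self.coefficients[w, 1:, :]
            if include_intercept:
                fitted = fitted + self.coefficients[w, 0, :][None, :]
            out_num[:, s:e] += (data[:, s:e] - fitted.T) * wts
            out_den[s:e] += wts
        return out_num / out_den


def windowed_regress(
    rec: Recording,
    regressors: np.ndarray,
    window_s: float = 10.0,
    overlap: float = 0.5,
    step_name: str = "windowed_regress",
    step_params: dict | None = None,
) -> tuple[Recording, RegressionReport]:
    """Per-window OLS of each scalp channel onto [intercept, regressors];
    fitted values are subtracted.  Reference and trigger channels pass
    through untouched."""
    regressors = np.atleast_2d(np.asarray(regressors, dtype=float))
    if regressors.shape[1] != rec.n_samples:
        raise ValueError("regressors and data differ in length")
    if not np.all(np.isfinite(regressors)):
        raise ValueError("regressors contain non-finite values")
    if np.all(regressors == 0.0):
        raise ValueError("regressor matrix is identically zero (rank deficient)")
    win = min(int(round(window_s * rec.fs)), rec.n_samples)
    n_reg = regressors.shape[0]
    if win <= n_reg + 2:
        raise ValueError("window too short for the number of regressors")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    hop = max(1, int(round(win * (1.0 - overlap))))

    rows = rec.picks("scalp")
    Y = rec.data[rows]
    out_num = np.zeros_like(Y)
    out_den = np.zeros(Y.shape[1])
    starts = _window_starts(Y.shape[1], win, hop)
    wts = _blend_weights(win)
    coefs = np.zeros((len(starts), n_reg + 1, rows.size))
    varexp = np.zeros((len(starts), rows.size))
    ranks = np.zeros(len(starts), dtype=int)
    windows = []
    for w, s in enumerate(starts):
        e = s + win
        windows.append((s, e))
        R = regressors[:, s:e].T
        R = R - R.mean(axis=0, keepdims=True)
        # regressors are standardised per window so that the intercept
        # column (magnitude 1) cannot numerically swamp field-scale
        # (~1e-12 T) regressors in the rank-revealing solve
        scale = R.std(axis=0)
        scale[scale == 0.0] = 1.0
        design = np.column_stack([np.ones(win), R / scale])
        seg = Y[:, s:e].T
        coef, _, rank, _ = np.linalg.lstsq(design, seg, rcond=None)
        resid = seg - design @ coef
        coef[1:] /= scale[:, None]
        coefs[w] = coef
        ranks[w] = rank
        var_y = seg.var(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ve = 1.0 - resid.var(axis=0) / var_y
        varexp[w] = np.where(var_y > 0, np.clip(ve, 0.0, 1.0), 0.0)
        out_num[:, s:e] += resid.T * wts
        out_den[s:e] += wts

    data = rec.data.copy()
    data[rows] = out_num / out_den
    params = {"window_s": window_s, "overlap": overlap, "n_regressors": n_reg}
    params.update(step_params or {})
    out = rec.with_data(data, step_name, **params)
    report = RegressionReport(
        windows=windows,
        coefficients=coefs,
        variance_explained=varexp,
        ranks=ranks,
        target_rows=rows,
        target_names=[rec.channels[i].name for i in rows],
        n_samples=rec.n_samples,
    )
    return out, report


def regress_motion(
    rec: Recording, motion: MotionTrace, window_s: float = 10.0, overlap: float = 0.5
) -> tuple[Recording, RegressionReport]:
    """Regress the six rigid-body pose parameters out of the scalp channels.

    ``motion`` must already be aligned and upsampled to the recording's
    time base (and low-pass conditioned, typically at 2 Hz, so that marker
    jitter is not injected into the field data).
    """
    if motion.time.size != rec.n_samples:
        raise ValueError("motion trace and recording differ in length; align/upsample first")
    if np.all(motion.pose == 0.0):
        # a perfectly still session has nothing to regress
        rows = rec.picks("scalp")
        report = RegressionReport(
            windows=[], coefficients=np.zeros((0, 7, rows.size)),
            variance_explained=np.zeros((0, rows.size)), ranks=np.zeros(0, dtype=int),
            target_rows=rows, target_names=[rec.channels[i].name for i in rows],
            n_samples=rec.n_samples,
        )
        return rec.with_data(rec.data, "regress_motion", window_s=window_s, still=True), report
    return windowed_regress(
        rec, motion.pose.T, window_s=window_s, overlap=overlap, step_name="regress_motion"
    )


def synthetic_gradiometry(
    rec: Recording,
    reference_names: list[str] | None = None,
    bands: list[tuple[float, float]] = [(2.0, 20.0), (20.0, 80.0)],
    window_s: float = 100.0,
    overlap: float = 0.5,
    filter_order: int = 6,
) -> tuple[Recording, RegressionReport]:
    """Reference-channel regression with per-band splitting.

    Each reference channel is split into the given frequency bands with a
    zero-phase Butterworth filter, yielding n_refs x n_bands regressors;
    interference the references can see is then removed from the scalp
    channels by windowed regression, emulating a hardware gradiometer.
    """
    if reference_names is None:
        ref_rows = rec.picks("reference")
        if ref_rows.size == 0:
            raise ValueError("recording has no reference channels")
    else:
        known = set(rec.channel_names)
        unknown = [n for n in reference_names if n not in known]
        if unknown:
            raise ValueError(f"unknown reference channels {unknown}")
        ref_rows = np.array([rec.index_of(n) for n in reference_names], dtype=int)
    regs = []
    for lo, hi in bands:
        sos = scipy.signal.butter(filter_order, [lo, hi], "bandpass", fs=rec.fs, output="sos")
        regs.append(scipy.signal.sosfiltfilt(sos, rec.data[ref_rows], axis=1))
    regressors = np.vstack(regs)
    return windowed_regress(
        rec,
        regressors,
        window_s=window_s,
        overlap=overlap,
        step_name="synthetic_gradiometry",
        step_params={"bands": [list(b) for b in bands], "references": [rec.channels[i].name for i in ref_rows]},
    )


def gradiometry_regressors(
    rec_like_data: np.ndarray,
    ref_rows: np.ndarray,
    fs: float,
    bands: list[tuple[float, float]] = [(2.0, 20.0), (20.0, 80.0)],
    filter_order: int = 6,
) -> np.ndarray:
    """Band-split reference regressors for an arbitrary matrix (used to push
    ground-truth components through a fitted gradiometry operator)."""
    regs = []
    for lo, hi in bands:
        sos = scipy.signal.butter(filter_order, [lo, hi], "bandpass", fs=fs, output="sos")
        regs.append(scipy.signal.sosfiltfilt(sos, rec_like_data[ref_rows], axis=1))
    return np.vstack(regs)
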