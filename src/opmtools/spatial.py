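"""Spatial filtering: homogeneous field correction (HFC), signal-space
projection (SSP), ICA denoising, and automated artifact detectors.

Every spatial filter here is a channels x channels projector ``P`` applied
as ``Y = P X``.  HFC models interference as a spatially constant field
vector: with ``N`` the (n x 3) matrix of sensitive-axis unit normals, a
homogeneous field ``b`` appears as ``N b``, so projecting onto the
orthogonal complement of the column space of ``N`` removes it exactly while
leaving most of a dipolar field (whose pattern is far from uniform across
the array) intact.  SSP learns the interference subspace empirically from a
noise recording instead; ICA unmixes statistically independent components
so that physiological artifact components can be zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal
from sklearn.decomposition import FastICA

from .core import Recording

__all__ = [
    "Projector",
    "hfc_projector",
    "apply_hfc",
    "ssp_from_noise",
    "ica_denoise",
    "detect_bad_channels",
    "detect_artifact_segments",
]


@dataclass
class Projector:
    """Symmetric idempotent channels x channels spatial filter."""

    matrix: np.ndarray
    model_order: int
    channel_names: list[str]

    def __post_init__(self) -> None:
        P = np.asarray(self.matrix, dtype=float)
        if P.shape[0] != P.shape[1] or P.shape[0] != len(self.channel_names):
            raise ValueError("projector must be square and match the channel list")
        if np.max(np.abs(P - P.T)) > 1e-10:
            raise ValueError("projector is not symmetric")
        if np.max(np.abs(P @ P - P)) > 1e-8:
            raise ValueError("projector is not idempotent")
        self.matrix = P

    @property
    def rank(self) -> int:
        return len(self.channel_names) - self.model_order


def hfc_projector(channels) -> Projector:
    """Projector removing any spatially homogeneous field.

    Built from the row-wise concatenation of the sensors' sensitive-axis
    unit normals N: ``P = I - N (N^T N)^-1 N^T``; model order 3.
    """
    chans = [c for c in channels if c.kind in ("scalp", "reference")]
    if len(chans) < 4:
        raise ValueError("need at least 4 channels with orientations")
    N = np.stack([c.orientation for c in chans])
    if np.linalg.matrix_rank(N, tol=1e-8) < 3:
        raise ValueError(
            "orientation matrix has rank < 3 (coplanar sensitive axes); homogeneous"
            " fields are not identifiable on this array"
        )
    P = np.eye(len(chans)) - N @ np.linalg.solve(N.T @ N, N.T)
    return Projector(P, model_order=3, channel_names=[c.name for c in chans])


def apply_hfc(rec: Recording, scope: str = "scalp_only") -> Recording:
    """Apply homogeneous field correction sample-by-sample.

    ``scope`` selects whether the uniform-field model is fitted over the
    scalp channels only (default; references may already be consumed by
    gradiometry) or over scalp and reference channels jointly.
    """
    if scope not in ("scalp_only", "scalp_and_reference"):
        raise ValueError(f"unknown scope {scope!r}")
    kinds = ("scalp",) if scope == "scalp_only" else ("scalp", "reference")
    rows = np.array([i for i, c in enumerate(rec.channels) if c.kind in kinds], dtype=int)
    proj = hfc_projector([rec.channels[i] for i in rows])
    out = rec.data.copy()
    out[rows] = proj.matrix @ rec.data[rows]
    return rec.with_data(out, "hfc", scope=scope, rank_reduction=proj.model_order)


def ssp_from_noise(noise_rec: Recording, n_components: int) -> Projector:
    """Signal-space projector learned from a noise recording.

    PCA of the noise covariance gives the dominant interference directions
    U; ``P = I - U U^T`` projects experimental data onto the orthogonal
    subspace.
    """
    rows = np.array([i for i, c in enumerate(noise_rec.channels) if c.kind != "trigger"], dtype=int)
    X = noise_rec.data[rows]
    if n_components >= rows.size:
        raise ValueError("n_components must be < number of channels")
    names = [noise_rec.channels[i].name for i in rows]
    if n_components == 0:
        return Projector(np.eye(rows.size), 0, names)
    Xc = X - X.mean(axis=1, keepdims=True)
    cov = Xc @ Xc.T / Xc.shape[1]
    vals, vecs = np.linalg.eigh(cov)
    U = vecs[:, ::-1][:, :n_components]
    P = np.eye(rows.size) - U @ U.T
    return Projector(P, model_order=n_components, channel_names=names)


def apply_projector(rec: Recording, proj: Projector) -> Recording:
    rows = np.array([rec.index_of(n) for n in proj.channel_names], dtype=int)
    out = rec.data.copy()
    out[rows] = proj.matrix @ rec.data[rows]
    return rec.with_data(out, "apply_projector", model_order=proj.model_order)


# ---------------------------------------------------------------------------
# ICA
# ---------------------------------------------------------------------------

@dataclass
class ICAReport:
    flagged: list[int]
    flag_reasons: dict[int, str]
    sources: np.ndarray  # (n_components, n_samples)
    mixing: np.ndarray  # (n_channels, n_components)
    unmixing: np.ndarray  # (n_components, n_channels)
    channel_rows: np.ndarray
    low_freq_fraction: np.ndarray = field(default=None)

    def removal_operator(self) -> np.ndarray:
        """The linear map (I - A_f W_f) realised by zeroing the flagged
        components; apply it to any channels x samples matrix for exact
        component-wise accounting."""
        n = self.mixing.shape[0]
        if not self.flagged:
            return np.eye(n)
        A = self.mixing[:, self.flagged]
        W = self.unmixing[self.flagged, :]
        return np.eye(n) - A @ W


def _low_freq_fraction(sources: np.ndarray, fs: float, split_hz: float = 5.0) -> np.ndarray:
    nper = min(sources.shape[1], int(10 * fs))
    freqs, psd = scipy.signal.welch(sources, fs=fs, nperseg=nper, axis=1)
    total = psd.sum(axis=1) + 1e-300
    return psd[:, freqs < split_hz].sum(axis=1) / total


def ica_denoise(
    rec: Recording,
    n_components: int = 50,
    seed: int = 454,
    flag_rules: dict | None = None,
    max_iter: int = 500,
    tol: float = 1e-3,
    fit_decim: int = 3,
) -> tuple[Recording, ICAReport]:
    """FastICA decomposition of the scalp channels with artifact-component
    removal.

    ``flag_rules`` may contain:

    * ``indices``: explicit component indices to remove;
    * ``templates``: mapping name -> reference time course (e.g. a
      pseudo-ECG); components with |corr| > ``template_corr`` (default 0.5)
      are flagged;
    * ``low_freq``: if true, flag components whose power fraction below
      5 Hz exceeds ``low_freq_fraction`` (default 0.6).

    Flagged components are zeroed and the data remixed.  Best run on
    continuous data high-passed at 1-2 Hz, where slow drifts no longer
    dominate every channel and the unmixing is better conditioned.
    """
    rules = flag_rules or {}
    rows = rec.picks("scalp")
    if n_components > rows.size:
        raise ValueError("more components than scalp channels")
    X = rec.data[rows]
    mean = X.mean(axis=1, keepdims=True)
    Xc = (X - mean).T  # samples x channels

    last_err: Exception | None = None
    for attempt in range(3):
        try:
            ica = FastICA(
                n_components=n_components,
                random_state=seed + attempt,
                whiten="unit-variance",
                max_iter=max_iter,
                tol=tol,
            )
            # the unmixing matrix is fitted on a decimated view (artifact
            # topographies are broadband, so a reduced sample count loses
            # little) and then applied to the full-rate data
            with np.errstate(all="ignore"):
                ica.fit(Xc[:: max(1, fit_decim)])
            break
        except Exception as err:  # pragma: no cover - rare non-convergence
            last_err = err
    else:  # pragma: no cover
        raise RuntimeError(f"FastICA failed to converge after retries: {last_err}")

    A = ica.mixing_  # channels x components
    W = ica.components_  # components x channels
    S = W @ Xc.T  # components x samples, full rate

    flagged: dict[int, str] = {}
    for idx in rules.get("indices", []):
        flagged[int(idx)] = "manual"
    lf = _low_freq_fraction(S, rec.fs)
    if rules.get("low_freq", False):
        thresh = rules.get("low_freq_fraction", 0.6)
        for idx in np.flatnonzero(lf > thresh):
            flagged.setdefault(int(idx), "low_frequency_dominance")
    templates = rules.get("templates", {})
    corr_thresh = rules.get("template_corr", 0.5)
    for name, tmpl in templates.items():
        tmpl = np.asarray(tmpl, dtype=float)
        tc = tmpl - tmpl.mean()
        denom = np.linalg.norm(tc)
        if denom == 0:
            continue
        for idx in range(S.shape[0]):
            s = S[idx] - S[idx].mean()
            r = float(s @ tc / (np.linalg.norm(s) * denom + 1e-300))
            if abs(r) > corr_thresh:
                flagged.setdefault(idx, f"template:{name} (|r|={abs(r):.2f})")

    report = ICAReport(
        flagged=sorted(flagged),
        flag_reasons=flagged,
        sources=S,
        mixing=A,
        unmixing=W,
        channel_rows=rows,
        low_freq_fraction=lf,
    )
    out = rec.data.copy()
    M = report.removal_operator()
    out[rows] = M @ (X - mean) + mean
    if len(flagged) == n_components:
        import warnings

        warnings.warn("all ICA components flagged; output reduced to channel means", stacklevel=2)
    return rec.with_data(out, "ica_denoise", n_components=n_components, seed=seed,
                         flagged=sorted(flagged)), report


# ---------------------------------------------------------------------------
# Automated artifact detectors
# ---------------------------------------------------------------------------

def detect_bad_channels(
    rec: Recording, asd_factor: float = 5.0, rail_s: float = 0.5, window_s: float = 10.0
) -> list[str]:
    """Flag scalp channels that are far noisier than the array or that rail.

    A channel is flagged when its median broadband ASD exceeds
    ``asd_factor`` times the array median, or when it holds a constant
    value for longer than ``rail_s`` seconds (a sensor stuck at the edge of
    its dynamic range).
    """
    if rec.duration < 10.0:
        raise ValueError("need at least 10 s of data")
    rows = rec.picks("scalp")
    nper = int(min(window_s, rec.duration) * rec.fs)
    freqs, psd = scipy.signal.welch(rec.data[rows], fs=rec.fs, nperseg=nper, axis=1)
    band = (freqs >= 1.0) & (freqs <= min(100.0, rec.fs / 2 * 0.8))
    med = np.median(np.sqrt(psd[:, band]), axis=1)
    array_med = np.median(med)
    bad = set(np.flatnonzero(med > asd_factor * array_med))

    max_run = int(rail_s * rec.fs)
    for i_local, i in enumerate(rows):
        x = rec.data[i]
        const = np.diff(x) == 0.0
        if not const.any():
            continue
        # longest run of unchanged consecutive samples
        edges = np.flatnonzero(np.diff(np.concatenate([[0], const.view(np.int8), [0]])))
        if edges.size and np.max(edges[1::2] - edges[0::2]) >= max_run:
            bad.add(i_local)
    return [rec.channels[rows[i]].name for i in sorted(bad)]


def detect_artifact_segments(
    rec: Recording,
    jump_threshold: float = 5e-12,
    jump_window: float = 0.1,
    min_channel_fraction: float = 0.5,
    pad: float = 0.1,
) -> list[tuple[float, float]]:
    """Mark spans with large transient field shifts across the array.

    A window is artifactual when its peak-to-peak amplitude exceeds
    ``jump_threshold`` (tesla) on at least ``min_channel_fraction`` of the
    scalp channels; adjacent windows merge and each span is padded by
    ``pad`` seconds.
    """
    rows = rec.picks("scalp")
    win = max(2, int(round(jump_window * rec.fs)))
    hop = max(1, win // 2)
    n = rec.n_samples
    marks = []
    for s in range(0, n - win + 1, hop):
        seg = rec.data[rows, s : s + win]
        ptp = seg.max(axis=1) - seg.min(axis=1)
        if np.mean(ptp > jump_threshold) >= min_channel_fraction:
            marks.append((s / rec.fs, (s + win) / rec.fs))
    if not marks:
        return []
    merged = [list(marks[0])]
    for a, b in marks[1:]:
        if a <= merged[-1][1] + 1e-12:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [(max(0.0, a - pad), min(rec.duration, b + pad)) for a, b in merged]
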