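"""From node timeseries to leakage-corrected 1 Hz amplitude envelopes.

Stage order follows the standard amplitude-envelope connectivity recipe:
epoch concatenation, zero-phase band-pass, symmetric orthogonalization
(leakage correction), Hilbert envelope, median-filter despiking, 1 Hz
downsampling, and edge trimming (first 2 and last 3 one-second samples
removed).  The node-level activity summary is the coefficient of
variation of the envelope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import butter, hilbert, sosfiltfilt

from .bands import BandSpec
from .synthetic import SubjectRecording

__all__ = [
    "EnvelopeSet",
    "ActivityProfile",
    "segment_and_concatenate",
    "bandpass",
    "select_region_representative",
    "symmetric_orthogonalize",
    "hilbert_envelope",
    "condition_envelope",
    "cov_activity",
    "subject_band_envelope",
]

TRIM_HEAD = 2  # one-second samples dropped at the start
TRIM_TAIL = 3  # and at the end


@dataclass
class EnvelopeSet:
    """Non-negative band-limited amplitude envelopes for one subject."""

    subject_id: str
    band: BandSpec
    env: np.ndarray  # (n_nodes, n_samples)
    rate: float = 1.0  # Hz
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.env = np.asarray(self.env, dtype=float)
        if self.env.ndim != 2:
            raise ValueError("env must be 2-D (nodes x samples)")
        if not np.all(np.isfinite(self.env)):
            raise ValueError("envelope contains non-finite values")
        if np.any(self.env < 0):
            raise ValueError("envelope values must be non-negative")

    @property
    def n_nodes(self) -> int:
        return self.env.shape[0]

    @property
    def n_samples(self) -> int:
        return self.env.shape[1]


@dataclass
class ActivityProfile:
    """Per-node coefficient of variation of the amplitude envelope."""

    subject_id: str
    band: BandSpec
    cov: np.ndarray  # (n_nodes,)


def segment_and_concatenate(
    recording: SubjectRecording, epoch_s: float, reject: list[int] | None = None
) -> SubjectRecording:
    """Split into fixed-length epochs, drop rejected ones, re-concatenate.

    Retained epochs keep their original order.  ``reject`` holds 0-based
    epoch indices (e.g. from visual artifact inspection of real data).
    """
    epoch_len = int(round(epoch_s * recording.sampling_rate))
    if epoch_len < 1:
        raise ValueError("epoch length must be at least one sample")
    if recording.n_samples % epoch_len != 0:
        raise ValueError(
            f"epoch length {epoch_s} s ({epoch_len} samples) does not divide "
            f"the recording ({recording.n_samples} samples)"
        )
    n_epochs = recording.n_samples // epoch_len
    reject_set = set(reject or [])
    bad = [r for r in reject_set if not 0 <= r < n_epochs]
    if bad:
        raise ValueError(f"reject indices out of range [0, {n_epochs}): {sorted(bad)}")
    keep = [e for e in range(n_epochs) if e not in reject_set]
    if not keep:
        raise ValueError("all epochs rejected; nothing to concatenate")
    blocks = recording.data.reshape(recording.n_nodes, n_epochs, epoch_len)
    meta = dict(recording.metadata)
    meta.update(n_epochs_retained=len(keep), n_epochs_total=n_epochs, epoch_s=epoch_s)
    return SubjectRecording(
        subject_id=recording.subject_id,
        group=recording.group,
        data=blocks[:, keep, :].reshape(recording.n_nodes, -1),
        sampling_rate=recording.sampling_rate,
        node_labels=list(recording.node_labels),
        metadata=meta,
    )


def bandpass(recording: SubjectRecording, band: BandSpec, order: int = 4) -> SubjectRecording:
    """Zero-phase Butterworth band-pass of every node timeseries.

    Forward-backward filtering (``sosfiltfilt``) doubles the effective
    order and cancels phase distortion, which matters because envelope
    correlation is a zero-lag measure.
    """
    band.check_nyquist(recording.sampling_rate)
    nyq = recording.sampling_rate / 2
    sos = butter(order, [band.f_low / nyq, band.f_high / nyq], btype="bandpass", output="sos")
    meta = dict(recording.metadata)
    meta["band"] = band.name
    return SubjectRecording(
        subject_id=recording.subject_id,
        group=recording.group,
        data=sosfiltfilt(sos, recording.data, axis=1),
        sampling_rate=recording.sampling_rate,
        node_labels=list(recording.node_labels),
        metadata=meta,
    )


def select_region_representative(candidate_channels: np.ndarray) -> int:
    """Index of the candidate channel with the largest temporal SD.

    Used to reduce a parcel's virtual channels to a single node
    timeseries.  Ties break to the lowest index.
    """
    x = np.asarray(candidate_channels, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("need a non-empty 2-D (channels x samples) array")
    # ddof is irrelevant to the argmax; population SD avoids nan at 1 sample
    return int(np.argmax(x.std(axis=1)))


def symmetric_orthogonalize(
    node_timeseries: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> np.ndarray:
    """Closest set of mutually orthogonal timeseries to the input rows.

    Removes all zero-lag shared signal across nodes simultaneously — the
    multivariate leakage correction for beamformed source estimates.
    Solves ``min ||X - P||_F`` over matrices ``P`` whose rows are
    mutually orthogonal with free magnitudes, by alternating between the
    orthonormal polar factor (via SVD) and per-row least-squares scales.

    Parameters
    ----------
    node_timeseries
        (n_nodes, n_samples) with ``n_samples > n_nodes``; must be full
        row rank (duplicated or silent nodes make the problem singular).

    Returns
    -------
    (n_nodes, n_samples) array whose rows have exactly zero mutual dot
    products up to numerical precision.
    """
    x = np.asarray(node_timeseries, dtype=float)
    if x.ndim != 2:
        raise ValueError("input must be 2-D (nodes x samples)")
    n_nodes, n_samples = x.shape
    if n_samples <= n_nodes:
        raise ValueError(
            f"need more samples than nodes (got {n_nodes} nodes, {n_samples} samples)"
        )
    L = x.T  # samples x nodes; columns are node timeseries
    sv = np.linalg.svd(L, compute_uv=False)
    if sv[-1] <= sv[0] * 1e-10:
        # Identify likely culprits: node pairs with |correlation| ~ 1.
        c = np.corrcoef(x)
        bad = [
            (i, j)
            for i in range(n_nodes)
            for j in range(i + 1, n_nodes)
            if abs(c[i, j]) > 1 - 1e-8
        ]
        detail = f"; near-duplicate node pairs: {bad}" if bad else ""
        raise ValueError(
            "input is rank deficient; symmetric orthogonalization requires "
            f"linearly independent node timeseries{detail}"
        )
    d = np.linalg.norm(L, axis=0)
    prev_obj = np.inf
    for _ in range(max_iter):
        u, _, vt = np.linalg.svd(L * d, full_matrices=False)
        O = u @ vt  # orthonormal columns closest to L @ diag(d)
        d = np.einsum("ij,ij->j", O, L)  # per-column LS rescale
        obj = float(np.linalg.norm(L - O * d))
        if prev_obj - obj <= tol * max(prev_obj, 1.0):
            break
        prev_obj = obj
    else:
        warnings.warn(
            "symmetric orthogonalization did not converge within "
            f"{max_iter} iterations (last objective {obj:.6g})",
            RuntimeWarning,
        )
    return (O * d).T


def hilbert_envelope(node_timeseries: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal, per node."""
    x = np.atleast_2d(np.asarray(node_timeseries, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    return np.abs(hilbert(x, axis=-1))


def condition_envelope(
    env: np.ndarray,
    sampling_rate: float,
    subject_id: str = "",
    band: BandSpec | None = None,
    median_window: int = 5,
    target_rate: float = 1.0,
) -> EnvelopeSet:
    """Despike, downsample to 1 Hz, and trim a native-rate envelope.

    Despiking is a running median (default window 5 samples) at the
    native rate; downsampling averages each contiguous one-second window
    (anti-aliasing and deterministic); trimming drops the first 2 and
    last 3 one-second samples to avoid filter/Hilbert edge effects.
    """
    env = np.atleast_2d(np.asarray(env, dtype=float))
    if np.any(env < 0) or not np.all(np.isfinite(env)):
        raise ValueError("envelope must be non-negative and finite")
    window = int(round(sampling_rate / target_rate))
    if window < 1:
        raise ValueError("sampling_rate must be at least target_rate")
    if median_window > 1:
        env = median_filter(env, size=(1, median_window), mode="nearest")
    n_windows = env.shape[1] // window
    if n_windows - TRIM_HEAD - TRIM_TAIL < 2:
        raise ValueError(
            f"envelope too short: {n_windows} one-second samples leave fewer than "
            f"2 after trimming {TRIM_HEAD}+{TRIM_TAIL}"
        )
    down = env[:, : n_windows * window].reshape(env.shape[0], n_windows, window).mean(axis=2)
    trimmed = down[:, TRIM_HEAD : n_windows - TRIM_TAIL]
    return EnvelopeSet(
        subject_id=subject_id,
        band=band if band is not None else BandSpec("unspecified", 1.0, 2.0),
        env=trimmed,
        rate=target_rate,
        metadata={"median_window": median_window, "native_rate": sampling_rate},
    )


def cov_activity(env_set: EnvelopeSet) -> ActivityProfile:
    """Coefficient of variation (SD/mean) of each node's envelope.

    A normalized activity measure: invariant to per-node signal scaling,
    which varies enormously across beamformed source space.  Sample SD
    (n-1 denominator).
    """
    mean = env_set.env.mean(axis=1)
    if np.any(mean <= 0):
        bad = np.flatnonzero(mean <= 0).tolist()
        raise ValueError(f"zero-mean envelope at node(s) {bad}; CoV undefined")
    sd = env_set.env.std(axis=1, ddof=1)
    return ActivityProfile(subject_id=env_set.subject_id, band=env_set.band, cov=sd / mean)


def subject_band_envelope(
    recording: SubjectRecording,
    band: BandSpec,
    orthogonalize: bool = True,
    median_window: int = 5,
) -> EnvelopeSet:
    """Full single-band pipeline: band-pass → (orthogonalize) → Hilbert →
    despike/downsample/trim.  Convenience wrapper over the stage functions."""
    rec = bandpass(recording, band)
    data = symmetric_orthogonalize(rec.data) if orthogonalize else rec.data
    env = hilbert_envelope(data)
    return condition_envelope(
        env,
        recording.sampling_rate,
        subject_id=recording.subject_id,
        band=band,
        median_window=median_window,
    )
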