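"""Filtering, ocular-artifact removal and fixed-length segmentation.

The filtering front end mirrors common clinical practice for resting-state
EEG: an elliptic band-pass (default 0.1-60 Hz) applied forward-backward for
zero phase, and an optional narrow IIR notch at the mains frequency.  Ocular
artifacts can be attenuated by independent component analysis using the
frontal electrodes (FP1, FP2, F7, F8) as reference signals: components whose
absolute Pearson correlation with any reference channel exceeds a threshold
are zeroed before back-projection.

Recordings are then cut into fixed-length windows, optionally overlapping by
half a window.  Windows never span recording boundaries and trailing partial
windows are discarded, so a recording of ``d`` seconds yields
``floor((d - L) / step) + 1`` windows of length ``L``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import EEGRecording, normalize_channel_name

#: Frontal electrodes used as ocular references (closest to the eyes).
DEFAULT_OCULAR_REFS = ("FP1", "FP2", "F7", "F8")


@dataclass(frozen=True)
class SegmentationSpec:
    """Window length in seconds and fractional overlap in [0, 1)."""

    segment_length_s: float
    overlap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.segment_length_s <= 0:
            raise ValueError("segment_length_s must be positive")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must lie in [0, 1)")

    @property
    def step_s(self) -> float:
        return self.segment_length_s * (1.0 - self.overlap_fraction)


@dataclass
class Segment:
    """One fixed-length window of one recording (all channels)."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    subject_id: str
    start_s: float
    label: str
    channel_labels: list[str]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def design_bandpass(
    low_hz: float,
    high_hz: float,
    fs: float,
    *,
    order: int = 4,
    rp_db: float = 0.2,
    rs_db: float = 40.0,
) -> np.ndarray:
    """Elliptic band-pass in second-order sections.

    The default 0.2 dB passband ripple keeps the *forward-backward* (squared)
    magnitude response within 5% of unity across the passband; stopband
    attenuation is 40 dB per pass.
    """
    if not (0 < low_hz < high_hz < fs / 2):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < fs/2; "
            f"got low={low_hz}, high={high_hz}, fs={fs}"
        )
    return signal.ellip(order, rp_db, rs_db, [low_hz, high_hz],
                        btype="bandpass", fs=fs, output="sos")


def bandpass_filter(
    rec: EEGRecording,
    low_hz: float = 0.1,
    high_hz: float = 60.0,
    *,
    order: int = 4,
    rp_db: float = 0.2,
    rs_db: float = 40.0,
) -> EEGRecording:
    """Zero-phase elliptic band-pass of every channel."""
    sos = design_bandpass(low_hz, high_hz, rec.fs, order=order, rp_db=rp_db, rs_db=rs_db)
    return rec.replace_data(signal.sosfiltfilt(sos, rec.data, axis=1))


def notch_filter(rec: EEGRecording, stop_hz: float = 60.0, *, q: float = 30.0) -> EEGRecording:
    """Zero-phase second-order IIR notch (default Q = 30) at ``stop_hz``."""
    if not (0 < stop_hz < rec.fs / 2):
        raise ValueError(f"notch frequency must lie in (0, fs/2); got {stop_hz}")
    b, a = signal.iirnotch(stop_hz, q, fs=rec.fs)
    return rec.replace_data(signal.filtfilt(b, a, rec.data, axis=1))


def remove_ocular_artifacts(
    rec: EEGRecording,
    ref_channels: tuple[str, ...] = DEFAULT_OCULAR_REFS,
    *,
    threshold: float = 0.7,
    seed: int = 0,
    max_iter: int = 1000,
    on_no_convergence: str = "raise",
) -> EEGRecording:
    """ICA-based ocular-artifact suppression.

    FastICA decomposes the recording into as many components as channels;
    any component whose absolute Pearson correlation with one of the frontal
    reference channels (of the *input* recording) exceeds ``threshold`` is
    zeroed before back-projection.  Deterministic for a fixed ``seed``.

    ``on_no_convergence``: ``"raise"`` flags non-convergence as an error,
    ``"passthrough"`` returns the input unchanged with a warning.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    refs = [normalize_channel_name(c) for c in ref_channels]
    missing = [c for c in refs if c not in rec.channel_labels]
    if missing:
        raise ValueError(f"reference channels not in recording: {missing}")
    ref_idx = [rec.channel_labels.index(c) for c in refs]
    ref_data = rec.data[ref_idx]

    ica = FastICA(n_components=rec.n_channels, random_state=seed,
                  whiten="unit-variance", max_iter=max_iter)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        sources = ica.fit_transform(rec.data.T)  # (n_samples, n_components)
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    if not converged:
        if on_no_convergence == "passthrough":
            warnings.warn("ICA did not converge; returning recording unchanged")
            return rec.replace_data(rec.data.copy())
        raise RuntimeError(
            "ICA did not converge; increase max_iter or pass "
            "on_no_convergence='passthrough'"
        )

    # correlation of every component with every reference channel
    s = sources - sources.mean(axis=0)
    s_norm = np.linalg.norm(s, axis=0)
    r = ref_data - ref_data.mean(axis=1, keepdims=True)
    r_norm = np.linalg.norm(r, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (r @ s) / np.outer(r_norm, s_norm)
    corr = np.nan_to_num(corr)
    reject = np.abs(corr).max(axis=0) > threshold

    cleaned = sources.copy()
    cleaned[:, reject] = 0.0
    return rec.replace_data(ica.inverse_transform(cleaned).T)


def count_segments(duration_s: float, spec: SegmentationSpec) -> int:
    """Number of windows obtainable from a recording of ``duration_s`` seconds.

    ``floor((duration - length) / step) + 1``, or 0 if the recording is
    shorter than one window.
    """
    if duration_s < spec.segment_length_s:
        return 0
    # guard float fuzz at exact multiples (e.g. 90 s / step 30 s)
    return int(np.floor((duration_s - spec.segment_length_s) / spec.step_s + 1e-9)) + 1


def segment_recording(rec: EEGRecording, spec: SegmentationSpec) -> list[Segment]:
    """Cut a recording into fixed-length, optionally overlapping windows.

    Windows start at 0, step, 2*step, ...; trailing samples shorter than one
    window are discarded.  A recording shorter than one window yields an
    empty list with a warning.
    """
    win = int(round(spec.segment_length_s * rec.fs))
    step = int(round(win * (1.0 - spec.overlap_fraction)))
    if step < 1:
        raise ValueError("segmentation step must be at least one sample")
    if rec.n_samples < win:
        warnings.warn(
            f"recording {rec.subject_id!r} ({rec.duration_s:.1f} s) is shorter "
            f"than one {spec.segment_length_s} s window; no segments produced"
        )
        return []
    out = []
    for start in range(0, rec.n_samples - win + 1, step):
        out.append(
            Segment(
                data=rec.data[:, start:start + win],
                fs=rec.fs,
                subject_id=rec.subject_id,
                start_s=start / rec.fs,
                label=rec.label,
                channel_labels=list(rec.channel_labels),
            )
        )
    return out
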