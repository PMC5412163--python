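"""Reading and writing multichannel EEG recordings and feature tables.

Recordings are held as a channels-by-samples float matrix together with the
sampling rate, ordered electrode labels (10-20 system where applicable), a
subject identifier and a class label.  Two on-disk representations are
supported: EDF (European Data Format) and a plain comma-delimited matrix with
one header row of channel names, one row per sample and one column per
channel.  Plain matrices carry no metadata, so the sampling rate must be
supplied by the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LABELS = ("normal", "autistic", "unknown")

#: Electrode names of the international 10-20 placement system (including the
#: modernised T7/T8/P7/P8 aliases of T3/T4/T5/T6).  Matching is
#: case-insensitive; unknown names are allowed but excluded from
#: ocular-reference selection.
TEN_TWENTY = frozenset(
    {
        "FP1", "FP2", "FPZ", "F7", "F3", "FZ", "F4", "F8",
        "T3", "T7", "C3", "CZ", "C4", "T4", "T8",
        "T5", "P7", "P3", "PZ", "P4", "T6", "P8",
        "O1", "OZ", "O2", "A1", "A2", "AFZ",
    }
)

#: Default 16-channel montage used by the synthetic generator, mirroring a
#: typical 16-channel clinical cap.
DEFAULT_CHANNELS_16 = (
    "FP1", "FP2", "F7", "F3", "F4", "F8",
    "T7", "C3", "C4", "T8",
    "P7", "P3", "P4", "P8",
    "O1", "O2",
)


def normalize_channel_name(name: str) -> str:
    """Upper-case, whitespace-stripped channel name (``fp1`` -> ``FP1``)."""
    return name.strip().upper()


@dataclass
class EEGRecording:
    """One subject's multichannel EEG signal.

    Attributes
    ----------
    data:
        Array of shape ``(n_channels, n_samples)`` in microvolts (or
        arbitrary-but-consistent units for matrix files without calibration).
    fs:
        Sampling rate in Hz.
    channel_labels:
        Ordered, unique electrode names, one per data row.
    subject_id:
        Opaque subject identifier.
    label:
        ``"normal"``, ``"autistic"`` or ``"unknown"``.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    subject_id: str = ""
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (n_channels, n_samples) array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        self.channel_labels = [normalize_channel_name(c) for c in self.channel_labels]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def replace_data(self, data: np.ndarray) -> "EEGRecording":
        """Copy of this recording with ``data`` swapped (same metadata)."""
        return EEGRecording(
            data=data,
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            subject_id=self.subject_id,
            label=self.label,
        )


def _repair_linear(data: np.ndarray) -> np.ndarray:
    """Linearly interpolate isolated non-finite samples, channel by channel."""
    out = data.copy()
    for row in out:
        bad = ~np.isfinite(row)
        if bad.all():
            raise ValueError("cannot repair a channel with no finite samples")
        if bad.any():
            idx = np.arange(row.size)
            row[bad] = np.interp(idx[bad], idx[~bad], row[~bad])
    return out


def read_recording(
    path: str | Path,
    label: str = "unknown",
    *,
    fs: float | None = None,
    subject_id: str | None = None,
    repair: str | None = None,
) -> EEGRecording:
    """Load an EDF or delimited-matrix recording.

    Parameters
    ----------
    path:
        ``.edf`` file, or a delimited text matrix with a header row of channel
        names, rows = samples, columns = channels.
    label:
        Class label to attach (labels are not stored in either format).
    fs:
        Sampling rate in Hz.  Required for matrix files; ignored for EDF
        (taken from the header).
    repair:
        ``None`` rejects recordings containing non-finite samples; ``"linear"``
        interpolates isolated NaNs instead.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sid = subject_id if subject_id is not None else path.stem

    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # mne returns volts
        labels = list(raw.ch_names)
        rec_fs = float(raw.info["sfreq"])
    else:
        try:
            df = pd.read_csv(path)
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed matrix file {path}: {exc}") from exc
        if df.shape[1] < 1:
            raise ValueError(f"matrix file {path} has no columns")
        if not all(np.issubdtype(d, np.number) for d in df.dtypes):
            raise ValueError(
                f"matrix file {path} has non-numeric columns (ragged rows?)"
            )
        if fs is None:
            raise ValueError(
                "sampling rate `fs` is required for matrix recordings "
                "(plain matrices carry no metadata)"
            )
        data = df.to_numpy(dtype=float).T
        labels = [str(c) for c in df.columns]
        rec_fs = float(fs)

    if not np.isfinite(data).all():
        if repair == "linear":
            data = _repair_linear(data)
        else:
            raise ValueError(
                f"recording {path} contains non-finite samples; "
                "pass repair='linear' to interpolate isolated NaNs"
            )
    return EEGRecording(data=data, fs=rec_fs, channel_labels=labels,
                        subject_id=sid, label=label)


def write_recording_csv(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as a comma-delimited matrix (header = channel names)."""
    df = pd.DataFrame(rec.data.T, columns=rec.channel_labels)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Feature tables

_META_COLS = ("subject_id", "start_s", "label")


def features_to_frame(table: Sequence) -> pd.DataFrame:
    """Convert a list of FeatureVector to a tidy DataFrame.

    The first columns are segment provenance (subject, start time) and the
    class label; the remaining columns are the feature values in vector order.
    """
    if len(table) == 0:
        return pd.DataFrame(columns=list(_META_COLS))
    names = list(table[0].feature_names)
    for fv in table:
        if list(fv.feature_names) != names:
            raise ValueError("all feature vectors must share one feature-name ordering")
    rows = []
    for fv in table:
        row = {"subject_id": fv.subject_id, "start_s": fv.start_s, "label": fv.label}
        row.update(dict(zip(names, fv.values)))
        rows.append(row)
    return pd.DataFrame(rows, columns=list(_META_COLS) + names)


def write_features(table: Sequence, path: str | Path) -> None:
    """Write feature vectors as CSV; round-trips losslessly with read_features."""
    features_to_frame(table).to_csv(path, index=False)


def read_features(path: str | Path):
    """Read a feature CSV written by :func:`write_features`."""
    from .features import FeatureVector

    df = pd.read_csv(path)
    for col in _META_COLS:
        if col not in df.columns:
            raise ValueError(f"feature table {path} is missing column {col!r}")
    names = [c for c in df.columns if c not in _META_COLS]
    out = []
    for _, row in df.iterrows():
        out.append(
            FeatureVector(
                values=row[names].to_numpy(dtype=float),
                feature_names=list(names),
                label=str(row["label"]),
                subject_id=str(row["subject_id"]),
                start_s=float(row["start_s"]),
            )
        )
    return out
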