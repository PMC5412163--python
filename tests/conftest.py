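"""Shared fixtures: tiny recordings, feature-vector builders, an EDF writer.

The EDF writer emits a minimal but standard-conforming EDF file (ASCII
header, 16-bit little-endian samples, one data record per second) so the
EDF ingestion path can be exercised without any binary fixture in the
repository.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pytest

from eegcad.features import FeatureVector
from eegcad.io import EEGRecording


def write_minimal_edf(
    path: Path,
    data_uv: np.ndarray,
    fs: int,
    channel_labels: list[str],
    phys_range: float = 1000.0,
) -> None:
    """Write (n_channels, n_samples) microvolt data as an EDF file.

    Samples are linearly quantised into int16 over +-``phys_range`` uV.
    ``n_samples`` must be a multiple of ``fs`` (whole 1 s data records).
    """
    n_ch, n_samp = data_uv.shape
    if n_samp % fs:
        raise ValueError("need whole seconds of data")
    n_rec = n_samp // fs

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        assert len(b) <= width
        return b + b" " * (width - len(b))

    hdr = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X X X X", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(str(256 * (1 + n_ch)), 8), pad("", 44),
        pad(str(n_rec), 8), pad("1", 8), pad(str(n_ch), 4),
    ])
    per_sig = b"".join([
        b"".join(pad(lab, 16) for lab in channel_labels),
        b"".join(pad("AgAgCl electrode", 80) for _ in channel_labels),
        b"".join(pad("uV", 8) for _ in channel_labels),
        b"".join(pad(str(-phys_range), 8) for _ in channel_labels),
        b"".join(pad(str(phys_range), 8) for _ in channel_labels),
        b"".join(pad("-32768", 8) for _ in channel_labels),
        b"".join(pad("32767", 8) for _ in channel_labels),
        b"".join(pad("", 80) for _ in channel_labels),
        b"".join(pad(str(fs), 8) for _ in channel_labels),
        b"".join(pad("", 32) for _ in channel_labels),
    ])
    scale = 65535.0 / (2 * phys_range)
    digital = np.clip(np.round((data_uv + phys_range) * scale) - 32768,
                      -32768, 32767).astype("<i2")
    body = b"".join(
        digital[ch, rec * fs:(rec + 1) * fs].tobytes()
        for rec in range(n_rec) for ch in range(n_ch)
    )
    path.write_bytes(hdr + per_sig + body)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def sine_recording() -> EEGRecording:
    """Two-channel 10 s recording: 10 Hz and 30 Hz unit sinusoids at 256 Hz."""
    fs = 256.0
    t = np.arange(int(10 * fs)) / fs
    data = np.stack([np.sin(2 * np.pi * 10 * t), np.sin(2 * np.pi * 30 * t)])
    return EEGRecording(data=data, fs=fs, channel_labels=["C3", "C4"],
                        subject_id="sine", label="unknown")


def make_feature_vectors(X: np.ndarray, labels: list[str]) -> list[FeatureVector]:
    names = [f"f{i}" for i in range(X.shape[1])]
    return [
        FeatureVector(values=x, feature_names=names, label=lab,
                      subject_id=f"s{i}", start_s=0.0)
        for i, (x, lab) in enumerate(zip(X, labels))
    ]


@pytest.fixture
def separable_toy() -> list[FeatureVector]:
    """40 two-dimensional points, two classes separated by ~4 sigma."""
    g = np.random.default_rng(7)
    X = np.vstack([g.normal([-2.0, -2.0], 1.0, (20, 2)),
                   g.normal([2.0, 2.0], 1.0, (20, 2))])
    labels = ["autistic"] * 20 + ["normal"] * 20
    return make_feature_vectors(X, labels)
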