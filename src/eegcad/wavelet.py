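"""Dyadic wavelet decomposition of EEG segments.

Each segment channel is decomposed with a 4-level discrete wavelet transform
using the Daubechies-4 (db4) mother wavelet, yielding detail coefficients
D1 (finest) through D4 and the final approximation A4.  With a 256 Hz
sampling rate the standard dyadic mapping assigns D1 to 64-128 Hz, D2 to
32-64 Hz (gamma), D3 to 16-32 Hz (beta), D4 to 8-16 Hz (alpha) and A4 to
0-8 Hz (theta + delta).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .preprocessing import Segment

#: Name of the untransformed segment channel in a coefficient set.
ORIG = "ORIG"


@dataclass
class WaveletCoefficients:
    """Per-channel wavelet coefficient arrays for one segment.

    ``coeffs`` maps channel label -> coefficient name (``D1``..``D4``,
    ``A4``, ``ORIG``) -> 1-D array.  ``ORIG`` is the raw channel signal.
    Segment provenance (subject, start time, label) is carried along so
    feature vectors can be traced back to their source window.
    """

    coeffs: dict[str, dict[str, np.ndarray]]
    wavelet: str
    levels: int
    fs: float
    subject_id: str = ""
    start_s: float = 0.0
    label: str = "unknown"

    @property
    def channel_labels(self) -> list[str]:
        return list(self.coeffs.keys())

    def names(self) -> list[str]:
        """Coefficient names, finest detail first: D1..D<levels>, A<levels>."""
        return [f"D{k}" for k in range(1, self.levels + 1)] + [f"A{self.levels}"]


def min_segment_length(wavelet: str, levels: int) -> int:
    """Shortest segment accepted for a ``levels``-deep decomposition."""
    return pywt.Wavelet(wavelet).dec_len * 2 ** levels


def dwt_decompose(
    seg: Segment,
    wavelet: str = "db4",
    levels: int = 4,
    mode: str = "symmetric",
) -> WaveletCoefficients:
    """Multi-level DWT of every channel of a segment.

    Returns detail coefficients ``D1``..``D<levels>`` and the final
    approximation ``A<levels>`` per channel, plus the untransformed channel
    under ``ORIG``.  Symmetric (half-sample) boundary extension by default;
    ``mode="periodization"`` gives exact energy conservation for orthogonal
    wavelets.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    nmin = min_segment_length(wavelet, levels)
    if seg.n_samples < nmin:
        raise ValueError(
            f"segment of {seg.n_samples} samples is too short for a "
            f"{levels}-level {wavelet} decomposition (minimum {nmin})"
        )
    out: dict[str, dict[str, np.ndarray]] = {}
    for ch, x in zip(seg.channel_labels, seg.data):
        arrs = pywt.wavedec(x, wavelet, level=levels, mode=mode)
        named = {f"A{levels}": arrs[0]}
        for k, d in enumerate(arrs[1:], start=1):
            named[f"D{levels + 1 - k}"] = d
        named[ORIG] = np.asarray(x, dtype=float)
        out[ch] = named
    return WaveletCoefficients(
        coeffs=out, wavelet=wavelet, levels=levels, fs=seg.fs,
        subject_id=seg.subject_id, start_s=seg.start_s, label=seg.label,
    )


def reconstruct_channel(wc: WaveletCoefficients, channel: str, mode: str = "symmetric") -> np.ndarray:
    """Inverse DWT of one channel's full coefficient set."""
    named = wc.coeffs[channel]
    arrs = [named[f"A{wc.levels}"]] + [named[f"D{k}"] for k in range(wc.levels, 0, -1)]
    n = named[ORIG].size
    return pywt.waverec(arrs, wc.wavelet, mode=mode)[:n]


def subband_frequency_map(fs: float, levels: int) -> dict[str, tuple[float, float]]:
    """Dyadic frequency band of each coefficient array.

    ``D_k`` spans ``(fs / 2**(k+1), fs / 2**k)``; ``A_levels`` spans
    ``(0, fs / 2**(levels+1))``.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    bands = {f"D{k}": (fs / 2 ** (k + 1), fs / 2 ** k) for k in range(1, levels + 1)}
    bands[f"A{levels}"] = (0.0, fs / 2 ** (levels + 1))
    return bands
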