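"""Two-class synthetic multichannel EEG generator.

Each channel is a sum of band-limited Gaussian noise components for the
conventional delta/theta/alpha/beta/gamma bands, with a 1/f-like weight
profile and a slow amplitude envelope per band (real EEG rhythms wax and
wane).  For the "autistic" class at positive effect size the alpha, beta
and gamma envelopes are sharpened into sparse oscillatory bursts, which
concentrates the histogram of the wavelet detail coefficients and lowers
their Shannon entropy monotonically with the effect size — the statistical
structure the subband-entropy classifier exploits — while every band's
variance is held at unity.  At effect size 0 the two classes are drawn
from the identical distribution.

The default dataset shape mirrors a small clinical resting-state cohort:
ten normal and nine autistic subjects, 16 channels in 10-20 placement at
256 Hz, with per-class recording-duration profiles of 5-27 min (normal,
148 min total) and 12-40 min (autistic, 173 min total).

The generator targets the statistical structure the method exploits, not
physiological realism; optional low-frequency blink transients (strongest on
FP1/FP2/F7/F8) are available for exercising the ocular-artifact stage.

All randomness flows from one master seed through a named substream per
subject, so datasets are reproducible recording by recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import DEFAULT_CHANNELS_16, EEGRecording
from .preprocessing import design_bandpass

#: (low Hz, high Hz, amplitude weight) of each synthesis band.
BAND_PROFILE = {
    "delta": (1.0, 4.0, 1.0),
    "theta": (4.0, 8.0, 0.8),
    "alpha": (8.0, 15.0, 0.7),
    "beta": (15.0, 30.0, 0.5),
    "gamma": (30.0, 60.0, 0.35),
}

#: Bands whose envelopes are sharpened in the autistic class.
EFFECT_BANDS = ("alpha", "beta", "gamma")

#: Per-subject recording durations (minutes).  Normal: 5-27 min each,
#: 148 min total; autistic: 12-40 min each, 173 min total.
NORMAL_DURATIONS_MIN = (5, 7, 9, 11, 13, 15, 17, 19, 25, 27)
AUTISTIC_DURATIONS_MIN = (12, 13, 14, 15, 17, 19, 21, 27, 35)

_CLASS_CODE = {"normal": 0, "autistic": 1}


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape and effect parameters of a synthetic two-class dataset.

    ``n_subjects_per_class`` is ``(n_normal, n_autistic)``; an int applies to
    both classes.  ``duration_s`` of ``None`` draws each subject's duration
    from the class profile (cycled); a number fixes all durations.
    ``effect_size`` of 0 makes the classes statistically identical; 2.0 is a
    strong, clearly separable effect.  ``blink_rate_hz`` > 0 adds ocular
    transients for artifact-removal testing.
    """

    n_subjects_per_class: int | tuple[int, int] = (10, 9)
    n_channels: int = 16
    fs: float = 256.0
    duration_s: float | None = None
    effect_size: float = 2.0
    blink_rate_hz: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")

    def class_counts(self) -> tuple[int, int]:
        """(n_normal, n_autistic)."""
        if isinstance(self.n_subjects_per_class, int):
            return self.n_subjects_per_class, self.n_subjects_per_class
        return tuple(self.n_subjects_per_class)  # type: ignore[return-value]

    def channel_labels(self) -> list[str]:
        if self.n_channels <= len(DEFAULT_CHANNELS_16):
            return list(DEFAULT_CHANNELS_16[: self.n_channels])
        extra = [f"X{i}" for i in range(self.n_channels - len(DEFAULT_CHANNELS_16))]
        return list(DEFAULT_CHANNELS_16) + extra

    def subject_duration_s(self, label: str, subject_index: int) -> float:
        if self.duration_s is not None:
            return float(self.duration_s)
        profile = AUTISTIC_DURATIONS_MIN if label == "autistic" else NORMAL_DURATIONS_MIN
        return 60.0 * profile[subject_index % len(profile)]


def _am_band_noise(rng: np.random.Generator, n: int, fs: float,
                   lo: float, hi: float, sharpness: float = 0.0) -> np.ndarray:
    """Band-limited Gaussian noise with a slow (~0.3 Hz) amplitude envelope.

    The waxing-and-waning envelope mimics the amplitude modulation of real
    EEG rhythms and gives channels a super-Gaussian marginal, which keeps
    the blind source separation of the artifact-removal stage identifiable
    (independent Gaussian channels would leave ICA rotation-degenerate).

    ``sharpness`` > 0 raises the envelope to the power ``1 + sharpness``,
    turning sustained activity into sparse bursts.  Sparse oscillatory
    bursts concentrate the histogram of the signal (and of its wavelet
    detail coefficients), lowering subband entropy monotonically with
    ``sharpness`` while total variance is held at unity.
    """
    sos = design_bandpass(lo, hi, fs)
    bn = signal.sosfiltfilt(sos, rng.standard_normal(n))
    env_sos = signal.butter(2, 0.3, fs=fs, output="sos")
    env = signal.sosfiltfilt(env_sos, rng.standard_normal(n))
    env = np.clip(1.0 + 0.8 * env / env.std(), 0.05, None)
    if sharpness > 0:
        env = env ** (1.0 + sharpness)
    x = bn * env
    return x / x.std()


def _blink_train(rng: np.random.Generator, n: int, fs: float, rate_hz: float) -> np.ndarray:
    """Positive low-frequency transients (~300 ms Gaussian bumps)."""
    out = np.zeros(n)
    width = int(0.15 * fs)
    kernel = np.exp(-0.5 * ((np.arange(-3 * width, 3 * width + 1)) / width) ** 2)
    n_events = rng.poisson(rate_hz * n / fs)
    for center in rng.integers(0, n, size=n_events):
        lo = max(0, center - 3 * width)
        hi = min(n, center + 3 * width + 1)
        out[lo:hi] += kernel[: hi - lo]
    return out


def generate_recording(
    spec: SyntheticSpec,
    label: str,
    subject_index: int = 0,
    subject_id: str | None = None,
) -> EEGRecording:
    """One synthetic subject recording of the given class.

    Deterministic: the subject's random substream is derived from
    ``(spec.seed, class, subject_index)``.
    """
    if label not in _CLASS_CODE:
        raise ValueError(f"label must be 'normal' or 'autistic', got {label!r}")
    rng = np.random.default_rng([spec.seed, _CLASS_CODE[label], subject_index])
    dur = spec.subject_duration_s(label, subject_index)
    n = int(round(dur * spec.fs))
    effect = spec.effect_size if label == "autistic" else 0.0

    data = np.empty((spec.n_channels, n))
    blink = None
    if spec.blink_rate_hz > 0:
        blink = _blink_train(rng, n, spec.fs, spec.blink_rate_hz)
    labels = spec.channel_labels()
    for ci, ch in enumerate(labels):
        x = np.zeros(n)
        for band, (lo, hi, w) in BAND_PROFILE.items():
            sharp = effect if band in EFFECT_BANDS else 0.0
            x += w * _am_band_noise(rng, n, spec.fs, lo, hi, sharpness=sharp)
        if blink is not None:
            frontal = ch in ("FP1", "FP2", "F7", "F8")
            x += (8.0 if frontal else 0.5) * blink
        data[ci] = x

    sid = subject_id or f"{'A' if label == 'autistic' else 'N'}{subject_index + 1:02d}"
    return EEGRecording(data=data, fs=spec.fs, channel_labels=labels,
                        subject_id=sid, label=label)


def generate_dataset(spec: SyntheticSpec) -> list[EEGRecording]:
    """All recordings of both classes (normal subjects first)."""
    n_normal, n_autistic = spec.class_counts()
    recs = [generate_recording(spec, "normal", i) for i in range(n_normal)]
    recs += [generate_recording(spec, "autistic", i) for i in range(n_autistic)]
    return recs
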