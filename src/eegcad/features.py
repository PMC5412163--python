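"""Entropy and statistical features on wavelet coefficient arrays.

Entropies are defined over a discrete probability distribution.  Wavelet
coefficients are continuous, so almost every value is unique and a
unique-value distribution would degenerate to log2(n); probabilities are
therefore estimated with an equal-width histogram (default 256 bins) over
each array's own range, with empty bins dropped.  Because the bins scale
with the range, Shannon and Renyi entropies are invariant under affine
rescaling of the signal, which makes them robust to amplifier gain.  The
threshold count is *not* scale-invariant: it counts coefficients whose
absolute value exceeds a fixed threshold (default 0.2).

One feature function is used per experiment; a feature vector holds one
value per (channel, selected coefficient) pair, channels-major.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .wavelet import ORIG, WaveletCoefficients


@dataclass
class ProbabilityEstimate:
    """Occupied-bin probabilities of a histogram density estimate.

    Invariants: every ``p_i > 0`` (empty bins removed) and ``sum(p) == 1``.
    """

    p: np.ndarray
    k: int
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.size == 0 or (self.p <= 0).any():
            raise ValueError("probabilities must be positive (drop empty bins)")
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")


@dataclass
class FeatureVector:
    """Ordered features for one segment plus provenance and class label."""

    values: np.ndarray
    feature_names: list[str]
    label: str
    subject_id: str = ""
    start_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.feature_names):
            raise ValueError("values and feature_names lengths differ")
        if not np.isfinite(self.values).all():
            raise ValueError("feature values must be finite")


def estimate_probabilities(x: np.ndarray, n_bins: int = 256) -> ProbabilityEstimate:
    """Equal-width histogram probabilities over ``[min(x), max(x)]``.

    Empty bins are dropped.  A degenerate array (all values equal) yields a
    single bin with probability one.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot estimate probabilities of an empty array")
    if not np.isfinite(x).all():
        raise ValueError("input contains non-finite values")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lo, hi = x.min(), x.max()
    if lo == hi:
        return ProbabilityEstimate(p=np.array([1.0]), k=1,
                                   bin_edges=np.array([lo, hi]))
    counts, edges = np.histogram(x, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return ProbabilityEstimate(p=p, k=int(p.size), bin_edges=edges)


def shannon_entropy(pe: ProbabilityEstimate) -> float:
    """``H = -sum p_i log2 p_i`` in bits; 0 <= H <= log2(k)."""
    return float(-(pe.p * np.log2(pe.p)).sum())


def log_energy_entropy(pe: ProbabilityEstimate) -> float:
    """``H = sum log(p_i^2)`` over occupied bins (natural log)."""
    return float(np.log(pe.p ** 2).sum())


def renyi_entropy(pe: ProbabilityEstimate, alpha: float = 2.0) -> float:
    """``H = log(sum p_i^alpha) / (1 - alpha)`` (natural log), alpha >= 0, != 1.

    The alpha -> 1 limit is the Shannon entropy in nats; pass alpha close to
    (but not equal to) 1 for that regime, or use :func:`shannon_entropy`.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if alpha == 1.0:
        raise ValueError("alpha=1 is the Shannon limit; use shannon_entropy")
    return float(np.log((pe.p ** alpha).sum()) / (1.0 - alpha))


def threshold_entropy(x: np.ndarray, thr: float = 0.2, *, absolute: bool = True) -> int:
    """Count of samples strictly exceeding the threshold.

    With ``absolute=True`` (default) the comparison is ``|x_i| > thr``;
    wavelet coefficients are signed, so a one-sided count would ignore half
    the excursions.  Not scale-invariant by construction.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("input contains non-finite values")
    if thr < 0:
        raise ValueError("threshold must be non-negative")
    v = np.abs(x) if absolute else x
    return int((v > thr).sum())


def statistical_features(x: np.ndarray) -> dict[str, float]:
    """Population moments: mean, std, variance, skewness, kurtosis.

    Kurtosis is the non-excess (Pearson) definition, 3 for a Gaussian.
    Zero-variance input yields 0 for skewness and kurtosis with a warning
    (keeps feature matrices finite).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least two samples for moment features")
    var = float(np.var(x))
    out = {
        "mean": float(np.mean(x)),
        "std": float(np.std(x)),
        "variance": var,
    }
    if var == 0.0:
        warnings.warn("zero-variance array: skewness and kurtosis set to 0")
        out["skewness"] = 0.0
        out["kurtosis"] = 0.0
    else:
        out["skewness"] = float(stats.skew(x, bias=True))
        out["kurtosis"] = float(stats.kurtosis(x, fisher=False, bias=True))
    return out


#: Feature functions selectable per experiment.
FEATURE_FUNCTIONS = (
    "mean", "std", "variance", "skewness", "kurtosis",
    "log_energy", "threshold", "renyi", "shannon",
)

#: Coefficient selections named after the subband combinations commonly swept.
DEFAULT_SELECTION = ("D1", "D2", "D3", "D4")


def compute_feature(
    x: np.ndarray,
    function: str,
    *,
    n_bins: int = 256,
    threshold: float = 0.2,
    threshold_abs: bool = True,
    renyi_alpha: float = 2.0,
) -> float:
    """Evaluate one named feature function on one coefficient array."""
    if function in ("mean", "std", "variance", "skewness", "kurtosis"):
        return statistical_features(x)[function]
    if function == "threshold":
        return float(threshold_entropy(x, threshold, absolute=threshold_abs))
    pe = estimate_probabilities(x, n_bins)
    if function == "shannon":
        return shannon_entropy(pe)
    if function == "log_energy":
        return log_energy_entropy(pe)
    if function == "renyi":
        return renyi_entropy(pe, renyi_alpha)
    raise ValueError(f"unknown feature function {function!r}; "
                     f"choose one of {FEATURE_FUNCTIONS}")


def build_feature_vector(
    wc: WaveletCoefficients,
    selection: tuple[str, ...] = DEFAULT_SELECTION,
    function: str = "shannon",
    **feature_kwargs,
) -> FeatureVector:
    """One feature value per (channel, selected coefficient), channels-major.

    ``selection`` is an ordered subset of ``{ORIG, D1..D<levels>, A<levels>}``.
    Feature names encode ``channel.coefficient.function``.
    """
    if len(selection) == 0:
        raise ValueError("coefficient selection must be non-empty")
    valid = set(wc.names()) | {ORIG}
    bad = [s for s in selection if s not in valid]
    if bad:
        raise ValueError(f"unknown coefficient names {bad}; valid: {sorted(valid)}")
    values, names = [], []
    for ch in wc.channel_labels:
        for coef in selection:
            values.append(compute_feature(wc.coeffs[ch][coef], function, **feature_kwargs))
            names.append(f"{ch}.{coef}.{function}")
    return FeatureVector(
        values=np.array(values), feature_names=names,
        label=wc.label, subject_id=wc.subject_id, start_s=wc.start_s,
    )
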