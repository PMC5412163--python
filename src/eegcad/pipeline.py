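"""End-to-end feature extraction: recording -> filter -> segment -> DWT -> features."""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

from .config import DEFAULTS
from .features import FeatureVector, build_feature_vector
from .io import EEGRecording
from .preprocessing import (
    SegmentationSpec,
    bandpass_filter,
    notch_filter,
    remove_ocular_artifacts,
    segment_recording,
)
from .wavelet import dwt_decompose

log = logging.getLogger("eegcad")


def extract_features(recordings: Iterable[EEGRecording], cfg: dict | None = None) -> list[FeatureVector]:
    """Run the full preprocessing + wavelet + feature chain on recordings.

    One feature vector per segment; configuration keys as in
    :data:`eegcad.config.DEFAULTS`.
    """
    cfg = cfg or DEFAULTS
    spec = SegmentationSpec(cfg["segment"]["length_s"], cfg["segment"]["overlap"])
    out: list[FeatureVector] = []
    for rec in recordings:
        if cfg["ica"]["enabled"]:
            rec = remove_ocular_artifacts(
                rec,
                tuple(cfg["ica"]["ref_channels"]),
                threshold=cfg["ica"]["threshold"],
                seed=cfg["ica"]["seed"],
            )
        rec = bandpass_filter(rec, cfg["filter"]["low_hz"], cfg["filter"]["high_hz"])
        if cfg["filter"]["notch_enabled"]:
            rec = notch_filter(rec, cfg["filter"]["notch_hz"])
        segments = segment_recording(rec, spec)
        log.info("subject %s: %d segments of %.0f s (overlap %.2f)",
                 rec.subject_id, len(segments), spec.segment_length_s,
                 spec.overlap_fraction)
        for seg in segments:
            wc = dwt_decompose(seg, cfg["dwt"]["wavelet"], cfg["dwt"]["levels"],
                               cfg["dwt"]["mode"])
            out.append(
                build_feature_vector(
                    wc,
                    tuple(cfg["features"]["selection"]),
                    cfg["features"]["function"],
                    n_bins=cfg["features"]["n_bins"],
                    threshold=cfg["features"]["threshold"],
                    threshold_abs=cfg["features"]["threshold_abs"],
                    renyi_alpha=cfg["features"]["renyi_alpha"],
                )
            )
    log.info("extracted %d feature vectors", len(out))
    return out
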