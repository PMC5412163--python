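"""Experiment configuration: defaults, YAML loading and overrides.

The default configuration reproduces the method's best-performing setting:
detail bands D1-D4, Shannon entropy features, 60 s windows with half-segment
overlap, 10-fold cross-validation, ocular-artifact removal off.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "filter": {"low_hz": 0.1, "high_hz": 60.0, "notch_hz": 60.0, "notch_enabled": False},
    "ica": {
        "enabled": False,
        "ref_channels": ["FP1", "FP2", "F7", "F8"],
        "threshold": 0.7,
        "seed": 0,
    },
    "segment": {"length_s": 60.0, "overlap": 0.5},
    "dwt": {"wavelet": "db4", "levels": 4, "mode": "symmetric"},
    "features": {
        "function": "shannon",
        "n_bins": 256,
        "threshold": 0.2,
        "threshold_abs": True,
        "renyi_alpha": 2.0,
        "selection": ["D1", "D2", "D3", "D4"],
    },
    "ann": {"hidden": 5, "lr": 0.01, "momentum": 0.9, "epochs": 500,
            "tol": 1e-6, "seed": 0},
    "evaluation": {"k": 10, "seed": 0},
    "synthetic": {
        "n_normal": 10,
        "n_autistic": 9,
        "n_channels": 16,
        "fs": 256.0,
        "duration_s": None,
        "effect_size": 2.0,
        "blink_rate_hz": 0.0,
        "seed": 0,
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, optionally updated from a YAML file and an override mapping."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        cfg = _deep_merge(cfg, loaded)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def archive_config(cfg: dict, out_dir: str | Path) -> Path:
    """Write the resolved config (plus package version) beside run outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"eegcad_version": __version__, "config": cfg}
    path = out_dir / "resolved_config.json"
    path.write_text(json.dumps(payload, indent=2))
    return path
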