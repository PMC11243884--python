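"""Declarative pipeline configuration.

One YAML file is the single source of truth for a run; CLI flags override
individual keys.  Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from .errors import ValidationError

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synth": {
        "grid_rows": 32,
        "grid_cols": 32,
        "n_active_sensors": 548,
        "sampling_rate": 32.0,
        "duration": 8.0,
        "onset_time": 1.5,
        "offset_time": 6.5,
        "peak_pressure": 600.0,
        "n_blobs": 3,
        "blob_width": 2.0,
        "temporal_smoothness": 0.4,
        "noise_sd": 2.0,
        "bit_depth": 10,
        "n_trials": 10,
        "jitter": {"onset_sd": 0.2, "amplitude_sd": 0.1, "center_sd": 1.0},
    },
    "denoise": {
        "enabled": True,
        "order": 2,
        "cutoff_fraction": 1.0 / 7.0,
        "causal": False,
    },
    "transform": {
        "wavelet": "sym4",
        "dimensionality": 1,
        "level": "max",
        "extension_mode": "periodization",
    },
    "sparsify": {
        "targets": [0.01, 0.0043, 0.0015, 0.0001],
        "tolerance_factor": 1e-4,
        "max_iterations": 60,
        "normalization": "mean",
    },
    "survey": {
        "wavelets": "all",  # or explicit list of registry names
        "dimensionalities": [1, 2, 3],
        "include_dct": True,
    },
    "diagnostics": {
        "recording_index": 0,
        "wavelet": "sym4",
        "dimensionality": 1,
        "k_values": [0, 16, 64, 256, 1024, 4096],
        "scaling_iterations": 5,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise ValidationError(f"config: unknown key {where!r}")
        if isinstance(base[key], dict) and not isinstance(value, dict):
            raise ValidationError(f"config: {where!r} must be a mapping")
        if isinstance(base[key], dict):
            out[key] = _merge(base[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults merged with an optional YAML override file."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    loaded = yaml.safe_load(path.read_text()) or {}
    if not isinstance(loaded, dict):
        raise ValidationError("config: top level must be a mapping")
    return _merge(DEFAULT_CONFIG, loaded)


def config_hash(config: dict) -> str:
    """Short stable hash identifying a configuration."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
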