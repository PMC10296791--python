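"""Declarative pipeline configuration.

A nested key/value mapping with defaults for every tunable knob in the
pipeline. Files are YAML; unknown keys are rejected so that typos fail
loudly. ``config_hash`` gives a stable digest that every artifact records
for provenance.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "DEFAULTS"]

DEFAULTS: dict = {
    "seed": 0,
    "filter": {
        "airflow": {"cutoff_hz": 0.3, "order": 4},
        "ecg": {"median_ms": [200.0, 600.0]},
    },
    "segment": {"window_s": 10.0, "overlap": 0.0, "context_s": 25.0},
    "entropy": {
        "n_bins": 10, "renyi_alpha": 2.0, "tsallis_q": 2.0,
        "te_lag": 1, "te_bins": 3, "word_length": 3,
    },
    "model": {
        "kind": "gradient_boosted_trees",
        "split_mode": "stratified_random",
        "test_frac": 0.2,
        "select_alpha": 0.05,
    },
    "subtype": {
        "overlap": 0.9, "normalization": "zscore", "exclusion_w": 0,
        "hidden": 32, "epochs": 300, "lr": 0.01,
    },
    "simulate": {
        "n_subjects": 4,
        "record_length_s": 1200.0,
        "ahi_targets": [3.0, 9.0, 21.0, 36.0],
        "mean_hr_bpm": 70.0,
        "breath_rate_hz": 0.25,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown config key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise TypeError(f"config key {here} must be a mapping")
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


class PipelineConfig:
    """Validated configuration; behaves like a nested read-only mapping."""

    def __init__(self, overrides: dict | None = None):
        self.data = _merge(DEFAULTS, overrides or {})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        return cls(yaml.safe_load(text) or {})

    def __getitem__(self, key: str):
        node = self.data
        for part in key.split("."):
            node = node[part]
        return node

    def override(self, key: str, value) -> None:
        parts = key.split(".")
        node = self.data
        for part in parts[:-1]:
            node = node[part]
        if parts[-1] not in node:
            raise KeyError(f"unknown config key: {key}")
        node[parts[-1]] = value

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def to_json(self) -> str:
        return json.dumps(self.data, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]
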