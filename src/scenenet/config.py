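"""Run configuration: the standard architecture table as defaults, strict
YAML/JSON loading, and named random-substream derivation from one seed.

The three-layer defaults (32x32 neurons per layer; 54 connections and
radius 1 into Layer 1 from V1; 40 connections and radius 1.7 into Layers 2
and 3; sparseness targets 0.1 / 0.12 / 0.08) are the architecture used for
the worked alphanumeric-scene demonstrations.
"""

from __future__ import annotations

import copy
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .topology import LayerConfig

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "architecture": {
        "layer1": {
            "n_rows": 32, "n_cols": 32, "n_connections": 54, "radius": 1.0,
            "sparseness": 0.1, "alpha": 1.0, "trace_eta": 0.0,
            "lateral_inhibition": {
                "enabled": True, "center_radius": 0.2, "surround_radius": 1.5,
            },
        },
        "layer2": {
            "n_rows": 32, "n_cols": 32, "n_connections": 40, "radius": 1.7,
            "sparseness": 0.12, "alpha": 1.0, "trace_eta": 0.0,
            "lateral_inhibition": {
                "enabled": True, "center_radius": 0.2, "surround_radius": 1.5,
            },
        },
        "layer3": {
            "n_rows": 32, "n_cols": 32, "n_connections": 40, "radius": 1.7,
            "sparseness": 0.08, "alpha": 1.0, "trace_eta": 0.0,
            "lateral_inhibition": {
                "enabled": True, "center_radius": 0.2, "surround_radius": 1.5,
            },
        },
    },
    "gabor": {
        "n_freq": 4, "n_orient": 4, "base_wavelength": 4.0,
        "octave_spacing": 2.0, "sigma_factor": 0.5, "freq_ratio": 2.0,
    },
    "training": {
        "n_epochs": 7, "n_update_presentations": 4,
        "n_buildup_presentations": 5, "sequential": True,
        "jitter": {"enabled": False, "amplitude_px": 4, "n_transforms": 3},
    },
    "attractor": {"alpha": 0.01, "sigma_d": 4.0, "w_max": 1.0,
                  "recall_sparseness": 0.08},
    "demo": {"adaptation_decay": 0.9, "adaptation_strength": 1.0,
             "n_steps": 200},
}


def _merge_strict(defaults: dict, override: dict, prefix: str = "") -> tuple[dict, list[str]]:
    merged = copy.deepcopy(defaults)
    bad: list[str] = []
    for key, value in override.items():
        path = f"{prefix}{key}"
        if key not in defaults:
            bad.append(path)
            continue
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                bad.append(f"{path} (expected a mapping)")
                continue
            merged[key], sub_bad = _merge_strict(defaults[key], value, path + ".")
            bad.extend(sub_bad)
        else:
            merged[key] = value
    return merged, bad


@dataclass
class RunConfig:
    """Resolved configuration: the defaults with user overrides applied."""

    data: dict[str, Any]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def layer_config(self, layer: int) -> LayerConfig:
        d = self.data["architecture"][f"layer{layer}"]
        inh = d["lateral_inhibition"]
        return LayerConfig(
            n_rows=d["n_rows"], n_cols=d["n_cols"],
            n_connections=d["n_connections"], radius=d["radius"],
            sparseness=d["sparseness"], alpha=d["alpha"],
            trace_eta=d["trace_eta"],
            inhibition_enabled=inh["enabled"],
            inhibition_center_radius=inh["center_radius"],
            inhibition_surround_radius=inh["surround_radius"],
        )

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.data, sort_keys=False))


def make_config(overrides: dict[str, Any] | None = None) -> RunConfig:
    """Build a RunConfig from the defaults plus an override mapping.

    Unknown keys are rejected with an error listing every offending key.
    """
    merged, bad = _merge_strict(DEFAULTS, overrides or {})
    if bad:
        raise ValueError("unknown configuration keys: " + ", ".join(sorted(bad)))
    return RunConfig(merged)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML (or JSON, a YAML subset) config file; None or an empty
    file yields the pure defaults."""
    if path is None:
        return make_config({})
    text = Path(path).read_text()
    loaded = yaml.safe_load(text)
    if loaded is None:
        loaded = {}
    if not isinstance(loaded, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return make_config(loaded)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible random substream derived from the single run
    seed (so components can be re-run independently yet reproducibly)."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
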