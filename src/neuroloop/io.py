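"""File-format plumbing: configs, CSV exports, NDJSON logs, record files.

Emulates the device-side file system: raw recordings as two-column CSV,
power-sample streams as CSV tables, event/transition logs as NDJSON, and
trained boundaries as JSON.  Configuration files may be JSON or TOML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import LinearBoundary
from .control_policy import ControllerConfig
from .plant import PlantParams

__all__ = [
    "load_config",
    "plant_params_from_config",
    "controller_config_from_config",
    "write_raw_csv",
    "read_raw_csv",
    "write_power_csv",
    "write_ndjson",
    "read_ndjson",
    "append_ndjson",
    "save_boundary",
    "load_boundary",
    "write_manifest",
]


def load_config(path: str | Path) -> dict:
    """Read a JSON or TOML configuration file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".toml":
        import tomllib
        return tomllib.loads(text)
    return json.loads(text)


def _from_section(cls, cfg: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    sub = cfg.get(section, {})
    unknown = set(sub) - names
    if unknown:
        raise KeyError(f"unknown {section} keys: {sorted(unknown)}")
    return cls(**sub)


def plant_params_from_config(cfg: dict) -> PlantParams:
    return _from_section(PlantParams, cfg, "plant")


def controller_config_from_config(cfg: dict) -> ControllerConfig:
    return _from_section(ControllerConfig, cfg, "controller")


def write_raw_csv(path: str | Path, samples: np.ndarray,
                  fs: float = 422.0, t0: float = 0.0) -> None:
    """Raw waveform export: columns time_s, microvolts."""
    samples = np.asarray(samples, dtype=float)
    t = t0 + np.arange(samples.size) / fs
    pd.DataFrame({"time_s": t, "microvolts": samples}).to_csv(
        path, index=False)


def read_raw_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_power_csv(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)


def write_ndjson(path: str | Path, records: list[dict]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def append_ndjson(path: str | Path, record: dict) -> None:
    with open(path, "a") as fh:
        fh.write(json.dumps(record) + "\n")


def read_ndjson(path: str | Path) -> list[dict]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(json.loads(line))
    return out


def save_boundary(path: str | Path, boundary: LinearBoundary,
                  extra: dict | None = None) -> None:
    d = json.loads(boundary.to_json())
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d, indent=2))


def load_boundary(path: str | Path) -> LinearBoundary:
    return LinearBoundary.from_json(Path(path).read_text())


def write_manifest(path: str | Path, config: dict) -> None:
    """Full-run manifest capturing configuration for reproducibility."""
    Path(path).write_text(json.dumps(config, indent=2, default=str))
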