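"""Run configuration parsing and result writers.

Config files are YAML with flat run-level keys plus a nested ``model``
block holding ModelParams fields.  Unknown keys are rejected so typos
surface immediately.  Results are written as CSV with a JSON sidecar
recording parameters, seed, package version and timestamp (the
timestamp is excluded from determinism comparisons).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .params import ModelParams

__all__ = ["RunConfig", "parse_config", "write_results"]

_RUN_KEYS = {"experiment", "seed", "max_divisions", "max_events",
             "out_dir", "format", "profile", "model"}


@dataclass
class RunConfig:
    model: ModelParams
    experiment: str = "simulate"
    seed: int = 0
    max_divisions: int = 10_000
    max_events: int = 0
    out_dir: str = "."
    format: str = "csv"
    profile: str = "ci"

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("experiment", "seed", "max_divisions", "max_events",
              "out_dir", "format", "profile")}
        d["model"] = self.model.to_dict()
        return d


def parse_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    The ``model`` block fills unspecified rate constants with the
    standard values k_f = k_b = k_x = k_y = 1, D = 0, p_loss = 0.
    Unknown keys anywhere raise ValueError naming the key.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = set(raw) - _RUN_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    model_block = raw.pop("model", {})
    if not isinstance(model_block, dict):
        raise ValueError("'model' must be a mapping")
    model = ModelParams.from_dict(model_block)
    cfg = RunConfig(model=model, **raw)
    if cfg.format not in ("csv", "json"):
        raise ValueError(f"format must be csv or json, got {cfg.format!r}")
    if cfg.profile not in ("ci", "full"):
        raise ValueError(f"profile must be ci or full, got {cfg.profile!r}")
    return cfg


def write_results(records: pd.DataFrame, path: str | Path,
                  format: str = "csv", meta: dict | None = None) -> None:
    """Write a result table plus a JSON metadata sidecar.

    CSV keeps the DataFrame's column order; an empty table yields a
    header-only file.  The sidecar ``<path>.meta.json`` carries the
    caller's metadata (parameters, seed, ...) plus package version and
    an ISO timestamp.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        records.to_csv(path, index=False)
    elif format == "json":
        records.to_json(path, orient="records", indent=1)
    else:
        raise ValueError(f"format must be csv or json, got {format!r}")
    from . import __version__
    sidecar = {"version": __version__,
               "timestamp": datetime.now(timezone.utc).isoformat(),
               **(meta or {})}
    Path(str(path) + ".meta.json").write_text(
        json.dumps(sidecar, indent=1, default=str))
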