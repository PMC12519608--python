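"""File formats: survival CSV, model JSON, simulation-config YAML, provenance.

The survival CSV has a header row with columns ``id`` (optional), ``time``,
``status`` (0 = censored, k = cause k) and covariates.  Model sets are
serialized as JSON (knots, spline and regression coefficients per cause);
Python's shortest-round-trip float repr keeps doubles bit-faithful.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .dataset import SurvivalDataset
from .fpm import ModelSet
from .simulator import CauseEffects, SimulationConfig, WeibullBaseline

__all__ = [
    "read_survival_csv",
    "write_survival_csv",
    "save_model_set",
    "load_model_set",
    "config_to_dict",
    "config_from_dict",
    "save_config",
    "load_config",
    "file_sha256",
    "write_provenance",
]


def read_survival_csv(path, n_causes: int | None = None) -> SurvivalDataset:
    """Read and validate a survival CSV (errors carry offending row numbers)."""
    frame = pd.read_csv(path)
    return SurvivalDataset(frame, n_causes=n_causes)


def write_survival_csv(data: SurvivalDataset, path) -> None:
    data.frame.to_csv(path, index=False)


def save_model_set(models: ModelSet, path) -> None:
    Path(path).write_text(json.dumps(models.to_dict(), indent=1))


def load_model_set(path) -> ModelSet:
    return ModelSet.from_dict(json.loads(Path(path).read_text()))


def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "baselines": [{"rate": b.rate, "shape": b.shape} for b in config.baselines],
        "effects": [
            {"x1": e.x1, "x1_sq": e.x1_sq, "x2": e.x2, "x3": e.x3, "x4": list(e.x4)}
            for e in config.effects
        ],
        "c_admin": config.c_admin,
        "n": config.n,
        "seed": config.seed,
        "x4_probs": list(config.x4_probs),
        "censoring_rate": config.censoring_rate,
    }


def config_from_dict(d: dict) -> SimulationConfig:
    return SimulationConfig(
        baselines=tuple(WeibullBaseline(b["rate"], b["shape"]) for b in d["baselines"]),
        effects=tuple(
            CauseEffects(e["x1"], e["x1_sq"], e["x2"], e["x3"], tuple(e["x4"]))
            for e in d["effects"]
        ),
        c_admin=float(d.get("c_admin", 10.0)),
        n=int(d.get("n", 50_000)),
        seed=int(d.get("seed", 0)),
        x4_probs=tuple(d.get("x4_probs", (0.25, 0.25, 0.25, 0.25))),
        censoring_rate=float(d.get("censoring_rate", 0.0)),
    )


def save_config(config: SimulationConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def load_config(path) -> SimulationConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_provenance(path, **fields) -> None:
    """JSON sidecar recording hashes, seeds and settings of a pipeline step."""
    Path(path).write_text(json.dumps(fields, indent=1, default=str))
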