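"""Configuration parsing and result serialization.

One flat key-value file (YAML mapping of scalars) drives every analysis:
model-parameter overrides, integrator tolerances and scenario settings.
Unknown keys are rejected, defaults reproduce the baseline parameter table
exactly, and every value is echoed to the log with its source so a run is
auditable.  Reports are written as JSON carrying a full parameter echo and
a hash of the effective configuration; trajectories as tidy CSV with a
fixed column order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from .model import ModelParams, Trajectory

__all__ = ["RunConfig", "load_config", "write_trajectory_csv",
           "read_trajectory_csv", "write_json_report"]

logger = logging.getLogger("wolbsim")

#: Fixed trajectory CSV column order.
TRAJECTORY_COLUMNS = ("t", "Mu", "Mw", "Fu", "Fw", "Eu", "Ew", "Lu", "Lw",
                      "frac_female", "frac_adult")

_PARAM_KEYS = tuple(f.name for f in fields(ModelParams))


@dataclass
class RunConfig:
    """Validated run settings: parameters plus scenario knobs."""

    params: ModelParams = field(default_factory=ModelParams)
    rtol: float = 1e-8
    atol: float = 1e-6
    # intervention scenario
    mitigation_larvae: float = 0.0
    mitigation_adults: float = 0.0
    release_factor: float = 0.0
    release_batches: int = 1
    release_window: float = 60.0
    release_start_day: float = 0.0
    time_limit: float | None = None
    # seasonality
    season_amplitude: float | None = None
    season_seed: int = 0
    rainfall_file: str | None = None
    # reporting
    metric: str = "female"
    horizon: float = 3000.0

    def __post_init__(self) -> None:
        if self.metric not in ("female", "adult"):
            raise ValueError("metric must be 'female' or 'adult'")
        for name in ("rtol", "atol", "horizon"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("mitigation_larvae", "mitigation_adults"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def to_dict(self) -> dict:
        out = {k: v for k, v in dataclasses.asdict(self).items() if k != "params"}
        out.update(self.params.to_dict())
        return out

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


_SCENARIO_KEYS = tuple(f.name for f in fields(RunConfig) if f.name != "params")


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a flat key-value config file.

    An empty (or missing ``path=None``) configuration yields the full
    baseline defaults.  Unknown keys, out-of-range fractions and
    non-positive rates are rejected.  Every model parameter is logged with
    its source (default vs override).
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("config must be a flat key-value mapping")
        raw = loaded
    unknown = set(raw) - set(_PARAM_KEYS) - set(_SCENARIO_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    def _coerce(value):
        # YAML 1.1 leaves "1.0e5" (no sign) as a string; accept it as float
        if isinstance(value, str):
            try:
                return float(value)
            except ValueError:
                return value
        return value

    param_overrides = {k: _coerce(raw[k]) for k in raw if k in _PARAM_KEYS}
    scenario = {k: _coerce(raw[k]) for k in raw if k in _SCENARIO_KEYS}
    params = ModelParams(**param_overrides)  # validates ranges
    for key in _PARAM_KEYS:
        source = "override" if key in param_overrides else "default"
        logger.info("param %-10s = %-12g (%s)", key, getattr(params, key), source)
    cfg = RunConfig(params=params, **scenario)
    for key in _SCENARIO_KEYS:
        if key in scenario:
            logger.info("config %-18s = %s (override)", key, scenario[key])
    return cfg


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    frame = traj.to_frame()[list(TRAJECTORY_COLUMNS)]
    frame.to_csv(path, index=False, float_format="%.10g")


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(TRAJECTORY_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"trajectory file missing columns: {sorted(missing)}")
    return frame


def write_json_report(payload: dict, path: str | Path,
                      config: RunConfig | None = None) -> None:
    """Serialize a report with a reproducibility echo.

    The effective configuration (all parameters and scenario settings) and
    its hash are embedded so the output is self-describing; key order is
    deterministic.
    """
    doc = dict(payload)
    if config is not None:
        doc["config"] = config.to_dict()
        doc["config_hash"] = config.config_hash()
    Path(path).write_text(json.dumps(_jsonify(doc), indent=2, sort_keys=True) + "\n")


def _jsonify(obj):
    import numpy as np
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and obj != obj:  # NaN
        return None
    return obj
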