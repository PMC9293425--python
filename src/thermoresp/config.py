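"""Pipeline configuration: one structured file drives every stage.

All defaults are valid without any user input; a YAML file (or a
nested dict) can override any field.  Dict-valued fields (anchors,
medians) are replaced wholesale when overridden; tuples may be given
as YAML lists.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .constants import ThermoConstants
from .simulate import DesignSpec, EnvironmentModel, IncubationProtocol, TraitModel

__all__ = ["FittingConfig", "StatsConfig", "StudyConfig", "load_config", "config_hash"]


@dataclass
class FittingConfig:
    min_positive_points: int = 5
    q10_grid_C: tuple[float, float, float] = (5.0, 45.0, 1.0)  # start, stop, step


@dataclass
class StatsConfig:
    alpha: float = 0.05
    anova_factors: tuple[str, str, str] = ("biome", "depth", "distance_m")
    stepwise_covariates: tuple[str, ...] = ("MET_C", "Ws_m3m3", "C_pct")
    lmm_group: str = "transect"


@dataclass
class StudyConfig:
    """Top-level configuration for the synthetic-study pipeline."""

    seed: int = 0
    dead_sample: bool = True
    constants: ThermoConstants = field(default_factory=ThermoConstants)
    design: DesignSpec = field(default_factory=DesignSpec)
    environment: EnvironmentModel = field(default_factory=EnvironmentModel)
    traits: TraitModel = field(default_factory=TraitModel)
    protocol: IncubationProtocol = field(default_factory=IncubationProtocol)
    fitting: FittingConfig = field(default_factory=FittingConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)


def _coerce(value, target):
    """Coerce YAML scalars/lists toward the type of the default value."""
    if isinstance(target, tuple) and isinstance(value, (list, tuple)):
        return tuple(value)
    if isinstance(target, dict) and isinstance(value, dict):
        # dict keys may arrive as lists (YAML has no tuple keys)
        out = {}
        for k, v in value.items():
            if isinstance(next(iter(target), None), tuple) and isinstance(k, str):
                k = tuple(x.strip() for x in k.split("|"))
                k = tuple(int(x) if x.lstrip("-").isdigit() else x for x in k)
            out[k] = v
        return out
    return value


def _update_dataclass(obj, overrides: dict):
    """Recursively apply a dict of overrides to a dataclass instance."""
    changes = {}
    names = {f.name for f in dataclasses.fields(obj)}
    for key, value in overrides.items():
        if key not in names:
            raise ValueError(f"unknown configuration field: {type(obj).__name__}.{key}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            changes[key] = _update_dataclass(current, value)
        else:
            changes[key] = _coerce(value, current)
    return dataclasses.replace(obj, **changes)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> StudyConfig:
    """Build a :class:`StudyConfig` from defaults, a YAML file and overrides.

    The YAML layout mirrors the dataclass structure, with the three
    generator models grouped under a ``synthetic`` section::

        seed: 1
        synthetic:
          design: {n_transects: 2}
          traits: {rate_log_sd: 0.0}
        fitting: {min_positive_points: 5}
    """
    cfg = StudyConfig()
    merged: dict = {}
    if path is not None:
        with open(path) as fh:
            merged.update(yaml.safe_load(fh) or {})
    if overrides:
        merged.update(overrides)
    synthetic = merged.pop("synthetic", None)
    if synthetic:
        for sub in ("design", "environment", "traits", "protocol"):
            if sub in synthetic:
                merged[sub] = synthetic[sub]
    return _update_dataclass(cfg, merged)


def config_hash(cfg: StudyConfig) -> str:
    """Short stable hash of a configuration, for run manifests."""
    return hashlib.sha256(repr(cfg).encode()).hexdigest()[:12]
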