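"""Pipeline configuration: YAML loading, validation, defaults, provenance."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .allometry import AGBModel, HeightModel
from .distributions import WeibullDBHModel

__all__ = ["PipelineConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """A configuration file violated the schema."""


_SCHEMA: dict[str, set[str]] = {
    "": {"n_iter", "master_seed", "dbh_model", "height_model", "agb_model",
         "simulation", "grid", "scenario", "paths", "stratified_assignment"},
    "dbh_model": {"scale", "shape", "d_min", "d_max", "family"},
    "height_model": {"a_h", "b_h", "c_h", "sigma_h"},
    "agb_model": {"alpha", "beta", "sigma_ln", "coef_rel_sd"},
    "simulation": {"n_plots", "plot_area_ha", "stem_density", "n_taxa"},
    "grid": {"pixel_size", "origin_x", "origin_y", "crs_label"},
    "paths": {"out_dir"},
}


@dataclass(frozen=True)
class SimulationConfig:
    n_plots: int = 200
    plot_area_ha: float = 0.5
    stem_density: float = 500.0
    n_taxa: int = 50


@dataclass(frozen=True)
class GridConfig:
    pixel_size: float = 1000.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_label: str = "EPSG:3395"


@dataclass(frozen=True)
class PipelineConfig:
    n_iter: int = 1000
    master_seed: int = 0
    dbh_model: WeibullDBHModel = field(default_factory=WeibullDBHModel)
    height_model: HeightModel = field(default_factory=HeightModel)
    agb_model: AGBModel = field(default_factory=AGBModel)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    scenario: str = "best"
    out_dir: str = "."
    stratified_assignment: bool = True

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ConfigError("n_iter must be >= 1")

    def sha256(self) -> str:
        payload = {
            "n_iter": self.n_iter,
            "master_seed": self.master_seed,
            "dbh_model": asdict(self.dbh_model),
            "height_model": asdict(self.height_model),
            "agb_model": asdict(self.agb_model),
            "simulation": asdict(self.simulation),
            "grid": asdict(self.grid),
            "scenario": self.scenario,
            "stratified_assignment": self.stratified_assignment,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _check_keys(section: str, mapping: dict) -> None:
    allowed = _SCHEMA[section]
    for key in mapping:
        if key not in allowed:
            where = f"in section {section!r} " if section else ""
            raise ConfigError(f"unknown configuration key {key!r} {where}".strip())


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config, reject unknown keys, fill documented defaults."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    _check_keys("", raw)
    for section in ("dbh_model", "height_model", "agb_model", "simulation", "grid", "paths"):
        sub = raw.get(section, {})
        if not isinstance(sub, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        _check_keys(section, sub)
    try:
        return PipelineConfig(
            n_iter=int(raw.get("n_iter", 1000)),
            master_seed=int(raw.get("master_seed", 0)),
            dbh_model=WeibullDBHModel(**raw.get("dbh_model", {})),
            height_model=HeightModel(**raw.get("height_model", {})),
            agb_model=AGBModel(**raw.get("agb_model", {})),
            simulation=SimulationConfig(**raw.get("simulation", {})),
            grid=GridConfig(**raw.get("grid", {})),
            scenario=str(raw.get("scenario", "best")),
            out_dir=str(raw.get("paths", {}).get("out_dir", ".")),
            stratified_assignment=bool(raw.get("stratified_assignment", True)),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc
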