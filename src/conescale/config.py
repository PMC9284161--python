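"""Run configuration: one YAML file drives the whole pipeline.

Every block has full defaults, so an empty file is a valid configuration.
Unknown keys are rejected by name; every defaulted value is echoed back into
outputs (``to_flat_dict`` feeds the ``# key=value`` reproducibility headers
of the CLI).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .exceptions import ConfigurationError
from .geometry import LENGTH_DEFAULT_MM, BendingZone, LayerProfile, ScaleModel
from .materials import (
    DryingPath,
    MaterialCurve,
    load_material_curves,
    preset_curve,
)

__all__ = ["RunConfig", "load_config", "dump_config", "build_scale_model",
           "build_drying_path", "build_model"]


def _from_dict(cls, data: dict[str, Any], where: str):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{where}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"{where}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        try:
            if f.type in ("float", float):
                val = float(val)
            elif f.type in ("int", int):
                val = int(val)
            elif f.type in ("bool", bool):
                if not isinstance(val, bool):
                    raise TypeError("expected a boolean")
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"{where}.{f.name}: {exc}") from None
        kwargs[f.name] = val
    return cls(**kwargs)


@dataclass(frozen=True)
class GeometryConfig:
    length_mm: float = LENGTH_DEFAULT_MM
    width_start_mm: float = 1.8
    width_end_mm: float = 3.5
    t_active_start_mm: float = 0.8
    t_active_end_mm: float = 0.65
    t_passive_start_mm: float = 0.6
    t_passive_end_mm: float = 0.43
    n_stations: int = 201
    lever_mm: float = 40.0

    def validate(self) -> None:
        for key in ("length_mm", "width_start_mm", "width_end_mm",
                    "t_active_start_mm", "t_active_end_mm",
                    "t_passive_start_mm", "t_passive_end_mm"):
            if getattr(self, key) <= 0:
                raise ConfigurationError(f"geometry.{key} must be > 0")
        if self.n_stations < 2:
            raise ConfigurationError("geometry.n_stations must be >= 2")
        if self.lever_mm < 0:
            raise ConfigurationError("geometry.lever_mm must be >= 0")


@dataclass(frozen=True)
class MaterialsConfig:
    passive_preset: str = "sclerenchyma_sim"
    active_preset: str = "sclereid_regression"
    csv_path: str = ""  # optional override table (same columns as the preset CSV)
    poisson_ratio: float = 0.3
    plane_strain: bool = False

    def validate(self) -> None:
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ConfigurationError("materials.poisson_ratio must be in [0, 0.5)")
        if self.csv_path and not Path(self.csv_path).exists():
            raise ConfigurationError(
                f"materials.csv_path does not exist: {self.csv_path}"
            )

    def curves(self) -> dict[str, MaterialCurve]:
        curves = {name: preset_curve(name)
                  for name in ("sclerenchyma_sim", "sclerenchyma_afm",
                               "sclereid_regression", "sclereid_afm",
                               "brown_tissue")}
        if self.csv_path:
            curves.update(load_material_curves(self.csv_path))
        return curves

    def curve(self, name: str) -> MaterialCurve:
        curves = self.curves()
        if name not in curves:
            raise ConfigurationError(
                f"materials: unknown curve {name!r}; available {sorted(curves)}"
            )
        return curves[name]


@dataclass(frozen=True)
class DryingConfig:
    eps_max: float = 0.22
    e_passive_wet_mpa: float = 70.0
    e_passive_dry_mpa: float = 1170.0

    def validate(self) -> None:
        if not (0.0 <= self.eps_max <= 1.0):
            raise ConfigurationError("drying.eps_max must be in [0, 1]")
        if self.e_passive_wet_mpa <= 0 or self.e_passive_dry_mpa <= 0:
            raise ConfigurationError("drying moduli must be > 0")
        if self.e_passive_dry_mpa <= self.e_passive_wet_mpa:
            raise ConfigurationError(
                "drying.e_passive_dry_mpa must exceed e_passive_wet_mpa"
            )


@dataclass(frozen=True)
class CalibrationConfig:
    target_gamma_dry_deg: float = 24.4
    target_interval_deg: float = 12.0
    rh_interval_wet: float = 80.0
    rh_interval_dry: float = 30.0
    e_active_dry_mpa: float = 37.0
    bracket_e_lo_mpa: float = 100.0
    bracket_e_hi_mpa: float = 5000.0
    bracket_eps_lo: float = 0.0
    bracket_eps_hi: float = 0.22
    tol_deg: float = 1e-4
    max_iter: int = 200

    def validate(self) -> None:
        if self.bracket_e_lo_mpa >= self.bracket_e_hi_mpa:
            raise ConfigurationError("calibration: modulus bracket must be ordered")
        if self.bracket_eps_lo >= self.bracket_eps_hi:
            raise ConfigurationError("calibration: contraction bracket must be ordered")
        if self.tol_deg <= 0:
            raise ConfigurationError("calibration.tol_deg must be > 0")
        if self.max_iter < 1:
            raise ConfigurationError("calibration.max_iter must be >= 1")


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_scales: int = 10
    noise_sd_deg: float = 4.2
    size_cv: float = 0.15
    n_locations: int = 64
    modulus_cv: float = 0.3

    def validate(self) -> None:
        if self.n_scales < 1:
            raise ConfigurationError("synthetic.n_scales must be >= 1")
        for key in ("noise_sd_deg", "size_cv", "modulus_cv"):
            if getattr(self, key) < 0:
                raise ConfigurationError(f"synthetic.{key} must be >= 0")
        if self.n_locations < 1:
            raise ConfigurationError("synthetic.n_locations must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    materials: MaterialsConfig = field(default_factory=MaterialsConfig)
    drying: DryingConfig = field(default_factory=DryingConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    output_dir: str = "."

    _BLOCKS = {
        "geometry": GeometryConfig,
        "materials": MaterialsConfig,
        "drying": DryingConfig,
        "calibration": CalibrationConfig,
        "synthetic": SyntheticConfig,
    }

    @classmethod
    def from_dict(cls, data: dict[str, Any] | None) -> "RunConfig":
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigurationError("config root must be a mapping")
        unknown = set(data) - set(cls._BLOCKS) - {"output_dir"}
        if unknown:
            raise ConfigurationError(f"unknown top-level key(s) {sorted(unknown)}")
        kwargs: dict[str, Any] = {
            name: _from_dict(block, data.get(name, {}), name)
            for name, block in cls._BLOCKS.items()
        }
        if "output_dir" in data:
            kwargs["output_dir"] = str(data["output_dir"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in self._BLOCKS:
            getattr(self, name).validate()

    def to_dict(self) -> dict[str, Any]:
        out = {name: dataclasses.asdict(getattr(self, name)) for name in self._BLOCKS}
        out["output_dir"] = self.output_dir
        return out

    def to_flat_dict(self) -> dict[str, Any]:
        """Flattened ``block.key -> value`` view for reproducibility headers."""
        flat: dict[str, Any] = {}
        for name in self._BLOCKS:
            for key, val in dataclasses.asdict(getattr(self, name)).items():
                flat[f"{name}.{key}"] = val
        flat["output_dir"] = self.output_dir
        return flat


def load_config(path: str | Path | None) -> RunConfig:
    """Load (or default) a run configuration from a YAML file.

    ``path=None`` and an empty file both yield the all-defaults
    configuration.  Unknown keys, type mismatches and invariant violations
    raise :class:`ConfigurationError` naming the offending key.
    """
    if path is None:
        return RunConfig.from_dict({})
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"config file not found: {p}")
    with open(p) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse {p}: {exc}") from None
    return RunConfig.from_dict(data)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration back to YAML (round-trips with load_config)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# -- builders ---------------------------------------------------------------

def build_scale_model(config: RunConfig) -> ScaleModel:
    g = config.geometry
    zone = BendingZone(
        length_mm=g.length_mm,
        w_start=g.width_start_mm,
        w_end=g.width_end_mm,
        active=LayerProfile("active", g.t_active_start_mm, g.t_active_end_mm),
        passive=LayerProfile("passive", g.t_passive_start_mm, g.t_passive_end_mm),
        n_stations=g.n_stations,
    )
    return ScaleModel(zone=zone, lever_mm=g.lever_mm)


def build_drying_path(config: RunConfig) -> DryingPath:
    d = config.drying
    return DryingPath(eps_max=d.eps_max, e_passive_wet=d.e_passive_wet_mpa,
                      e_passive_dry=d.e_passive_dry_mpa)


def build_model(config: RunConfig):
    """Assemble a :class:`~conescale.model.ScaleActuationModel`."""
    from .model import ScaleActuationModel

    m = config.materials
    return ScaleActuationModel(
        scale=build_scale_model(config),
        drying=build_drying_path(config),
        passive_curve=m.curve(m.passive_preset),
        active_curve=m.curve(m.active_preset),
    )
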