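"""Validated run configuration (YAML or JSON) and conversion to domain objects."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigError
from .geometry import Aperture, BeamlineGeometry
from .source import SourceModel

__all__ = [
    "GeometryConfig",
    "ApertureConfig",
    "SourceConfig",
    "MetricsConfig",
    "RunConfig",
    "load_config",
]

log = logging.getLogger("penumbra")

#: default margin (mm) added on each side of the projected nominal field
GRID_MARGIN = 10.0


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=False)


class GeometryConfig(_Strict):
    source_height: float = Field(gt=0, description="focal spot height above the plane (mm)")
    grid_min: Optional[float] = None
    grid_max: Optional[float] = None
    grid_step: float = Field(default=0.1, gt=0)


class ApertureConfig(_Strict):
    radius: float = Field(gt=0)
    height: float = Field(ge=0)
    offset: float = 0.0


class SourceConfig(_Strict):
    kind: Literal["gaussian", "tabulated"] = "gaussian"
    fwhm: Optional[float] = Field(default=1.5, gt=0)
    table: Optional[list[tuple[float, float]]] = None
    table_file: Optional[str] = None
    center_offset: float = 0.0
    slice_step: float = Field(default=0.001, gt=0)
    truncation: float = Field(default=4.0, gt=0)
    normalization: Literal["peak", "total"] = "peak"

    @model_validator(mode="after")
    def _check_kind(self) -> "SourceConfig":
        if self.kind == "tabulated" and self.table is None and self.table_file is None:
            raise ValueError("tabulated source requires 'table' or 'table_file'")
        return self


class MetricsConfig(_Strict):
    penumbra_low: float = Field(default=0.2, gt=0, lt=1)
    penumbra_high: float = Field(default=0.8, gt=0, lt=1)
    detector_diameter: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "MetricsConfig":
        if self.penumbra_low >= self.penumbra_high:
            raise ValueError("penumbra_low must be < penumbra_high")
        return self


class RunConfig(_Strict):
    """One beamline: geometry, focal spot, aperture stack, metric options."""

    geometry: GeometryConfig
    source: SourceConfig = SourceConfig()
    apertures: list[ApertureConfig] = Field(min_length=1)
    metrics: MetricsConfig = MetricsConfig()
    seed: int = 20240713

    @model_validator(mode="after")
    def _apertures_below_source(self) -> "RunConfig":
        for i, ap in enumerate(self.apertures):
            if ap.height >= self.geometry.source_height:
                raise ValueError(
                    f"apertures[{i}].height ({ap.height} mm) must be below "
                    f"source_height ({self.geometry.source_height} mm)"
                )
        return self

    # -- conversion to domain objects -------------------------------------
    def build_apertures(self) -> list[Aperture]:
        return [Aperture(a.radius, a.height, a.offset) for a in self.apertures]

    def build_source(self) -> SourceModel:
        s = self.source
        if s.kind == "gaussian":
            return SourceModel.gaussian(
                fwhm=s.fwhm,
                center_offset=s.center_offset,
                slice_step=s.slice_step,
                truncation=s.truncation,
                normalization=s.normalization,
            )
        if s.table is not None:
            table = np.asarray(s.table, dtype=float)
            return SourceModel.tabulated(
                table,
                center_offset=s.center_offset,
                slice_step=s.slice_step,
                normalization=s.normalization,
            )
        return SourceModel.from_table_file(
            s.table_file,
            center_offset=s.center_offset,
            slice_step=s.slice_step,
            normalization=s.normalization,
        )

    def build_geometry(self) -> BeamlineGeometry:
        g = self.geometry
        if g.grid_min is None or g.grid_max is None:
            half = 0.5 * self.nominal_field() + GRID_MARGIN
            half = round(half / g.grid_step) * g.grid_step
            return BeamlineGeometry(g.source_height, -half, half, g.grid_step)
        return BeamlineGeometry(g.source_height, g.grid_min, g.grid_max, g.grid_step)

    def nominal_field(self) -> float:
        """Point-source field diameter: governed by the tightest aperture."""
        h = self.geometry.source_height
        return min(2.0 * a.radius * h / (h - a.height) for a in self.apertures)

    def build(self) -> tuple[SourceModel, list[Aperture], BeamlineGeometry]:
        return self.build_source(), self.build_apertures(), self.build_geometry()


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    The effective configuration (with defaults applied) is echoed at INFO
    level so any published number is regenerable from logs.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise ConfigError(f"invalid config {path}: {details}") from exc
    log.info("effective config (seed=%d): %s", cfg.seed, cfg.model_dump())
    return cfg
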