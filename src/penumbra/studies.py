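"""Design studies: parameter sweeps over source and aperture parameters.

These wrap the projection integrator in reproducible tables supporting
collimator optimization: how focal-spot size, aperture radius/height/offset
and misalignment move the FWHM, the 20-80% penumbras and the peak intensity.

Peak ("dose rate") comparisons across spot sizes use sources normalized to
equal total intensity; with unit-peak spots a smaller spot simply carries less
total intensity and every peak comparison would be dominated by that
bookkeeping rather than by collimator clipping.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import BeamModelError
from .metrics import compute_metrics
from .projection import integrate_profile

__all__ = ["StudyResult", "sweep_source_fwhm", "sweep_aperture", "misalignment_study"]

#: profile value at the grid boundary above this fraction of peak flags clipping
_CLIP_FRACTION = 0.01


@dataclass(frozen=True)
class StudyResult:
    """One row per parameter combination, plus a provenance snapshot."""

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _profile_row(cfg: RunConfig) -> dict:
    src, aps, geom = cfg.build()
    profile = integrate_profile(src, aps, geom)
    boundary = max(profile.values[0], profile.values[-1])
    clipped = bool(profile.peak > 0 and boundary > _CLIP_FRACTION * profile.peak)
    try:
        m = compute_metrics(profile, cfg.metrics.detector_diameter)
    except BeamModelError as exc:
        # e.g. the field escaped the grid: keep the clip flag with the error
        row = _error_row(exc)
        row["grid_clipped"] = clipped
        return row
    return {
        "fwhm": m.fwhm,
        "penumbra_left": m.penumbra_left,
        "penumbra_right": m.penumbra_right,
        "peak": m.peak,
        "field_center": m.field_center,
        "grid_clipped": clipped,
        "error": "",
    }


def _error_row(exc: Exception) -> dict:
    return {
        "fwhm": np.nan,
        "penumbra_left": np.nan,
        "penumbra_right": np.nan,
        "peak": np.nan,
        "field_center": np.nan,
        "grid_clipped": False,
        "error": f"{type(exc).__name__}: {exc}",
    }


def _provenance(cfg: RunConfig, **extra) -> dict:
    prov = {
        "config": cfg.model_dump(),
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    prov.update(extra)
    return prov


def sweep_source_fwhm(base: RunConfig, fwhm_values: Sequence[float]) -> StudyResult:
    """Metrics per focal-spot FWHM, all other parameters fixed.

    Sources are switched to the equal-total-intensity convention so the
    ``peak_ratio_vs_first`` column is a meaningful relative dose rate.
    """
    if len(fwhm_values) == 0:
        raise ValueError("at least one fwhm value is required")
    if base.source.kind != "gaussian":
        raise ValueError("sweep_source_fwhm requires a gaussian source")
    rows = []
    for f in fwhm_values:
        cfg = base.model_copy(deep=True)
        cfg.source.fwhm = f
        cfg.source.normalization = "total"
        row = {"source_fwhm": f}
        row.update(_profile_row(cfg))
        rows.append(row)
    table = pd.DataFrame(rows)
    table["peak_ratio_vs_first"] = table["peak"] / table["peak"].iloc[0]
    return StudyResult(table, _provenance(base, study="sweep_source_fwhm", values=list(fwhm_values)))


def sweep_aperture(
    base: RunConfig,
    aperture_index: int,
    parameter: Literal["radius", "height", "offset"],
    values: Sequence[float],
) -> StudyResult:
    """Metrics per value of one aperture parameter.

    Rows whose geometry is invalid (e.g. height at or above the source) are
    recorded with an ``error`` message and the sweep continues.  The
    provenance carries simple monotonicity flags for the valid rows.
    """
    if len(values) == 0:
        raise ValueError("at least one value is required")
    if parameter not in ("radius", "height", "offset"):
        raise ValueError(f"unknown aperture parameter {parameter!r}")
    if not 0 <= aperture_index < len(base.apertures):
        raise ValueError(f"aperture_index {aperture_index} out of range")
    rows = []
    for v in values:
        cfg = base.model_copy(deep=True)
        setattr(cfg.apertures[aperture_index], parameter, v)
        row = {parameter: v}
        try:
            cfg = RunConfig.model_validate(cfg.model_dump())  # re-run invariants
            row.update(_profile_row(cfg))
        except (BeamModelError, ValueError) as exc:
            row.update(_error_row(exc))
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table[table["error"] == ""]
    flags = {}
    if len(ok) >= 2:
        order = ok.sort_values(parameter)
        for col in ("fwhm", "penumbra_left", "penumbra_right", "peak"):
            d = np.diff(order[col].to_numpy())
            flags[f"{col}_monotonic"] = bool(np.all(d >= 0) or np.all(d <= 0))
    return StudyResult(
        table,
        _provenance(
            base,
            study="sweep_aperture",
            aperture_index=aperture_index,
            parameter=parameter,
            values=list(values),
            monotonicity=flags,
        ),
    )


def misalignment_study(
    base: RunConfig,
    source_offsets: Sequence[float],
    aperture_offsets: Sequence[float],
) -> StudyResult:
    """Profile asymmetry per (source offset, rigid aperture-stack offset) pair.

    Reports the left/right penumbra difference and the 50%-edge field-centre
    shift for every combination.
    """
    if len(source_offsets) == 0 or len(aperture_offsets) == 0:
        raise ValueError("offset lists must be non-empty")
    rows = []
    for ds in source_offsets:
        for da in aperture_offsets:
            cfg = base.model_copy(deep=True)
            cfg.source.center_offset = ds
            for ap in cfg.apertures:
                ap.offset = ap.offset + da
            row = {"source_offset": ds, "aperture_offset": da}
            try:
                row.update(_profile_row(cfg))
                row["asymmetry"] = row["penumbra_left"] - row["penumbra_right"]
            except (BeamModelError, ValueError) as exc:
                row.update(_error_row(exc))
                row["asymmetry"] = np.nan
            rows.append(row)
    table = pd.DataFrame(rows)
    return StudyResult(
        table,
        _provenance(
            base,
            study="misalignment",
            source_offsets=list(source_offsets),
            aperture_offsets=list(aperture_offsets),
        ),
    )
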