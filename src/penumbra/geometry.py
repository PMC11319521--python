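"""Beamline geometry: apertures, point-source edge projection, interval intersection.

The treatment (isocenter) plane is at height 0 and the focal spot at height
``source_height`` above it; all lengths are millimetres.  A point source at
lateral position ``r0`` shining through a circular aperture of radius ``Ra``
at height ``Ha`` illuminates a signed interval on the treatment plane whose
edges follow from similar triangles with magnification
``M = Hbeam / (Hbeam - Ha)``:

    right = r0 + M * (c + Ra - r0)
    left  = r0 + M * (c - Ra - r0)

where ``c`` is the lateral offset of the aperture centre.  With several
collimation levels the illuminated interval is the intersection of the
per-aperture intervals (innermost edge on each side wins).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import GeometryError

__all__ = [
    "BeamlineGeometry",
    "Aperture",
    "FieldInterval",
    "magnification",
    "project_edges",
    "project_edges_arrays",
    "intersect",
    "cone_tangent_height",
    "tangent_diameter",
]


@dataclass(frozen=True)
class BeamlineGeometry:
    """Source height above the treatment plane and the evaluation grid.

    Parameters
    ----------
    source_height : float
        Distance (mm) of the focal spot from the treatment plane. Must be > 0.
    grid_min, grid_max : float
        Extent (mm) of the treatment-plane evaluation grid.
    grid_step : float, default 0.1
        Grid resolution (mm).
    """

    source_height: float
    grid_min: float
    grid_max: float
    grid_step: float = 0.1

    def __post_init__(self) -> None:
        if self.source_height <= 0:
            raise GeometryError("source_height must be > 0")
        if self.grid_step <= 0:
            raise GeometryError("grid_step must be > 0")
        if self.grid_min >= self.grid_max:
            raise GeometryError("grid_min must be < grid_max")
        if (self.grid_max - self.grid_min) / self.grid_step > 2e6:
            raise GeometryError(
                "grid would exceed 2e6 points; widen grid_step or narrow the range"
            )

    def grid(self) -> np.ndarray:
        """Treatment-plane positions (mm).

        A symmetric range (``grid_min == -grid_max``) is built as
        ``step * arange(-m, m + 1)`` so mirrored positions are bitwise
        negatives of each other; profile symmetry then holds to rounding.
        """
        g = self.grid_step
        if abs(self.grid_min + self.grid_max) < 1e-12 * max(1.0, abs(self.grid_max)):
            m = int(round(self.grid_max / g))
            return g * np.arange(-m, m + 1)
        n = int(np.floor((self.grid_max - self.grid_min) / g + 1e-9))
        return self.grid_min + g * np.arange(n + 1)


@dataclass(frozen=True)
class Aperture:
    """One circular collimation level.

    ``height`` is measured from the treatment plane upward; ``offset`` is the
    lateral displacement of the aperture centre (misalignment studies).
    """

    radius: float
    height: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise GeometryError("aperture radius must be > 0")
        if self.height < 0:
            raise GeometryError("aperture height must be >= 0")

    def with_offset(self, offset: float) -> "Aperture":
        return replace(self, offset=offset)


@dataclass(frozen=True)
class FieldInterval:
    """Signed illuminated interval on the treatment plane for one slice.

    ``left`` stores the signed coordinate of the left edge; the
    positive-magnitude "left edge" used in reporting is ``-left``.
    """

    left: float
    right: float
    empty: bool = False

    def __post_init__(self) -> None:
        if not self.empty and self.left > self.right:
            raise ValueError("non-empty interval requires left <= right")

    @property
    def width(self) -> float:
        return 0.0 if self.empty else self.right - self.left

    @property
    def edge_left_magnitude(self) -> float:
        """The left edge as a positive distance from the axis (reporting form)."""
        return -self.left

    def contains(self, r: float) -> bool:
        """Closed-interval membership (edges count as illuminated)."""
        return (not self.empty) and self.left <= r <= self.right

    @staticmethod
    def make_empty() -> "FieldInterval":
        return FieldInterval(np.inf, -np.inf, empty=True)


def magnification(geom: BeamlineGeometry, ap: Aperture) -> float:
    """Projection factor ``Hbeam / (Hbeam - Ha)`` for one aperture (>= 1)."""
    if ap.height >= geom.source_height:
        raise GeometryError(
            f"aperture height {ap.height} mm must lie below the source "
            f"({geom.source_height} mm)"
        )
    return geom.source_height / (geom.source_height - ap.height)


def project_edges(r0: float, ap: Aperture, geom: BeamlineGeometry) -> FieldInterval:
    """Project a point source at ``r0`` through one aperture onto the plane."""
    m = magnification(geom, ap)
    left = r0 + m * ((ap.offset - ap.radius) - r0)
    right = r0 + m * ((ap.offset + ap.radius) - r0)
    if left > right:  # cannot happen for radius > 0, kept for safety
        return FieldInterval.make_empty()
    return FieldInterval(left, right)


def project_edges_arrays(
    r0: np.ndarray, ap: Aperture, geom: BeamlineGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`project_edges`: returns ``(left, right)`` arrays."""
    m = magnification(geom, ap)
    left = r0 + m * ((ap.offset - ap.radius) - r0)
    right = r0 + m * ((ap.offset + ap.radius) - r0)
    return left, right


def intersect(intervals: Sequence[FieldInterval] | Iterable[FieldInterval]) -> FieldInterval:
    """Intersection across collimation levels: innermost edge per side wins."""
    intervals = list(intervals)
    if not intervals:
        raise ValueError("intersect() requires at least one interval")
    if any(iv.empty for iv in intervals):
        return FieldInterval.make_empty()
    left = max(iv.left for iv in intervals)
    right = min(iv.right for iv in intervals)
    if left > right:
        return FieldInterval.make_empty()
    return FieldInterval(left, right)


def cone_tangent_height(
    diameter: float, nominal_field: float, geom: BeamlineGeometry
) -> float:
    """Height at which an aperture of ``diameter`` is tangent to the cone from a
    point source through the edges of a ``nominal_field``-wide field.

    Inverse of :func:`tangent_diameter`; used to reconstruct aperture heights
    when only diameters and the design field size are known.
    """
    if diameter <= 0:
        raise GeometryError("diameter must be > 0")
    if diameter > nominal_field:
        raise GeometryError(
            f"diameter {diameter} mm exceeds the nominal field {nominal_field} mm: "
            "no tangent solution"
        )
    return geom.source_height * (1.0 - diameter / nominal_field)


def tangent_diameter(height: float, nominal_field: float, geom: BeamlineGeometry) -> float:
    """Aperture diameter tangent to the nominal-field cone at ``height``."""
    if not 0 <= height < geom.source_height:
        raise GeometryError("height must lie in [0, source_height)")
    return nominal_field * (geom.source_height - height) / geom.source_height
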