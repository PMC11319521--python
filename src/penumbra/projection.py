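"""Projection integration: sum slice contributions into the treatment-plane profile.

For each slice the illuminated interval is the intersection of the
per-aperture projected intervals; the slice contributes its intensity inside
that interval and zero outside.  The profile is

    Profile(r) = sum_k I_k * 1[r in interval_k] * slice_step

evaluated on the geometry's grid with closed-interval membership at the exact
edges (the choice is immaterial as slice_step -> 0).  Air attenuation and
transmission through the collimator material are neglected.

Extensions: orthogonal-plane rectangular fields (two independent 1D runs) and
a 2D pixelated mode where each source pixel is tested against every circular
aperture along the ray to each target pixel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .geometry import (
    Aperture,
    BeamlineGeometry,
    FieldInterval,
    intersect,
    project_edges,
    project_edges_arrays,
)
from .source import SourceModel, SourceSlice, slice_arrays

__all__ = [
    "Profile",
    "IntensityMap",
    "slice_contribution",
    "integrate_profile",
    "rectangular_profile",
    "integrate_profile_2d",
]


@dataclass(frozen=True)
class Profile:
    """Integrated intensity versus treatment-plane position.

    ``positions`` is a strictly increasing, uniformly spaced grid (mm);
    ``values`` are non-negative intensities (arbitrary units, or relative to
    peak when ``normalized``).
    """

    positions: np.ndarray
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if pos.ndim != 1 or pos.shape != val.shape:
            raise ValueError("positions and values must be 1D arrays of equal length")
        if pos.size < 2:
            raise ValueError("a profile needs at least two grid points")
        d = np.diff(pos)
        if np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-6, atol=1e-12):
            raise ValueError("positions must be strictly increasing with constant step")
        if np.any(val < 0):
            raise ValueError("profile values must be >= 0")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)

    @property
    def step(self) -> float:
        return float(self.positions[1] - self.positions[0])

    @property
    def peak(self) -> float:
        return float(self.values.max())

    def scaled(self, factor: float) -> "Profile":
        if factor <= 0:
            raise ValueError("scale factor must be > 0")
        return replace(self, values=self.values * factor, normalized=False)


@dataclass(frozen=True)
class IntensityMap:
    """Dense 2D treatment-plane intensity map with its grid axes (mm)."""

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.x), len(self.y)):
            raise ValueError("values must have shape (len(x), len(y))")

    def central_row(self) -> Profile:
        """Profile along x through y closest to 0."""
        j = int(np.argmin(np.abs(self.y)))
        return Profile(self.x, self.values[:, j])


def slice_contribution(
    sl: SourceSlice, apertures: Sequence[Aperture], geom: BeamlineGeometry
) -> tuple[FieldInterval, float]:
    """Illuminated interval (intersection over apertures) and slice intensity."""
    if not apertures:
        raise ValueError("at least one aperture is required")
    interval = intersect([project_edges(sl.r0, ap, geom) for ap in apertures])
    return interval, sl.intensity


def _combined_bounds(
    r0: np.ndarray, apertures: Sequence[Aperture], geom: BeamlineGeometry
) -> tuple[np.ndarray, np.ndarray]:
    left = np.full_like(r0, -np.inf)
    right = np.full_like(r0, np.inf)
    for ap in apertures:
        lo, hi = project_edges_arrays(r0, ap, geom)
        left = np.maximum(left, lo)
        right = np.minimum(right, hi)
    return left, right


def integrate_profile(
    src: SourceModel, apertures: Sequence[Aperture], geom: BeamlineGeometry
) -> Profile:
    """Sum slice contributions over the geometry's grid.

    The result is deterministic for fixed inputs.  If the grid misses the
    whole illuminated field a warning is emitted and an all-zero profile
    returned.
    """
    if not apertures:
        raise ValueError("at least one aperture is required")
    grid = geom.grid()
    r0, inten = slice_arrays(src)
    left, right = _combined_bounds(r0, apertures, geom)
    member = (grid[None, :] >= left[:, None]) & (grid[None, :] <= right[:, None])
    values = (inten * src.slice_step) @ member
    if values.max() == 0.0:
        warnings.warn(
            "evaluation grid excludes the entire illuminated field; profile is all zero",
            stacklevel=2,
        )
    return Profile(grid, values)


def rectangular_profile(
    src: SourceModel,
    x_apertures: Sequence[Aperture],
    y_apertures: Sequence[Aperture],
    geom: BeamlineGeometry,
) -> tuple[Profile, Profile]:
    """Rectangular fields: the two orthogonal planes computed independently."""
    return (
        integrate_profile(src, x_apertures, geom),
        integrate_profile(src, y_apertures, geom),
    )


def integrate_profile_2d(
    src: SourceModel,
    apertures: Sequence[Aperture],
    geom: BeamlineGeometry,
    source_pixel: float = 0.1,
    aperture_offsets_y: Sequence[float] | None = None,
) -> IntensityMap:
    """2D pixelated mode: isotropic Gaussian source, disc apertures.

    Each source pixel contributes to a target pixel iff the straight ray
    between them passes inside every aperture disc (point-in-disc test at each
    aperture height by linear interpolation along the ray).  Aperture offsets
    are applied along x; ``aperture_offsets_y`` optionally adds per-aperture
    y displacements.
    """
    if src.kind != "gaussian":
        raise ValueError("the 2D mode supports the isotropic Gaussian source only")
    if not apertures:
        raise ValueError("at least one aperture is required")
    if source_pixel > 0.5 or geom.grid_step > 0.5:
        warnings.warn(
            "pixel grids coarser than 0.5 mm poorly resolve the penumbra",
            stacklevel=2,
        )
    offs_y = list(aperture_offsets_y) if aperture_offsets_y is not None else [0.0] * len(apertures)
    if len(offs_y) != len(apertures):
        raise ValueError("aperture_offsets_y must match the number of apertures")

    sigma = src.sigma
    m = int(np.floor(src.truncation * sigma / source_pixel))
    if m < 1:
        raise ValueError("source_pixel too coarse for the focal spot")
    s = source_pixel * np.arange(-m, m + 1)
    sx = s[:, None] + src.center_offset
    sy = s[None, :]
    w = np.exp(-(s[:, None] ** 2 + s[None, :] ** 2) / (2.0 * sigma**2))

    grid = geom.grid()
    h = geom.source_height
    ts = [(h - ap.height) / h for ap in apertures]  # ray fraction source->target

    # Per aperture, squared y-distance from the disc centre for every target y,
    # precomputed once: shape (n_grid, 1, n_source_y).
    dy2 = [
        (sy[None, :, :] * (1.0 - t) + grid[:, None, None] * t - cy) ** 2
        for t, cy in zip(ts, offs_y)
    ]
    out = np.empty((grid.size, grid.size))
    for i, x in enumerate(grid):
        ok = np.ones((grid.size,) + w.shape, dtype=bool)
        for ap, t, d2 in zip(apertures, ts, dy2):
            px = sx * (1.0 - t) + x * t  # ray x at aperture height, (n_source_x, 1)
            ok &= (px - ap.offset) ** 2 + d2 <= ap.radius**2
        out[i, :] = np.einsum("st,jst->j", w, ok)
    out *= source_pixel**2
    meta = {
        "grid_step": geom.grid_step,
        "source_pixel": source_pixel,
        "source_fwhm": src.fwhm,
        "source_height": h,
    }
    return IntensityMap(grid, grid.copy(), out, meta)
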