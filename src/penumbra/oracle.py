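"""Independent validation engines for the projection integrator.

Two cross-checks that never touch the edge-projection algebra of the main
engine:

* a closed-form profile for one centred aperture and a Gaussian spot — the
  slice-membership condition is linear in the slice position, so the Gaussian
  integral collapses to a difference of normal CDFs:

      value(r) = Phi((M*Ra - r) / ((M-1)*sigma)) - Phi((-M*Ra - r) / ((M-1)*sigma))

* a Monte-Carlo ray oracle — sample source positions from the spot
  distribution and, for every grid point, count the fraction of straight rays
  that pass inside every aperture disc.  With a defined target point the ray
  is unique, mirroring the scatter-free geometric transport of the main
  engine; agreement is judged against binomial standard errors.

Both return transmitted fractions of the (untruncated) spot distribution, so
the integrator is compared after dividing by the discretized spot mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import ndtr

from .errors import GeometryError
from .geometry import Aperture, BeamlineGeometry, magnification
from .source import SourceModel

__all__ = ["OracleResult", "closed_form_single_aperture", "mc_ray_oracle"]

MIN_MC_SAMPLES = 10_000
DEFAULT_SEED = 20240713


@dataclass(frozen=True)
class OracleResult:
    """Oracle profile: positions, values and (for MC) binomial uncertainties."""

    positions: np.ndarray
    values: np.ndarray
    standard_errors: np.ndarray | None = None
    sample_count: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.standard_errors is not None and np.any(self.standard_errors < 0):
            raise ValueError("standard errors must be >= 0")
        if self.sample_count is not None and self.sample_count <= 0:
            raise ValueError("sample_count must be > 0")


def closed_form_single_aperture(
    src: SourceModel,
    ap: Aperture,
    geom: BeamlineGeometry,
    grid: np.ndarray | None = None,
) -> OracleResult:
    """Analytic transmitted-fraction profile for one centred aperture.

    Requires a centred Gaussian source and a centred aperture.  At
    ``height = 0`` the magnification is 1 and the expression degenerates; the
    exact result there is a top-hat of half-width ``radius``.
    """
    if src.kind != "gaussian" or src.center_offset != 0.0:
        raise ValueError("closed form requires a centred gaussian source")
    if ap.offset != 0.0:
        raise ValueError("closed form requires a centred aperture")
    r = geom.grid() if grid is None else np.asarray(grid, dtype=float)
    m = magnification(geom, ap)
    if m == 1.0:
        values = ((r >= -ap.radius) & (r <= ap.radius)).astype(float)
        return OracleResult(r, values)
    sigma_proj = (m - 1.0) * src.sigma
    values = ndtr((m * ap.radius - r) / sigma_proj) - ndtr((-m * ap.radius - r) / sigma_proj)
    return OracleResult(r, values)


def _sample_source_positions(src: SourceModel, n: int, rng: np.random.Generator) -> np.ndarray:
    if src.kind == "gaussian":
        return rng.normal(src.center_offset, src.sigma, n)
    # tabulated: inverse-CDF sampling of the linearly interpolated density
    tab = src.table
    pos = np.linspace(tab[0, 0], tab[-1, 0], 4097)
    pdf = np.maximum(np.interp(pos, tab[:, 0], tab[:, 1]), 0.0)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(pos))])
    if cdf[-1] <= 0:
        raise ValueError("tabulated source has zero total intensity")
    cdf /= cdf[-1]
    return np.interp(rng.uniform(0.0, 1.0, n), cdf, pos)


def mc_ray_oracle(
    src: SourceModel,
    apertures: Sequence[Aperture],
    geom: BeamlineGeometry,
    grid: np.ndarray | None = None,
    samples: int = 1_000_000,
    seed: int = DEFAULT_SEED,
) -> OracleResult:
    """Monte-Carlo ray transmission: pass fraction per grid point.

    A sampled source position ``r0`` passes for target ``r`` iff
    ``|x(Ha) - offset| <= Ra`` at every aperture, where
    ``x(Ha) = r0 + (r - r0) * (Hbeam - Ha) / Hbeam``.  A fixed seed makes the
    result bitwise reproducible.
    """
    if samples < MIN_MC_SAMPLES:
        raise ValueError(f"samples must be >= {MIN_MC_SAMPLES}")
    if not apertures:
        raise ValueError("at least one aperture is required")
    for ap in apertures:
        if ap.height >= geom.source_height:
            raise GeometryError("aperture height must lie below the source")
    r = geom.grid() if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    r0 = _sample_source_positions(src, samples, rng)

    h = geom.source_height
    ts = np.array([(h - ap.height) / h for ap in apertures])
    base = [r0 * (1.0 - t) for t in ts]  # source-side term, per aperture
    counts = np.empty(r.size, dtype=np.int64)
    for i, ri in enumerate(r):
        ok = np.ones(samples, dtype=bool)
        for b, t, ap in zip(base, ts, apertures):
            ok &= np.abs(b + ri * t - ap.offset) <= ap.radius
        counts[i] = np.count_nonzero(ok)
    p = counts / samples
    se = np.sqrt(p * (1.0 - p) / samples)
    return OracleResult(r, p, standard_errors=se, sample_count=samples, seed=seed)
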