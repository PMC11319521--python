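"""Profile figures of merit: FWHM, 20-80% penumbra, peak, detector emulation.

All level thresholds are taken relative to the profile's actual peak (small-
field practice: the central axis of a heavily clipped field may never reach
the open-field plateau).  Crossings are located by scanning from the grid
boundary inward and linearly interpolating between the bracketing points, so
the outermost crossing wins when imported data are noisy.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from typing import Literal

import numpy as np

from .errors import UndefinedMetricError
from .projection import Profile

__all__ = [
    "ProfileMetrics",
    "ProfileComparison",
    "normalize",
    "fwhm",
    "edges50",
    "penumbra",
    "peak_ratio",
    "detector_convolve",
    "compare_profiles",
    "compute_metrics",
    "percent_difference",
]

Side = Literal["left", "right"]


@dataclass(frozen=True)
class ProfileMetrics:
    """FWHM, per-side 20-80% penumbra, peak and the 50% edge positions (mm)."""

    fwhm: float
    penumbra_left: float
    penumbra_right: float
    peak: float
    edge50_left: float
    edge50_right: float

    @property
    def field_center(self) -> float:
        return 0.5 * (self.edge50_left + self.edge50_right)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def normalize(p: Profile) -> Profile:
    """Scale so the peak equals 1 (idempotent)."""
    peak = p.peak
    if peak <= 0:
        raise UndefinedMetricError("cannot normalize an all-zero profile")
    return replace(p, values=p.values / peak, normalized=True)


def _crossing(p: Profile, level_value: float, side: Side) -> float:
    """Outermost crossing of ``level_value``, scanning from ``side`` inward."""
    v = p.values
    above = v >= level_value
    if not above.any():
        raise UndefinedMetricError(f"profile never reaches level {level_value:.6g}")
    if side == "left":
        i = int(np.argmax(above))
        if i == 0:
            raise UndefinedMetricError(
                "left boundary already above the level: crossing not bracketed by the grid"
            )
        lo, hi = i - 1, i
    else:
        i = len(v) - 1 - int(np.argmax(above[::-1]))
        if i == len(v) - 1:
            raise UndefinedMetricError(
                "right boundary already above the level: crossing not bracketed by the grid"
            )
        lo, hi = i + 1, i  # scan inward: from below-level point toward the field
    x0, x1 = p.positions[lo], p.positions[hi]
    y0, y1 = v[lo], v[hi]
    if y1 == y0:
        return float(x1)
    return float(x0 + (level_value - y0) * (x1 - x0) / (y1 - y0))


def edges50(p: Profile) -> tuple[float, float]:
    """Outermost 50%-of-peak crossings (left, right)."""
    peak = p.peak
    if peak <= 0:
        raise UndefinedMetricError("profile has no positive peak")
    t = 0.5 * peak
    return _crossing(p, t, "left"), _crossing(p, t, "right")


def fwhm(p: Profile) -> float:
    """Full width at half maximum (mm)."""
    left, right = edges50(p)
    return right - left


def penumbra(p: Profile, side: Side, low: float = 0.2, high: float = 0.8) -> float:
    """Distance between the ``low`` and ``high`` fraction-of-peak crossings."""
    peak = p.peak
    if peak <= 0:
        raise UndefinedMetricError("profile has no positive peak")
    x_low = _crossing(p, low * peak, side)
    x_high = _crossing(p, high * peak, side)
    return abs(x_high - x_low)


def peak_ratio(a: Profile, b: Profile) -> float:
    """max(a) / max(b) for unnormalized profiles (dose-rate surrogate)."""
    if a.normalized or b.normalized:
        raise UndefinedMetricError("peak_ratio requires unnormalized profiles")
    if b.peak <= 0:
        raise UndefinedMetricError("denominator profile has zero peak")
    return a.peak / b.peak


def detector_convolve(p: Profile, detector_diameter: float) -> Profile:
    """Moving average with a top-hat window of the detector diameter.

    Emulates volume averaging by a finite detector: a 1D top-hat kernel with
    fractional end bins (window integral renormalized to one), edges padded
    with the boundary value so a constant profile is unchanged.
    """
    if detector_diameter <= 0:
        raise ValueError("detector_diameter must be > 0")
    g = p.step
    span = p.positions[-1] - p.positions[0]
    if detector_diameter > span:
        raise ValueError("detector window is wider than the profile span")
    half = 0.5 * detector_diameter
    k = int(np.ceil(half / g - 0.5))
    centers = g * np.arange(-k, k + 1)
    overlap = np.minimum(centers + 0.5 * g, half) - np.maximum(centers - 0.5 * g, -half)
    kernel = np.clip(overlap, 0.0, None)
    kernel /= kernel.sum()
    padded = np.pad(p.values, (k, k), mode="edge")
    smoothed = np.convolve(padded, kernel[::-1], mode="valid")
    return replace(p, values=np.maximum(smoothed, 0.0))


def compute_metrics(p: Profile, detector_diameter: float | None = None) -> ProfileMetrics:
    """All figures of merit for one profile (optionally detector-convolved)."""
    if detector_diameter is not None:
        p = detector_convolve(p, detector_diameter)
    left50, right50 = edges50(p)
    return ProfileMetrics(
        fwhm=right50 - left50,
        penumbra_left=penumbra(p, "left"),
        penumbra_right=penumbra(p, "right"),
        peak=p.peak,
        edge50_left=left50,
        edge50_right=right50,
    )


def percent_difference(reference: float, value: float) -> float:
    """|value - reference| / reference * 100 (reference = measured by convention)."""
    if reference == 0:
        raise ZeroDivisionError("reference value is zero")
    return abs(value - reference) / abs(reference) * 100.0


@dataclass(frozen=True)
class ProfileComparison:
    """Pairwise comparison of two normalized profiles on a common grid."""

    metrics_a: ProfileMetrics
    metrics_b: ProfileMetrics
    fwhm_percent_diff: float
    max_abs_diff: float
    mean_abs_diff: float

    def to_dict(self) -> dict:
        return {
            "a": self.metrics_a.to_dict(),
            "b": self.metrics_b.to_dict(),
            "fwhm_percent_diff": self.fwhm_percent_diff,
            "max_abs_diff": self.max_abs_diff,
            "mean_abs_diff": self.mean_abs_diff,
        }


def compare_profiles(a: Profile, b: Profile) -> ProfileComparison:
    """Compare two profiles after peak normalization.

    ``b`` is linearly re-interpolated onto ``a``'s grid over the overlapping
    position range; the FWHM percent difference uses ``a`` (the reference,
    e.g. the measured profile) as the denominator.
    """
    lo = max(a.positions[0], b.positions[0])
    hi = min(a.positions[-1], b.positions[-1])
    if lo >= hi:
        raise ValueError("profiles have no overlapping position range")
    na, nb = normalize(a), normalize(b)
    ma, mb = compute_metrics(na), compute_metrics(nb)
    sel = (na.positions >= lo) & (na.positions <= hi)
    bi = np.interp(na.positions[sel], nb.positions, nb.values)
    diff = np.abs(na.values[sel] - bi)
    return ProfileComparison(
        metrics_a=ma,
        metrics_b=mb,
        fwhm_percent_diff=percent_difference(ma.fwhm, mb.fwhm),
        max_abs_diff=float(diff.max()),
        mean_abs_diff=float(diff.mean()),
    )
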