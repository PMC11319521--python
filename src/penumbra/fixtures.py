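"""Example beamline configurations for the two reference conical collimators.

Both fixtures share a 457 mm source-to-plane distance and a 1.5 mm FWHM
Gaussian focal spot.  Only the aperture diameters (2.3 / 1.8 mm for the 4 mm
collimator), the design field sizes (4 and 25 mm) and the source distance are
known quantities; the aperture *heights* and the 25 mm entrance radius are
reconstructed and documented in each fixture's notes.  Every reconstructed
number is overridable through the configuration.

Reconstruction rules
--------------------
* Exit aperture: tangent to the point-source cone through the nominal field
  edge (this fixes its height given its diameter, or its radius given a
  height).
* Entrance aperture: placed 50 mm below the source (height 407 mm), where it
  trims far-off-focus rays.  For the 4 mm collimator its radius is half the
  stated 2.3 mm diameter; for the 25 mm collimator both radii are scaled from
  the 4 mm fixture by the 25/4 nominal-field ratio (geometric similarity), so
  the exit aperture governs the field edge and the 20-80% penumbra, as the
  reference profile data imply.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import ApertureConfig, GeometryConfig, RunConfig, SourceConfig
from .errors import ConfigError
from .geometry import BeamlineGeometry, cone_tangent_height

__all__ = ["Fixture", "make_fixture", "FIXTURE_NAMES"]

SOURCE_HEIGHT = 457.0  # mm, source to treatment plane
ENTRANCE_HEIGHT = 407.0  # mm, reconstructed: 50 mm below the source

FIXTURE_NAMES = ("collimator4", "collimator25")


@dataclass(frozen=True)
class Fixture:
    """A named example system: validated config plus provenance notes."""

    name: str
    config: RunConfig
    notes: str


def _exit_height(exit_diameter: float, nominal_field: float) -> float:
    geom = BeamlineGeometry(SOURCE_HEIGHT, -1.0, 1.0)  # grid unused here
    return cone_tangent_height(exit_diameter, nominal_field, geom)


def make_fixture(name: str, fwhm: float = 1.5, slice_step: float = 0.001) -> Fixture:
    """Build one of the documented example systems.

    ``collimator4``: 4 mm nominal field, entrance/exit diameters 2.3 / 1.8 mm.
    ``collimator25``: 25 mm nominal field, apertures scaled 25/4 from the 4 mm
    system at the same heights.
    """
    if name == "collimator4":
        exit_h = _exit_height(1.8, 4.0)  # 251.35 mm
        apertures = [
            ApertureConfig(radius=1.15, height=ENTRANCE_HEIGHT),
            ApertureConfig(radius=0.9, height=exit_h),
        ]
        notes = (
            "4 mm conical collimator. Known: source-plane distance 457 mm, "
            "entrance/exit diameters 2.3/1.8 mm, Gaussian spot FWHM 1.5 mm. "
            "Reconstructed: exit height 251.35 mm (cone-tangent to the 4 mm "
            "field), entrance height 407 mm (50 mm below the source, trims "
            "off-focus rays)."
        )
    elif name == "collimator25":
        exit_h = _exit_height(1.8, 4.0)  # same heights as the 4 mm system
        scale = 25.0 / 4.0
        apertures = [
            ApertureConfig(radius=1.15 * scale, height=ENTRANCE_HEIGHT),
            ApertureConfig(radius=0.9 * scale, height=exit_h),
        ]
        notes = (
            "25 mm conical collimator. Known: source-plane distance 457 mm, "
            "25 mm design field, Gaussian spot FWHM 1.5 mm. Reconstructed: "
            "aperture heights as in the 4 mm system; radii scaled by the 25/4 "
            "field ratio (exit 5.625 mm cone-tangent to the 25 mm field, "
            "entrance 7.1875 mm) so the exit aperture governs the field edge."
        )
    else:
        raise ConfigError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    config = RunConfig(
        geometry=GeometryConfig(source_height=SOURCE_HEIGHT),
        source=SourceConfig(kind="gaussian", fwhm=fwhm, slice_step=slice_step),
        apertures=apertures,
    )
    return Fixture(name=name, config=config, notes=notes)
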