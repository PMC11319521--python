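"""Exception hierarchy for the beam-model tool."""


class BeamModelError(Exception):
    """Base class for all errors raised by this package."""


class GeometryError(BeamModelError):
    """Invalid beamline geometry (e.g. aperture at or above the source)."""


class DegenerateSourceError(BeamModelError):
    """Source span too narrow to be discretized into slices."""


class UndefinedMetricError(BeamModelError):
    """A profile metric cannot be evaluated (missing level crossing, zero peak)."""


class ConfigError(BeamModelError):
    """Configuration file or fixture problem."""
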