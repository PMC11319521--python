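import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import penumbra as pn

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")

# The worked single-aperture system: 0.9 mm radius aperture at the
# cone-tangent height for a 4 mm field, 457 mm source distance.
SOURCE_HEIGHT = 457.0
EXIT_RADIUS = 0.9
EXIT_HEIGHT = 251.35
MAG = SOURCE_HEIGHT / (SOURCE_HEIGHT - EXIT_HEIGHT)  # 2.2222


@pytest.fixture
def geom():
    return pn.BeamlineGeometry(SOURCE_HEIGHT, -12.0, 12.0, 0.1)


@pytest.fixture
def exit_aperture():
    return pn.Aperture(EXIT_RADIUS, EXIT_HEIGHT)


@pytest.fixture
def gaussian_source():
    return pn.SourceModel.gaussian(1.5)


@pytest.fixture
def single_aperture_profile(gaussian_source, exit_aperture, geom):
    return pn.integrate_profile(gaussian_source, [exit_aperture], geom)


@pytest.fixture
def collimator4():
    return pn.make_fixture("collimator4")


@pytest.fixture
def top_hat():
    """Ideal top-hat of full width 4.0 mm sampled at 0.1 mm: edges fall on
    grid points, carrying the half value an ideal sampler records there."""
    r = 0.1 * np.arange(-60, 61)
    v = ((np.abs(r) < 2.0) + 0.5 * (np.abs(np.abs(r) - 2.0) < 1e-9)).astype(float)
    return pn.Profile(r, v)
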