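import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import transitqa as tq

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_geom() -> tq.BeamGeometry:
    """64x64 image at 2 mm pitch: desk-scale geometry for fast tests."""
    return tq.BeamGeometry(pixel_pitch_iso=0.2, shape=(64, 64))


@pytest.fixture(scope="session")
def small_field(small_geom) -> tq.PortalImage:
    return tq.open_field(small_geom, radius=4.0, penumbra=0.4)


@pytest.fixture(scope="session")
def sin_curve() -> tq.BreathingCurve:
    """Sinusoid: 4 s period, 2 cm peak-to-peak, 12 s duration."""
    return tq.make_sinusoid(4.0, 2.0, 12.0)


@pytest.fixture(scope="session")
def sphere2() -> tq.SpherePhantom:
    return tq.SpherePhantom(2.0)


@pytest.fixture(scope="session")
def sphere4() -> tq.SpherePhantom:
    return tq.SpherePhantom(4.0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
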