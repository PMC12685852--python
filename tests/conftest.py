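import numpy as np
import pytest

from mvquant import phantom

# keep hypothesis deterministic and cheap across the suite
try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "suite",
        derandomize=True,
        max_examples=25,
        deadline=None,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def default_spec():
    """The default study phantom: R=14 mm, 2 mm saddle, 16 frames, 0.5 mm."""
    return phantom.PhantomSpec()


@pytest.fixture(scope="session")
def default_sequence(default_spec):
    return phantom.make_phantom_sequence(default_spec)


@pytest.fixture(scope="session")
def small_spec():
    """A cheaper 4-frame phantom for per-operation tests."""
    return phantom.PhantomSpec(n_frames=4, grid_shape=(80, 80, 80))


@pytest.fixture(scope="session")
def small_frame(small_spec):
    """Mid-cycle frame (maximum opening, orifice radius = r_max = 10 mm)."""
    return phantom.make_phantom_frame(small_spec, 2)


@pytest.fixture(scope="session")
def flat_ring_spec():
    """Planar untilted ring phantom (saddle 0, tilt 0) for analytic checks."""
    return phantom.PhantomSpec(saddle_height_mm=0.0, tilt_deg=0.0, n_frames=4,
                               grid_shape=(80, 80, 80))


@pytest.fixture(scope="session")
def flat_ring_frame(flat_ring_spec):
    return phantom.make_phantom_frame(flat_ring_spec, 1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
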