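import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from icemorph.phantom import PhantomSpec, fast_freezing_spec, slow_freezing_spec, generate_phantom


#: reduced problem size used by phantom-based tests (full presets are 200^3)
TEST_SHAPE = (120, 120, 120)


@pytest.fixture(scope="session")
def fast_phantom():
    return generate_phantom(fast_freezing_spec(shape=TEST_SHAPE))


@pytest.fixture(scope="session")
def slow_phantom():
    return generate_phantom(slow_freezing_spec(shape=TEST_SHAPE))


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(
        fast_freezing_spec(shape=TEST_SHAPE, noise_sigma=0.0, blur_sigma=0.0)
    )


def digit_sphere(shape, center, radius):
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2
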