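import numpy as np
import pytest

from activeecho import (
    AEDevice,
    PhantomSpec,
    Scene,
    ScattererField,
    make_phantom,
    preset_probe,
    water,
)


@pytest.fixture(scope="session")
def water_med():
    return water()


@pytest.fixture(scope="session")
def probe():
    """Default general-mode probe: 128 elements, 256 lines, aperture 32."""
    return preset_probe("general")


@pytest.fixture(scope="session")
def fast_probe():
    """Small probe for end-to-end tests that loop over frames."""
    return preset_probe("general", n_elements=64, lines_per_frame=64, max_depth=0.05)


@pytest.fixture(scope="session")
def empty_scene(water_med):
    return Scene(water_med, ScattererField.empty())


@pytest.fixture(scope="session")
def speckle_scene(water_med):
    spec = PhantomSpec(bounds=(0.04, 0.012, 0.05), density=40.0)
    return Scene(water_med, make_phantom(spec, seed=7))


@pytest.fixture()
def device():
    return AEDevice(position=(0.0, 0.0, 0.04))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
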