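import numpy as np
import pytest

from hu2rgb.phantom import default_spec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Noise-free default phantom slice and its ground truth."""
    return generate_phantom(default_spec())


@pytest.fixture(scope="session")
def phantom_no_calc():
    """Default phantom without the calcification blob."""
    return generate_phantom(default_spec(calcifications=()))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_hu_grid(rng, shape=(32, 32)):
    """A random HU slice covering air..bone, including the cap boundaries."""
    choices = np.array(
        [-1000.0, -50.0, 0.0, 10.0, 15.0, 20.0, 25.0, 35.0, 40.0, 60.0,
         80.0, 110.0, 111.0, 120.0, 200.0, 1000.0]
    )
    return choices[rng.integers(0, len(choices), size=shape)]
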