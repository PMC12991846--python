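import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from paiq import Image, PhantomSpec, generate_phantom, validate_pair


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def vessel():
    return generate_phantom(PhantomSpec(kind="vessel", size=128, seed=7))


@pytest.fixture
def derenzo():
    return generate_phantom(PhantomSpec(kind="derenzo", size=128, seed=7))


@pytest.fixture
def noisy_pair(vessel, rng):
    noisy = np.clip(vessel.pixels + rng.normal(0, 0.08, vessel.shape), 0, 1)
    return validate_pair(vessel, Image(noisy, data_range=1.0, id="noisy"))


def random_pair(rng, size=64):
    x = rng.random((size, size))
    y = np.clip(x + rng.normal(0, 0.1, (size, size)), 0, 1)
    return validate_pair(Image(x, id="x"), Image(y, id="y"))
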