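import numpy as np
import pytest

from trabecula3d import BinaryMask
from trabecula3d.phantoms import PhantomSpec, generate


def make_phantom(kind, shape, **params):
    seed = params.pop("rng_seed", 0)
    spacing = params.pop("spacing", 1.0)
    unit = params.pop("unit", "")
    return generate(PhantomSpec(kind, shape, spacing=spacing, unit=unit, rng_seed=seed, params=params))


@pytest.fixture
def ball_mask() -> BinaryMask:
    return make_phantom("ball", (32, 32, 32), radius=10).mask


@pytest.fixture
def slab_mask() -> BinaryMask:
    return make_phantom("slab", (20, 40, 40), thickness=5).mask


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
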