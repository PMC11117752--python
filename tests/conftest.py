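import numpy as np
import pytest

from spatreg.core import BinaryMask, Volume3D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape=(16, 16, 16), p=0.2, spacing=(1.0, 1.0, 1.5), role="lesion"):
    return BinaryMask(rng.random(shape) < p, spacing, role=role)


def mask_from_coords(coords, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0), role="lesion"):
    data = np.zeros(shape, dtype=bool)
    for c in coords:
        data[tuple(c)] = True
    return BinaryMask(data, spacing, role=role)


@pytest.fixture
def small_post_phantom():
    from spatreg.phantoms import PhantomSpec, generate_phantom

    spec = PhantomSpec.for_style(
        "post_treatment", shape=(32, 32, 16), spacing=(1.0, 1.0, 1.5),
        lesion_radius_mm=4.0, cavity_radius_mm=2.0, irregularity_mm=0.8,
        noise_sd=0.05, seed=7)
    return generate_phantom(spec)
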