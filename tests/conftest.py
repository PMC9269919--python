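import numpy as np
import pytest

from atriaquant import LabelMap, PhantomSpec, generate_la_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20220708)


@pytest.fixture
def noise_free_spec():
    """Binary-wall, noise-free phantom: classes are exact delta functions."""
    return PhantomSpec(fibrosis_fraction=0.10, tissue_sigma=0.0, noise_sigma=0.0)


@pytest.fixture
def noise_free_phantom(noise_free_spec):
    return generate_la_phantom(noise_free_spec)


@pytest.fixture
def default_phantom():
    return generate_la_phantom(PhantomSpec(seed=11))


def random_mask(rng, shape=(12, 12, 4), p=0.2, spacing=(1.0, 1.0, 1.0)) -> LabelMap:
    return LabelMap(rng.random(shape) < p, "generic", spacing)
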