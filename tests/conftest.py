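import numpy as np
import pytest

from renalswin.io import ImageSlice, SegMask
from renalswin.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cyst_phantom():
    return generate_phantom(PhantomSpec(class_label="cyst", seed=7))


@pytest.fixture
def normal_phantom():
    return generate_phantom(PhantomSpec(class_label="normal", seed=11))


@pytest.fixture
def random_slice(rng):
    return ImageSlice(rng.uniform(0, 255, size=(32, 32)))


@pytest.fixture
def paired_mask(rng):
    labels = np.zeros((32, 32), dtype=np.int64)
    labels[8:24, 8:24] = 1
    labels[12:18, 12:18] = 2
    return SegMask(labels)
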