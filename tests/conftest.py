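import numpy as np
import pytest
from hypothesis import settings

from imgtrain import make_shapes_dataset, make_stained_culture

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def shapes_train():
    return make_shapes_dataset(n_classes=3, n_per_class=16, side=32, seed=7,
                               split="train")


@pytest.fixture(scope="session")
def shapes_valid():
    return make_shapes_dataset(n_classes=3, n_per_class=6, side=32, seed=8,
                               split="valid")


@pytest.fixture(scope="session")
def stained_small():
    # 160x160 keeps tile counts small (25 grid tiles per image)
    return make_stained_culture(n_images=4, side=160, seed=3)
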