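import numpy as np
import pytest

from cardioseg import LabelMap, PhantomConfig, generate_split


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom_cfg32():
    """Small phantom configuration for fast training smoke tests."""
    return PhantomConfig(dim=2, grid=(32, 32), num_classes=4,
                         lv_radius=(0.09, 0.13), myo_thickness=(0.07, 0.09),
                         rv_radius=(0.11, 0.14))


@pytest.fixture(scope="session")
def tiny_split(phantom_cfg32):
    """A small fully generated semi-supervised split plus test pairs."""
    return generate_split(phantom_cfg32, n_total=24, labeled_fraction=0.25,
                          seed=42, n_test=4)


def random_label_map(rng, shape, num_classes) -> LabelMap:
    return LabelMap(rng.integers(0, num_classes, size=shape).astype(np.int32),
                    num_classes)
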