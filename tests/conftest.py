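import numpy as np
import pytest

import bactexture as bt
from bactexture.synthetic import get_preset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_image(rng):
    return bt.LabeledImage(rng.random((64, 64)), label="noise")


@pytest.fixture(scope="session")
def demo_dataset():
    """Small in-memory synthetic dataset: 3 contrasted classes, 8 images each."""
    specs = [get_preset("demo5")[i] for i in (0, 2, 4)]
    index, images = bt.generate_dataset(specs, images_per_class=8,
                                        size=(96, 96), seed=42)
    return index, images


@pytest.fixture(scope="session")
def blob_features():
    """Well-separated 3-class Gaussian blobs in 2-D."""
    rng = np.random.default_rng(7)
    centers = np.array([[0.0, 0.0], [8.0, 0.0], [0.0, 8.0]])
    X = np.concatenate([c + rng.normal(0, 0.4, size=(30, 2)) for c in centers])
    y = np.repeat(["a", "b", "c"], 30)
    return X, y
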