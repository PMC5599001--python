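"""Pluggable backends for deep local descriptors.

A backend exposes two extractors: a convolutional one, producing a
spatial grid of D-dimensional local descriptors (the network truncated
at its last convolutional layer), and a global one, producing a single
fixed-length vector (the penultimate fully-connected layer).  Pretrained
ImageNet networks ("AN" = AlexNet, "M" = VGG-M, "VD" = VGG-VD) are
adapter slots that require user-supplied weights; a seeded toy
filter-bank backend ships with the package so the FV-CNN / FC-CNN code
paths are exercisable without any weights.
"""

from __future__ import annotations

import numpy as np
from PIL import Image
from scipy.ndimage import correlate

from .dsift import DescriptorField
from .io import LabeledImage


class BackendNotAvailableError(RuntimeError):
    """Raised when a backend's weights are not installed."""


class FeatureBackend:
    """Contract: deterministic conv-field and FC-vector extraction."""

    name: str = "base"

    def conv_field(self, image: LabeledImage) -> DescriptorField:
        raise NotImplementedError

    def fc_vector(self, image: LabeledImage) -> np.ndarray:
        raise NotImplementedError


def _resize(pixels: np.ndarray, hw: tuple[int, int]) -> np.ndarray:
    im = Image.fromarray((np.clip(pixels, 0, 1) * 255).astype(np.uint8))
    out = np.asarray(im.resize(hw[::-1], Image.BILINEAR), dtype=np.float64) / 255.0
    return out


class ToyBackend(FeatureBackend):
    """Seeded random 3x3 filter bank with rectification and striding.

    Not a trained network: its role is to produce descriptor fields and
    global vectors with the same shapes and determinism guarantees as a
    real backend, so encoding and classification plumbing can be tested.
    The FC vector is the per-channel global average and maximum of the
    rectified responses on a canonically resized input (2 statistics x
    n_filters channels).
    """

    def __init__(self, seed: int = 0, n_filters: int = 8, kernel_size: int = 3,
                 stride: int = 4, fc_input_side: int = 64):
        self.name = "toy"
        self.seed = seed
        self.n_filters = n_filters
        self.kernel_size = kernel_size
        self.stride = stride
        self.fc_input_side = fc_input_side
        rng = np.random.default_rng(seed)
        self.filters = rng.standard_normal((n_filters, kernel_size, kernel_size))
        self.filters -= self.filters.mean(axis=(1, 2), keepdims=True)

    def _response_maps(self, pixels: np.ndarray) -> np.ndarray:
        maps = np.stack([correlate(pixels, f, mode="reflect") for f in self.filters],
                        axis=-1)
        return np.maximum(maps, 0.0)  # rectification

    def conv_field(self, image: LabeledImage) -> DescriptorField:
        maps = self._response_maps(image.pixels)
        rows = np.arange(0, maps.shape[0], self.stride)
        cols = np.arange(0, maps.shape[1], self.stride)
        desc = maps[np.ix_(rows, cols)].reshape(len(rows) * len(cols), self.n_filters)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        return DescriptorField(
            locations=np.stack([rr.ravel(), cc.ravel()], axis=1),
            descriptors=desc, grid_shape=(len(rows), len(cols)))

    def fc_vector(self, image: LabeledImage) -> np.ndarray:
        side = self.fc_input_side
        pixels = image.pixels
        if pixels.shape != (side, side):
            pixels = _resize(pixels, (side, side))
        maps = self._response_maps(pixels)
        return np.concatenate([maps.mean(axis=(0, 1)), maps.max(axis=(0, 1))])


class PretrainedBackend(FeatureBackend):
    """Adapter slot for ImageNet-pretrained networks (weights not bundled)."""

    def __init__(self, name: str, weights_path: str | None = None):
        self.name = name
        self.weights_path = weights_path

    def _unavailable(self) -> BackendNotAvailableError:
        return BackendNotAvailableError(
            f"backend {self.name!r} is not available: pretrained weights are not "
            f"bundled; supply a weights adapter or use the 'toy' backend")

    def conv_field(self, image: LabeledImage) -> DescriptorField:
        raise self._unavailable()

    def fc_vector(self, image: LabeledImage) -> np.ndarray:
        raise self._unavailable()


#: known backend names (pretrained ones require user-supplied weights)
BACKEND_NAMES = ("toy", "AN", "M", "VD")


def get_backend(name: str, seed: int = 0, weights_path: str | None = None) -> FeatureBackend:
    """Look up a backend by name; unknown names raise with the known list."""
    if name == "toy":
        return ToyBackend(seed=seed)
    if name in BACKEND_NAMES:
        return PretrainedBackend(name, weights_path)
    raise ValueError(f"unknown backend {name!r}; known backends: {BACKEND_NAMES}")


def extract_conv_field(backend: FeatureBackend, image: LabeledImage) -> DescriptorField:
    """Grid of local descriptors from the backend's convolutional stage."""
    return backend.conv_field(image)


def extract_fc_vector(backend: FeatureBackend, image: LabeledImage) -> np.ndarray:
    """Fixed-length global descriptor from the backend's penultimate FC layer."""
    return backend.fc_vector(image)
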