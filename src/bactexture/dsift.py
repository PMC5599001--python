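"""Dense SIFT: gradient-orientation histograms on a regular pixel grid.

Each descriptor is the classic 4x4 spatial-bin x 8 orientation-bin
histogram (128 dimensions) of gradient magnitudes inside a square patch
of side ``4 * bin_size`` pixels.  Patches are sampled every ``step``
pixels (default 2) on a grid that keeps every patch fully inside the
image; no keypoint detection, rotation or scale machinery is involved.

Binning is soft: a pixel's gradient magnitude is split linearly between
the two adjacent orientation bins and bilinearly between the (up to
four) adjacent spatial bins, with the triangular spatial weights
truncated to the patch window.  Descriptors are L2-normalized, clamped
at 0.2 and re-normalized; flat patches yield all-zero descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import LabeledImage

N_ORIENTATIONS = 8
N_SPATIAL_BINS = 4
SIFT_DIM = N_SPATIAL_BINS * N_SPATIAL_BINS * N_ORIENTATIONS  # 128
CLAMP = 0.2
_FLAT_EPS = 1e-12


@dataclass
class DescriptorField:
    """A row-major grid of D-dimensional local descriptors.

    ``locations[i]`` is the (row, col) patch center of ``descriptors[i]``;
    the grid has ``grid_shape = (rows, cols)`` with ``rows * cols == N``.
    """

    locations: np.ndarray  # N x 2 int
    descriptors: np.ndarray  # N x D float
    grid_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.locations = np.asarray(self.locations)
        self.descriptors = np.asarray(self.descriptors, dtype=np.float64)
        n = self.descriptors.shape[0]
        if self.locations.shape != (n, 2):
            raise ValueError("locations must be N x 2")
        if n != self.grid_shape[0] * self.grid_shape[1]:
            raise ValueError("grid_shape inconsistent with descriptor count")
        if not np.all(np.isfinite(self.descriptors)):
            raise ValueError("descriptors contain non-finite values")

    @property
    def descriptor_dim(self) -> int:
        return self.descriptors.shape[1]

    def save(self, path) -> None:
        np.savez(path, locations=self.locations, descriptors=self.descriptors,
                 grid_shape=np.asarray(self.grid_shape))

    @classmethod
    def load(cls, path) -> "DescriptorField":
        with np.load(path) as z:
            return cls(locations=z["locations"], descriptors=z["descriptors"],
                       grid_shape=tuple(int(v) for v in z["grid_shape"]))


def gradient_orientation_maps(pixels: np.ndarray) -> np.ndarray:
    """Per-pixel gradient magnitude split over 8 orientation channels.

    Gradients are central differences (one-sided at image borders); the
    magnitude is shared linearly between the two orientation bins
    adjacent to the gradient angle.  Returns an H x W x 8 array.
    """
    gy, gx = np.gradient(pixels)
    mag = np.hypot(gx, gy)
    ang = np.mod(np.arctan2(gy, gx), 2 * np.pi)
    a = ang / (2 * np.pi / N_ORIENTATIONS)
    i0 = np.floor(a).astype(np.intp) % N_ORIENTATIONS
    frac = a - np.floor(a)
    h, w = pixels.shape
    maps = np.zeros((h * w, N_ORIENTATIONS))
    flat_idx = np.arange(h * w)
    maps[flat_idx, i0.ravel()] += (mag * (1 - frac)).ravel()
    maps[flat_idx, (i0.ravel() + 1) % N_ORIENTATIONS] += (mag * frac).ravel()
    return maps.reshape(h, w, N_ORIENTATIONS)


def spatial_bin_weights(bin_size: int) -> np.ndarray:
    """Truncated triangular weights, shape (4 spatial bins, 4*bin_size).

    Pixel offsets inside the patch are symmetrized to half-integers
    (u + 0.5 for u in -2b..2b-1); bin centers sit at
    (-1.5, -0.5, 0.5, 1.5) * bin_size.
    """
    offsets = np.arange(4 * bin_size) - 2 * bin_size + 0.5
    centers = (np.arange(N_SPATIAL_BINS) - 1.5) * bin_size
    return np.clip(1.0 - np.abs(offsets[None, :] - centers[:, None]) / bin_size, 0.0, None)


def _normalize_rows(desc: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(desc, axis=1, keepdims=True)
    flat = norms[:, 0] < _FLAT_EPS
    norms[flat] = 1.0
    desc = np.minimum(desc / norms, CLAMP)
    norms = np.linalg.norm(desc, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    desc = desc / norms
    desc[flat] = 0.0
    return desc


def _descriptors_from_maps(maps: np.ndarray, centers_r: np.ndarray,
                           centers_c: np.ndarray, bin_size: int) -> np.ndarray:
    """Pool orientation maps into descriptors at a grid of patch centers."""
    w = spatial_bin_weights(bin_size)  # (4, 4b)
    side = 4 * bin_size
    view = np.lib.stride_tricks.sliding_window_view(maps, (side, side), axis=(0, 1))
    # view: (H-side+1, W-side+1, 8, side, side); window start = center - 2b
    starts_r = centers_r - 2 * bin_size
    starts_c = centers_c - 2 * bin_size
    nr, nc = len(starts_r), len(starts_c)
    out = np.empty((nr, nc, N_SPATIAL_BINS, N_SPATIAL_BINS, N_ORIENTATIONS))
    # chunk grid rows to bound the materialized window copy
    chunk = max(1, int(8e7 / max(1, nc * N_ORIENTATIONS * side * side * 8)))
    for lo in range(0, nr, chunk):
        hi = min(lo + chunk, nr)
        win = view[starts_r[lo:hi]][:, starts_c]  # (m, nc, 8, side, side)
        t = np.tensordot(win, w, axes=([4], [1]))  # (m, nc, 8, side, 4cb)
        t = np.tensordot(t, w, axes=([3], [1]))  # (m, nc, 8, 4cb, 4rb)
        out[lo:hi] = np.transpose(t, (0, 1, 4, 3, 2))
    return out.reshape(nr * nc, SIFT_DIM)


def sift_descriptor_at(image: LabeledImage | np.ndarray, center: tuple[int, int],
                       bin_size: int = 8) -> np.ndarray:
    """SIFT descriptor (length 128) for the patch centered at (row, col).

    The 4*bin_size-pixel patch must lie entirely inside the image.
    """
    pixels = image.pixels if isinstance(image, LabeledImage) else np.asarray(image)
    h, w = pixels.shape
    r, c = center
    m = 2 * bin_size
    if not (m <= r <= h - m and m <= c <= w - m):
        raise ValueError(f"patch at {center} with bin_size {bin_size} "
                         f"exceeds image bounds {h}x{w}")
    maps = gradient_orientation_maps(pixels)
    desc = _descriptors_from_maps(maps, np.array([r]), np.array([c]), bin_size)
    return _normalize_rows(desc)[0]


def grid_centers(h: int, w: int, step: int, bin_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Patch centers: margin .. size - margin inclusive, every ``step``."""
    m = 2 * bin_size
    if h < 2 * m or w < 2 * m:
        raise ValueError(f"image too small ({h}x{w}) for bin_size {bin_size}")
    return np.arange(m, h - m + 1, step), np.arange(m, w - m + 1, step)


def extract_dsift(image: LabeledImage | np.ndarray, step: int = 2,
                  bin_size: int = 8) -> DescriptorField:
    """Dense SIFT over the whole image with the given sampling step."""
    pixels = image.pixels if isinstance(image, LabeledImage) else np.asarray(image)
    h, w = pixels.shape
    rows, cols = grid_centers(h, w, step, bin_size)
    maps = gradient_orientation_maps(pixels)
    desc = _normalize_rows(_descriptors_from_maps(maps, rows, cols, bin_size))
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    locations = np.stack([rr.ravel(), cc.ravel()], axis=1)
    return DescriptorField(locations=locations, descriptors=desc,
                           grid_shape=(len(rows), len(cols)))


class DenseSift(BaseEstimator, TransformerMixin):
    """Stateless sklearn-style transformer: images -> descriptor fields.

    Parameters
    ----------
    step : sampling step in pixels (2 reproduces the dense-grid protocol).
    bin_size : spatial bin side in pixels; the patch side is 4 * bin_size.
    """

    def __init__(self, step: int = 2, bin_size: int = 8):
        self.step = step
        self.bin_size = bin_size

    def fit(self, X, y=None):
        self.n_features_in_ = 0  # no fitting required
        return self

    def transform(self, X) -> list[DescriptorField]:
        return [extract_dsift(img, step=self.step, bin_size=self.bin_size) for img in X]
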