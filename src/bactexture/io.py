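"""Image collections, grayscale loading and seeded train/test splits.

Datasets follow the one-directory-per-class layout
``root/<class_id>/<image>.{tif,png,jpg,...}`` where the class id is a
"major.minor" genus/species shorthand (e.g. ``"18.2"``).  Images are
converted to single-channel intensity grids in [0, 1].
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = {".tif", ".tiff", ".png", ".jpg", ".jpeg", ".bmp"}

#: ITU-R 601 luminance weights for RGB -> intensity reduction.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class LabeledImage:
    """A single-channel intensity grid with its class label.

    ``pixels`` is an H x W float array with every value in [0, 1];
    coordinates are 0-based row-major (row, col).
    """

    pixels: np.ndarray
    label: str
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")
        h, w = self.pixels.shape
        if h < 16 or w < 16:
            raise ValueError(f"image too small: {h}x{w}, need at least 16x16")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("pixel intensities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def class_sort_key(label: str):
    """Sort key placing "major.minor" ids in numeric order (10.2 < 10.10).

    Labels that do not parse as dotted integers sort lexicographically
    after the numeric ones.
    """
    parts = label.split(".")
    try:
        return (0, tuple(int(p) for p in parts))
    except ValueError:
        return (1, (label,))


@dataclass
class DatasetIndex:
    """Entries ``(source, label)`` plus the ordered unique class list."""

    entries: list[tuple[str, str]]
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = {lab for _, lab in self.entries}
        if not self.classes:
            self.classes = sorted(labels, key=class_sort_key)
        missing = labels - set(self.classes)
        if missing:
            raise ValueError(f"entries reference unknown classes: {sorted(missing)}")

    def entries_for(self, label: str) -> list[str]:
        return [src for src, lab in self.entries if lab == label]

    def subset(self, classes: Sequence[str]) -> "DatasetIndex":
        keep = set(classes)
        ordered = [c for c in self.classes if c in keep]
        return DatasetIndex(
            entries=[(s, l) for s, l in self.entries if l in keep],
            classes=ordered,
        )

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class SplitPlan:
    """Disjoint per-class train/test source lists, reproducible from ``seed``."""

    per_class: dict[str, dict[str, list[str]]]
    seed: int

    def train_entries(self) -> list[tuple[str, str]]:
        return [(s, c) for c, d in self.per_class.items() for s in d["train"]]

    def test_entries(self) -> list[tuple[str, str]]:
        return [(s, c) for c, d in self.per_class.items() for s in d["test"]]

    def to_json(self) -> str:
        return json.dumps({"seed": self.seed, "classes": self.per_class}, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        obj = json.loads(text)
        return cls(per_class=obj["classes"], seed=obj["seed"])


def scan_dataset(root_dir: str | os.PathLike) -> DatasetIndex:
    """Index every readable image under ``root/<class_id>/``.

    Entry order is deterministic (classes in numeric id order, files
    lexicographic within a class); unreadable files are skipped with a
    logged warning.
    """
    root = Path(root_dir)
    subdirs = sorted((d for d in root.iterdir() if d.is_dir()),
                     key=lambda d: class_sort_key(d.name)) if root.is_dir() else []
    if not subdirs:
        raise ValueError(f"no classes found under {root}")
    entries: list[tuple[str, str]] = []
    for d in subdirs:
        files = sorted(p for p in d.iterdir()
                       if p.suffix.lower() in IMAGE_EXTENSIONS and p.is_file())
        for p in files:
            try:
                with Image.open(p) as im:
                    im.verify()
            except Exception as exc:  # corrupt or unreadable
                logger.warning("skipping unreadable image %s: %s", p, exc)
                continue
            entries.append((str(p), d.name))
    if not entries:
        raise ValueError(f"no readable images found under {root}")
    return DatasetIndex(entries=entries)


def _to_unit_interval(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    arr = arr.astype(np.float64)
    if arr.size and arr.max() > 1.0:  # integer-coded floats
        arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)


def load_grayscale(
    source: str | os.PathLike | np.ndarray,
    label: str = "",
    max_side: int | None = 512,
) -> LabeledImage:
    """Load an image as a [0, 1] intensity grid.

    Three-channel inputs are reduced with ITU-R 601 luminance weights
    (0.299, 0.587, 0.114).  If ``max_side`` is set and the longest side
    exceeds it, the image is downscaled (bilinear, aspect preserved).
    """
    if isinstance(source, np.ndarray):
        arr = source
        src_name = "array"
    else:
        path = Path(source)
        try:
            with Image.open(path) as im:
                im.load()
                arr = np.asarray(im)
        except Exception as exc:
            raise IOError(f"cannot load image {path}: {exc}") from exc
        src_name = str(path)
    arr = _to_unit_interval(np.asarray(arr))
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise ValueError(f"unsupported channel count {arr.shape[2]}")
        arr = arr @ LUMA_WEIGHTS
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim}")
    if max_side is not None and max(arr.shape) > max_side:
        scale = max_side / max(arr.shape)
        new_hw = (max(1, round(arr.shape[0] * scale)), max(1, round(arr.shape[1] * scale)))
        im = Image.fromarray((np.clip(arr, 0, 1) * 255).astype(np.uint8))
        arr = np.asarray(im.resize(new_hw[::-1], Image.BILINEAR)).astype(np.float64) / 255.0
    return LabeledImage(pixels=np.clip(arr, 0.0, 1.0), label=label, source=src_name)


def make_split(index: DatasetIndex, per_class_train: int = 10, seed: int = 0) -> SplitPlan:
    """Draw a balanced per-class train/test split without replacement.

    Each class contributes ``per_class_train`` training and an equal
    number of test images.  The per-class draw is seeded by
    ``seed + class position`` so adding a class leaves other classes'
    splits unchanged.
    """
    per_class: dict[str, dict[str, list[str]]] = {}
    for ci, cls in enumerate(index.classes):
        sources = index.entries_for(cls)
        if len(sources) < 2 * per_class_train:
            raise ValueError(
                f"class {cls!r} has {len(sources)} images, "
                f"needs at least {2 * per_class_train}"
            )
        rng = np.random.default_rng(seed + ci)
        perm = rng.permutation(len(sources))
        train = [sources[i] for i in perm[:per_class_train]]
        test = [sources[i] for i in perm[per_class_train:2 * per_class_train]]
        per_class[cls] = {"train": train, "test": test}
    return SplitPlan(per_class=per_class, seed=seed)
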