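"""Seeded synthetic micrograph-like texture classes.

Classes differ in particle shape (disc / rod / curved rod), size,
density and spatial arrangement (solitary, chains, clusters) on a noisy
background — the morphotype axes along which stained bacterial smears
differ.  Particles are placed by a seeded point process, rendered with
anti-aliased edges at a foreground intensity (overlaps combine by
intensity max), and additive Gaussian noise is clipped to [0, 1].

The generator emulates texture statistics only: it makes no attempt at
biophysical realism or at matching any real species' appearance.  Two
frozen presets ship with the package: ``demo5`` (5 well-contrasted
classes) and ``scale12`` (12 classes for scalability runs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .io import DatasetIndex, LabeledImage

PARTICLES = ("disc", "rod", "curved-rod")
ARRANGEMENTS = ("solitary", "chain", "cluster")

#: arc angle subtended by a curved rod's midline (radians)
CURVED_ROD_ARC = 1.8
#: number of polyline segments used to render a curved rod
_ARC_SEGMENTS = 8


@dataclass(frozen=True)
class TextureClassSpec:
    """Parameters of one synthetic texture class.

    ``particle_size`` is the disc diameter or rod length in pixels
    (jittered per particle by a Gaussian of sd ``size_jitter``);
    ``density`` is expected particles per 10^4 px^2; ``group_size`` is
    the mean chain length or cluster size (ignored for solitary).
    Orientation is uniform or concentrated around ``orientation_mean``
    with sd ``orientation_spread`` (radians).
    """

    class_id: str
    particle: str = "disc"
    particle_size: float = 5.0
    size_jitter: float = 0.5
    density: float = 40.0
    arrangement: str = "solitary"
    group_size: float = 1.0
    orientation: str = "uniform"
    orientation_mean: float = 0.0
    orientation_spread: float = 0.3
    fg: float = 0.85
    bg: float = 0.2
    noise_sigma: float = 0.05

    def __post_init__(self) -> None:
        if self.particle not in PARTICLES:
            raise ValueError(f"unknown particle {self.particle!r}")
        if self.arrangement not in ARRANGEMENTS:
            raise ValueError(f"unknown arrangement {self.arrangement!r}")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.particle_size < 1:
            raise ValueError("particle_size must be at least 1 px")
        if not (0 <= self.fg <= 1 and 0 <= self.bg <= 1):
            raise ValueError("intensities must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def _render_capsule(alpha: np.ndarray, points: np.ndarray, radius: float) -> None:
    """Max-composite an anti-aliased capsule around a polyline into alpha."""
    h, w = alpha.shape
    pad = radius + 1.5
    r0 = max(0, int(math.floor(points[:, 0].min() - pad)))
    r1 = min(h, int(math.ceil(points[:, 0].max() + pad)) + 1)
    c0 = max(0, int(math.floor(points[:, 1].min() - pad)))
    c1 = min(w, int(math.ceil(points[:, 1].max() + pad)) + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    grid = np.stack([rr, cc], axis=-1).astype(float)
    dist = np.full(rr.shape, np.inf)
    for a, b in zip(points[:-1], points[1:]):
        ab = b - a
        denom = float(ab @ ab)
        ap = grid - a
        t = np.clip((ap @ ab) / denom, 0.0, 1.0) if denom > 1e-12 else 0.0
        closest = a + np.multiply.outer(t, ab)
        dist = np.minimum(dist, np.linalg.norm(grid - closest, axis=-1))
    patch = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    np.maximum(alpha[r0:r1, c0:c1], patch, out=alpha[r0:r1, c0:c1])


def _particle_points(spec: TextureClassSpec, center: np.ndarray, size: float,
                     theta: float) -> tuple[np.ndarray, float]:
    """Midline polyline and capsule radius for one particle."""
    if spec.particle == "disc":
        return np.array([center, center]), size / 2.0
    width = max(1.5, size / 3.5)
    radius = width / 2.0
    half = max(0.5, (size - width) / 2.0)
    direction = np.array([math.sin(theta), math.cos(theta)])
    if spec.particle == "rod":
        return np.array([center - half * direction, center + half * direction]), radius
    # curved rod: circular arc with chord ~ 2*half, bulging normal to theta
    arc_r = 2 * half / (2 * math.sin(CURVED_ROD_ARC / 2))
    normal = np.array([math.cos(theta), -math.sin(theta)])
    arc_center = center - arc_r * math.cos(CURVED_ROD_ARC / 2) * normal
    angles = np.linspace(-CURVED_ROD_ARC / 2, CURVED_ROD_ARC / 2, _ARC_SEGMENTS + 1)
    pts = arc_center[None, :] \
        + arc_r * np.cos(angles)[:, None] * normal[None, :] \
        + arc_r * np.sin(angles)[:, None] * direction[None, :]
    return pts, radius


def _draw_orientation(spec: TextureClassSpec, rng: np.random.Generator) -> float:
    if spec.orientation == "uniform":
        return float(rng.uniform(0.0, 2 * math.pi))
    return float(rng.normal(spec.orientation_mean, spec.orientation_spread))


def generate_image(
    spec: TextureClassSpec,
    size: tuple[int, int] = (128, 128),
    seed: int | Sequence[int] = 0,
    positions: Sequence[tuple[float, float]] | None = None,
) -> LabeledImage:
    """Render one seeded texture image for a class spec.

    ``positions`` is a test hook: when given, exactly one solitary
    particle is placed at each (row, col) and the point process is
    skipped.  Identical spec + seed yields bit-identical pixels.
    """
    h, w = size
    if h < 64 or w < 64:
        raise ValueError(f"image size {h}x{w} too small, need at least 64x64")
    rng = np.random.default_rng(seed)
    area = spec.particle_size ** 2  # generous per-particle bound
    lam = spec.density * h * w / 1e4
    if lam * area > 5 * h * w:
        raise ValueError(f"density {spec.density} too high for {h}x{w} image")
    alpha = np.zeros((h, w))

    # particles: list of (center, orientation); chains keep each member
    # aligned with the chain's local direction so consecutive cells touch
    if positions is not None:
        particles = [(np.asarray(p, dtype=float), _draw_orientation(spec, rng))
                     for p in positions]
    else:
        n_particles = int(rng.poisson(lam))
        particles = []
        while len(particles) < n_particles:
            anchor = rng.uniform([0, 0], [h, w])
            if spec.arrangement == "solitary":
                particles.append((anchor, _draw_orientation(spec, rng)))
                continue
            g = max(2, int(rng.poisson(spec.group_size)))
            g = min(g, n_particles - len(particles)) or 1
            if spec.arrangement == "chain":
                theta = _draw_orientation(spec, rng)
                step = spec.particle_size * 0.95  # consecutive cells touch
                pos = anchor.copy()
                for _ in range(g):
                    particles.append((pos.copy(), theta))
                    theta += rng.normal(0.0, 0.15)
                    direction = np.array([math.sin(theta), math.cos(theta)])
                    pos = pos + step * direction + rng.normal(0, 0.3, size=2)
            else:  # cluster
                radius = spec.particle_size * math.sqrt(g) / 1.6
                for _ in range(g):
                    particles.append((anchor + rng.normal(0, radius, size=2),
                                      _draw_orientation(spec, rng)))

    for center, theta in particles:
        psize = max(1.5, rng.normal(spec.particle_size, spec.size_jitter))
        pts, radius = _particle_points(spec, np.asarray(center), psize, theta)
        _render_capsule(alpha, pts, radius)

    pixels = spec.bg + (spec.fg - spec.bg) * alpha
    if spec.noise_sigma > 0:
        pixels = pixels + rng.normal(0.0, spec.noise_sigma, size=pixels.shape)
    return LabeledImage(pixels=np.clip(pixels, 0.0, 1.0), label=spec.class_id,
                        source="synthetic")


def generate_dataset(
    specs: Sequence[TextureClassSpec],
    images_per_class: int = 20,
    size: tuple[int, int] = (128, 128),
    seed: int = 0,
) -> tuple[DatasetIndex, dict[str, LabeledImage]]:
    """Generate a labeled collection in the standard index layout.

    Every class draws from its own seeded sub-stream
    (``[seed, class position, image position]``), so regenerating with
    the same seed is bit-identical and class order does not leak
    randomness across classes.
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 class specs")
    ids = [s.class_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate class_id in specs")
    entries, images = [], {}
    for ci, spec in enumerate(specs):
        for i in range(images_per_class):
            src = f"synthetic://{spec.class_id}/{i:03d}"
            img = generate_image(spec, size=size, seed=[seed, ci, i])
            img.source = src
            entries.append((src, spec.class_id))
            images[src] = img
    return DatasetIndex(entries=entries), images


def write_dataset(images: dict[str, LabeledImage], root: str | Path) -> Path:
    """Write generated images as 8-bit PNGs in the per-class directory layout."""
    root = Path(root)
    for src, img in images.items():
        stem = src.rsplit("/", 1)[-1]
        out_dir = root / img.label
        out_dir.mkdir(parents=True, exist_ok=True)
        arr = np.round(np.clip(img.pixels, 0, 1) * 255).astype(np.uint8)
        Image.fromarray(arr).save(out_dir / f"{stem}.png")
    return root


def _demo5() -> list[TextureClassSpec]:
    return [
        TextureClassSpec(class_id="1.1", particle="disc", particle_size=5.0,
                         density=55.0, arrangement="solitary"),
        TextureClassSpec(class_id="1.2", particle="disc", particle_size=5.0,
                         density=55.0, arrangement="cluster", group_size=8.0),
        TextureClassSpec(class_id="2.1", particle="rod", particle_size=11.0,
                         size_jitter=1.0, density=35.0, arrangement="solitary"),
        TextureClassSpec(class_id="2.2", particle="rod", particle_size=11.0,
                         size_jitter=1.0, density=35.0, arrangement="chain",
                         group_size=4.0),
        TextureClassSpec(class_id="3.1", particle="curved-rod", particle_size=12.0,
                         size_jitter=1.0, density=35.0, arrangement="solitary"),
    ]


def _scale12() -> list[TextureClassSpec]:
    specs = []
    shapes = {"disc": 5.0, "rod": 11.0, "curved-rod": 12.0}
    for si, (shape, size) in enumerate(shapes.items(), start=1):
        for ai, arr in enumerate(ARRANGEMENTS, start=1):
            specs.append(TextureClassSpec(
                class_id=f"{si}.{ai}", particle=shape, particle_size=size,
                density=45.0 if shape == "disc" else 32.0, arrangement=arr,
                group_size=1.0 if arr == "solitary" else (4.0 if arr == "chain" else 7.0)))
    specs.append(TextureClassSpec(class_id="4.1", particle="disc", particle_size=8.0,
                                  density=25.0, arrangement="solitary"))
    specs.append(TextureClassSpec(class_id="4.2", particle="rod", particle_size=16.0,
                                  size_jitter=1.5, density=18.0, arrangement="solitary"))
    specs.append(TextureClassSpec(class_id="4.3", particle="disc", particle_size=3.5,
                                  density=110.0, arrangement="solitary"))
    return specs


#: frozen presets; parameters are part of the package's test conditions
PRESETS: dict[str, list[TextureClassSpec]] = {
    "demo5": _demo5(),
    "scale12": _scale12(),
}


def get_preset(name: str) -> list[TextureClassSpec]:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return [replace(s) for s in PRESETS[name]]
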