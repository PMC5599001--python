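"""Representation recipes: X-Y part tags composed into feature matrices.

A recipe is a " & "-separated list of part tags, each naming a pooling
encoder and a local descriptor: ``FV-SIFT`` (Fisher vector over dense
SIFT), ``FV-<backend>`` (Fisher vector over a backend's convolutional
descriptor field), ``FC-<backend>`` (the backend's global vector used
directly), and ``FCFV-<backend>`` as shorthand for FC-<backend>
concatenated with FV-<backend>.  Parts are L2-normalized independently,
concatenated, and the result L2-normalized globally.
"""

from __future__ import annotations

from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .deep import FeatureBackend, get_backend
from .dsift import extract_dsift
from .fisher import FisherVectorEncoder, concat_representations, fc_pool
from .io import LabeledImage


def parse_recipe(recipe: str) -> list[tuple[str, str]]:
    """Expand a recipe string into (pooling, descriptor) parts.

    >>> parse_recipe("FCFV-toy & FV-SIFT")
    [('FC', 'toy'), ('FV', 'toy'), ('FV', 'SIFT')]
    """
    parts: list[tuple[str, str]] = []
    for tag in [t.strip() for t in recipe.split("&")]:
        if not tag:
            raise ValueError(f"empty part in recipe {recipe!r}")
        pooling, _, desc = tag.partition("-")
        if not desc:
            raise ValueError(f"malformed part {tag!r}: expected '<pooling>-<descriptor>'")
        if pooling == "FCFV":
            parts += [("FC", desc), ("FV", desc)]
        elif pooling in ("FV", "FC"):
            if pooling == "FC" and desc == "SIFT":
                raise ValueError("FC pooling requires a deep backend, not SIFT")
            parts.append((pooling, desc))
        else:
            raise ValueError(f"unknown pooling {pooling!r} in part {tag!r}")
    return parts


class RepresentationBuilder(BaseEstimator, TransformerMixin):
    """Images -> feature matrix for a representation recipe.

    fit() extracts local descriptors from the training images and fits
    one Fisher-vector encoder (PCA + GMM) per FV part; transform()
    encodes images into rows.  Descriptor extraction is cached per image
    source across fit/transform (and across repeated splits when the
    same builder cache dict is shared).

    Parameters
    ----------
    recipe : part tags joined by " & " (see :func:`parse_recipe`).
    step, bin_size : dense-SIFT sampling step and spatial bin size.
    gmm_k : GMM components per FV part.
    pca_dim : PCA dimension for SIFT descriptors (None disables);
        deep descriptor fields skip PCA by default.
    subsample : cap on pooled training descriptors per FV part.
    fv_norm : Fisher-vector normalization mode.
    backend_seed : seed of the toy backend's filter bank.
    random_state : seed for descriptor subsampling and GMM EM.
    cache : optional dict shared across builders to reuse descriptor
        extraction keyed by (image source, part descriptor).
    """

    def __init__(self, recipe: str = "FV-SIFT", step: int = 2, bin_size: int = 8,
                 gmm_k: int = 64, pca_dim: int | None = 64, subsample: int = 100_000,
                 fv_norm: str = "ssr+l2", backend_seed: int = 0, random_state: int = 0,
                 cache: dict | None = None):
        self.recipe = recipe
        self.step = step
        self.bin_size = bin_size
        self.gmm_k = gmm_k
        self.pca_dim = pca_dim
        self.subsample = subsample
        self.fv_norm = fv_norm
        self.backend_seed = backend_seed
        self.random_state = random_state
        self.cache = cache

    # -- descriptor extraction ------------------------------------------
    def _backend(self, name: str) -> FeatureBackend:
        if not hasattr(self, "_backends"):
            self._backends = {}
        if name not in self._backends:
            self._backends[name] = get_backend(name, seed=self.backend_seed)
        return self._backends[name]

    def _local_descriptors(self, image: LabeledImage, desc: str):
        key = (image.source, desc, self.step, self.bin_size) \
            if image.source != "array" else None
        if self.cache is not None and key is not None and key in self.cache:
            return self.cache[key]
        if desc == "SIFT":
            out = extract_dsift(image, step=self.step, bin_size=self.bin_size)
        else:
            out = self._backend(desc).conv_field(image)
        if self.cache is not None and key is not None:
            self.cache[key] = out
        return out

    # -- estimator API --------------------------------------------------
    def fit(self, images, y=None):
        self.parts_ = parse_recipe(self.recipe)
        self.encoders_ = {}
        for pooling, desc in self.parts_:
            if pooling != "FV" or (pooling, desc) in self.encoders_:
                continue
            fields = [self._local_descriptors(img, desc) for img in images]
            enc = FisherVectorEncoder(
                n_components=self.gmm_k,
                pca_dim=self.pca_dim if desc == "SIFT" else None,
                subsample=self.subsample, normalization=self.fv_norm,
                random_state=self.random_state)
            self.encoders_[(pooling, desc)] = enc.fit(fields)
        self.output_dim_ = sum(
            self.encoders_[(p, d)].output_dim_ if p == "FV"
            else len(self._backend(d).fc_vector(images[0]))
            for p, d in self.parts_)
        return self

    def _encode_one(self, image: LabeledImage) -> np.ndarray:
        vectors = []
        for pooling, desc in self.parts_:
            if pooling == "FV":
                enc = self.encoders_[(pooling, desc)]
                field = self._local_descriptors(image, desc)
                vectors.append(enc.transform([field])[0])
            else:
                vectors.append(fc_pool(self._backend(desc).fc_vector(image),
                                       source_tag=f"FC-{desc}").values)
        if len(vectors) == 1:
            v = vectors[0]
            norm = np.linalg.norm(v)
            return v / norm if norm > 0 else v
        return concat_representations(vectors).values

    def transform(self, images) -> np.ndarray:
        out = np.empty((len(images), self.output_dim_))
        for i, img in enumerate(images):
            out[i] = self._encode_one(img)
        return out

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        cache, self.cache = self.cache, None  # never persist the cache
        try:
            joblib.dump({"format": "bactexture-encoder", "version": 1,
                         "builder": self}, Path(path))
        finally:
            self.cache = cache

    @classmethod
    def load(cls, path) -> "RepresentationBuilder":
        bundle = joblib.load(Path(path))
        if bundle.get("format") != "bactexture-encoder" or bundle.get("version") != 1:
            raise ValueError("unrecognized or mismatched encoder bundle version")
        return bundle["builder"]
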