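"""Fisher Vector pooling over a diagonal-covariance Gaussian mixture.

A GMM is fitted (EM, k-means initialization) to local descriptors pooled
from training images, optionally after a PCA projection.  Any descriptor
field is then encoded into a single 2*K*d vector holding, per mixture
component, the soft-assignment-weighted first-order (mean) and
second-order (variance) statistics:

    F1_k = 1/(N*sqrt(w_k))   * sum_i g_ik * (x_i - mu_k) / sigma_k
    F2_k = 1/(N*sqrt(2*w_k)) * sum_i g_ik * ((x_i - mu_k)^2 / sigma_k^2 - 1)

where g_ik is the posterior of component k for descriptor x_i.  The
default normalization is the improved-FV convention: signed square root
followed by global L2.  Zeroth-order (mixture-weight) statistics are
deliberately excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .dsift import DescriptorField

#: valid normalization modes for Fisher vectors
FV_NORMS = ("off", "ssr", "ssr+l2")
_DEGENERATE_WEIGHT = 1e-8


@dataclass
class PcaModel:
    """Mean and orthonormal basis of a principal-component projection."""

    mean: np.ndarray  # D
    basis: np.ndarray  # D x d, orthonormal columns
    retained_dim: int

    def project(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X) - self.mean) @ self.basis


@dataclass
class GmmModel:
    """Diagonal-covariance Gaussian mixture over descriptor space."""

    weights: np.ndarray  # K
    means: np.ndarray  # K x d
    variances: np.ndarray  # K x d
    log_likelihood_path: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.means = np.asarray(self.means, dtype=np.float64)
        self.variances = np.asarray(self.variances, dtype=np.float64)
        if abs(self.weights.sum() - 1.0) > 1e-8 or np.any(self.weights <= 0):
            raise ValueError("mixture weights must be positive and sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be strictly positive")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def save(self, path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), weights=self.weights, means=self.means,
                 variances=self.variances)
        path.with_suffix(".json").write_text(json.dumps(
            {"format": "bactexture-gmm", "version": 1,
             "n_components": int(self.n_components), "dim": int(self.dim)}))

    @classmethod
    def load(cls, path) -> "GmmModel":
        with np.load(Path(path).with_suffix(".npz")) as z:
            return cls(weights=z["weights"], means=z["means"], variances=z["variances"])


@dataclass
class FisherVector:
    """Pooled 2*K*d representation with its normalization state."""

    values: np.ndarray
    normalized: bool
    source_tag: str = "FV"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Fisher vector contains non-finite values")


def fit_pca(descriptors: np.ndarray, retained_dim: int) -> PcaModel:
    """Top-``retained_dim`` principal directions of mean-centered data.

    Sign convention: each basis column is flipped so its
    largest-magnitude component is positive (deterministic output).
    """
    X = np.asarray(descriptors, dtype=np.float64)
    n, d = X.shape
    if retained_dim > d:
        raise ValueError(f"retained_dim {retained_dim} exceeds descriptor dim {d}")
    if n <= retained_dim:
        raise ValueError("need more samples than retained dimensions")
    pca = PCA(n_components=retained_dim, svd_solver="full").fit(X)
    basis = pca.components_.T.copy()
    flip = np.sign(basis[np.argmax(np.abs(basis), axis=0), np.arange(retained_dim)])
    flip[flip == 0] = 1.0
    basis *= flip
    return PcaModel(mean=pca.mean_, basis=basis, retained_dim=retained_dim)


def _log_gaussians(gmm: GmmModel, X: np.ndarray) -> np.ndarray:
    """log(w_k) + log N(x | mu_k, diag(var_k)), shape N x K."""
    const = -0.5 * (gmm.dim * np.log(2 * np.pi) + np.sum(np.log(gmm.variances), axis=1))
    # (x - mu)^2 / var expanded to avoid an N x K x d intermediate
    x2 = (X ** 2) @ (1.0 / gmm.variances).T
    xm = X @ (gmm.means / gmm.variances).T
    m2 = np.sum(gmm.means ** 2 / gmm.variances, axis=1)
    mahal = x2 - 2 * xm + m2[None, :]
    return np.log(gmm.weights)[None, :] + const[None, :] - 0.5 * mahal


def _posteriors(gmm: GmmModel, X: np.ndarray) -> tuple[np.ndarray, float]:
    logp = _log_gaussians(gmm, X)
    norm = logsumexp(logp, axis=1, keepdims=True)
    return np.exp(logp - norm), float(norm.sum())


def soft_assign(gmm: GmmModel, descriptor: np.ndarray) -> np.ndarray:
    """Posterior component responsibilities for one descriptor (or N x d batch)."""
    X = np.atleast_2d(np.asarray(descriptor, dtype=np.float64))
    gamma, _ = _posteriors(gmm, X)
    return gamma[0] if np.asarray(descriptor).ndim == 1 else gamma


def fit_gmm(
    descriptors: np.ndarray,
    n_components: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    var_floor_frac: float = 1e-4,
) -> GmmModel:
    """EM fit of a diagonal-covariance GMM from a k-means initialization.

    The training log-likelihood is recorded per iteration (it is
    non-decreasing up to round-off) and stored on the returned model.
    Variances are floored at ``var_floor_frac`` times the per-dimension
    data variance; a component whose weight collapses below 1e-8 is
    re-seeded at a random data point once, after which collapse is an
    error.
    """
    X = np.asarray(descriptors, dtype=np.float64)
    n, d = X.shape
    if n < 10 * n_components:
        raise ValueError(f"need at least {10 * n_components} descriptors "
                         f"for K={n_components}, got {n}")
    floor = var_floor_frac * np.maximum(X.var(axis=0), 1e-12)
    km = KMeans(n_clusters=n_components, n_init=1, random_state=seed).fit(X)
    labels = km.labels_
    weights = np.array([max(np.mean(labels == k), 1.0 / n) for k in range(n_components)])
    weights /= weights.sum()
    means = km.cluster_centers_.copy()
    variances = np.empty((n_components, d))
    for k in range(n_components):
        pts = X[labels == k]
        variances[k] = pts.var(axis=0) if len(pts) > 1 else X.var(axis=0)
    variances = np.maximum(variances, floor)

    rng = np.random.default_rng(seed)
    reseeded = set()
    ll_path = []
    gmm = GmmModel(weights=weights, means=means, variances=variances)
    prev_ll = -np.inf
    for _ in range(max_iter):
        gamma, ll = _posteriors(gmm, X)
        ll_path.append(ll)
        nk = gamma.sum(axis=0)
        for k in np.where(nk / n < _DEGENERATE_WEIGHT)[0]:
            if k in reseeded:
                raise RuntimeError(f"GMM component {k} degenerated twice")
            reseeded.add(k)
            means[k] = X[rng.integers(n)]
            variances[k] = np.maximum(X.var(axis=0), floor)
            nk[k] = 1.0
        weights = np.maximum(nk / nk.sum(), _DEGENERATE_WEIGHT)
        weights /= weights.sum()
        means = (gamma.T @ X) / nk[:, None]
        ex2 = (gamma.T @ (X ** 2)) / nk[:, None]
        variances = np.maximum(ex2 - means ** 2, floor)
        gmm = GmmModel(weights=weights, means=means, variances=variances)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol * abs(prev_ll):
            break
        prev_ll = ll
    gmm.log_likelihood_path = np.asarray(ll_path)
    return gmm


def encode_fv(
    gmm: GmmModel,
    field: DescriptorField | np.ndarray,
    pca: PcaModel | None = None,
    normalization: str = "ssr+l2",
    posterior_floor: float = 1e-8,
    source_tag: str = "FV",
) -> FisherVector:
    """Pool a descriptor field into a single Fisher vector.

    Layout: first-order blocks for components 0..K-1, then second-order
    blocks, each block of length d.  ``posterior_floor`` hard-truncates
    tiny responsibilities for speed (set to 0 to disable).
    """
    X = field.descriptors if isinstance(field, DescriptorField) else np.asarray(field)
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] == 0:
        raise ValueError("empty descriptor field")
    if pca is not None:
        X = pca.project(X)
    if X.shape[1] != gmm.dim:
        raise ValueError(f"descriptor dim {X.shape[1]} != GMM dim {gmm.dim}")
    n = X.shape[0]
    gamma, _ = _posteriors(gmm, X)
    if posterior_floor > 0:
        gamma = np.where(gamma < posterior_floor, 0.0, gamma)
    sigma = np.sqrt(gmm.variances)  # K x d
    nk = gamma.sum(axis=0)  # K
    sx = gamma.T @ X  # K x d
    sx2 = gamma.T @ (X ** 2)  # K x d
    # sums of (x - mu)/sigma and ((x - mu)^2/var - 1) expressed via moments
    first = (sx - nk[:, None] * gmm.means) / sigma
    second = (sx2 - 2 * gmm.means * sx + nk[:, None] * gmm.means ** 2) / gmm.variances \
        - nk[:, None]
    first /= n * np.sqrt(gmm.weights)[:, None]
    second /= n * np.sqrt(2 * gmm.weights)[:, None]
    values = np.concatenate([first.ravel(), second.ravel()])
    return FisherVector(values=normalize_fv(values, normalization),
                        normalized=normalization != "off", source_tag=source_tag)


def normalize_fv(values: np.ndarray, mode: str = "ssr+l2") -> np.ndarray:
    """Apply the configured FV normalization (off, ssr, or ssr+l2)."""
    if mode not in FV_NORMS:
        raise ValueError(f"unknown normalization {mode!r}; choose from {FV_NORMS}")
    v = np.asarray(values, dtype=np.float64)
    if mode == "off":
        return v
    v = np.sign(v) * np.sqrt(np.abs(v))
    if mode == "ssr+l2":
        norm = np.linalg.norm(v)
        if norm > 0:
            v = v / norm
    return v


def fc_pool(vector: np.ndarray, source_tag: str = "FC") -> FisherVector:
    """Wrap a global (fully-connected-layer style) descriptor, L2-normalized."""
    v = np.asarray(vector, dtype=np.float64).ravel()
    norm = np.linalg.norm(v)
    if norm > 0:
        v = v / norm
    return FisherVector(values=v, normalized=True, source_tag=source_tag)


def concat_representations(parts: list[FisherVector | np.ndarray]) -> FisherVector:
    """L2-normalize each part, concatenate, then L2-normalize globally."""
    if not parts:
        raise ValueError("no representation parts to concatenate")
    blocks, tags = [], []
    for p in parts:
        v = p.values if isinstance(p, FisherVector) else np.asarray(p, dtype=np.float64)
        norm = np.linalg.norm(v)
        blocks.append(v / norm if norm > 0 else v)
        tags.append(p.source_tag if isinstance(p, FisherVector) else "raw")
    combined = np.concatenate(blocks)
    norm = np.linalg.norm(combined)
    if norm > 0:
        combined = combined / norm
    return FisherVector(values=combined, normalized=True, source_tag=" & ".join(tags))


class FisherVectorEncoder(BaseEstimator, TransformerMixin):
    """sklearn-style encoder: descriptor fields -> Fisher-vector matrix.

    fit() pools descriptors from the training fields (subsampled to at
    most ``subsample``), optionally fits a PCA, then the GMM; transform()
    encodes each field into one 2*K*d row.

    Parameters
    ----------
    n_components : GMM components K (default 64).
    pca_dim : retained PCA dimension, or None to skip projection.
    subsample : cap on pooled training descriptors (seeded draw).
    normalization : "off", "ssr" or "ssr+l2".
    random_state : seed for subsampling and EM initialization.
    """

    def __init__(self, n_components: int = 64, pca_dim: int | None = 64,
                 subsample: int = 100_000, normalization: str = "ssr+l2",
                 random_state: int = 0):
        self.n_components = n_components
        self.pca_dim = pca_dim
        self.subsample = subsample
        self.normalization = normalization
        self.random_state = random_state

    def _pool(self, fields) -> np.ndarray:
        mats = [f.descriptors if isinstance(f, DescriptorField) else np.asarray(f)
                for f in fields]
        X = np.concatenate(mats, axis=0)
        if len(X) > self.subsample:
            rng = np.random.default_rng(self.random_state)
            X = X[rng.choice(len(X), self.subsample, replace=False)]
        return X

    def fit(self, fields, y=None):
        X = self._pool(fields)
        if self.pca_dim is not None and self.pca_dim < X.shape[1]:
            self.pca_ = fit_pca(X, self.pca_dim)
            X = self.pca_.project(X)
        else:
            self.pca_ = None
        self.gmm_ = fit_gmm(X, self.n_components, seed=self.random_state)
        self.output_dim_ = 2 * self.gmm_.n_components * self.gmm_.dim
        return self

    def transform(self, fields) -> np.ndarray:
        out = np.empty((len(fields), self.output_dim_))
        for i, f in enumerate(fields):
            out[i] = encode_fv(self.gmm_, f, pca=self.pca_,
                               normalization=self.normalization).values
        return out
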