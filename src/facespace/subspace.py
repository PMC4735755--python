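"""Eigenface PCA preprocessing and Linear Fisher Discriminant subspaces.

Pipeline: vectorize images row-major -> subtract the global mean face ->
PCA to ``k`` components ("Eigenfaces") -> multi-class Fisher analysis in
PCA coordinates ("Fisherfaces"): between-class scatter S_B (class means
weighted by class size) against pooled within-class scatter S_W, solved
as the symmetric-definite generalized eigenproblem S_B v = lambda S_W v.

Conventions
-----------
* The number of discriminants is capped at C - 1 for C classes (and at k).
* Eigenvectors keep the generalized-eigenvector normalization
  v' S_W v = 1: the Fisher projection whitens within-class scatter, so
  Euclidean distance in the projected space measures separation in
  within-class noise units.  This is the property that lets a subspace
  trained on one labeling suppress the structure of another.
* Random orthogonal padding draws extra directions that are orthonormal
  in the same S_W metric (the stacked map W satisfies W S_W W' = I), so
  padded axes carry within-class scale ~1, commensurate with the
  discriminant axes.
* S_W is ridge-regularized (relative ridge, default 1e-8 * tr(S_W)/k)
  because pooled scatter is singular whenever samples-per-class are few.
* Eigenvector signs are fixed (largest-magnitude entry positive) for
  reproducibility.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg

from .faces import LabeledFaceSet

__all__ = [
    "EigenModel",
    "FisherModel",
    "ProjectedSet",
    "vectorize_and_center",
    "fit_pca",
    "project_pca",
    "fit_lfd",
    "pad_orthogonal",
    "project_fisher",
]


def _fix_signs(rows: np.ndarray) -> np.ndarray:
    """Flip each row so its largest-magnitude entry is positive."""
    rows = rows.copy()
    for i in range(rows.shape[0]):
        j = np.argmax(np.abs(rows[i]))
        if rows[i, j] < 0:
            rows[i] *= -1.0
    return rows


@dataclass(frozen=True)
class EigenModel:
    """Mean face plus orthonormal principal components ("Eigenfaces")."""

    mean_face: np.ndarray       # (n_pixels,)
    components: np.ndarray      # (k, n_pixels), orthonormal rows
    eigenvalues: np.ndarray     # (k,), non-increasing
    image_shape: tuple[int, int]

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


@dataclass(frozen=True)
class FisherModel:
    """Discriminant directions in PCA coordinate space ("Fisherfaces").

    ``directions`` are generalized eigenvectors of (S_B, S_W) with
    v' S_W v = 1; ``padding`` holds optional random directions that are
    S_W-orthonormal to the discriminants and to each other.
    """

    directions: np.ndarray          # (m, k)
    eigenvalues: np.ndarray         # (m,) generalized eigenvalues, non-increasing
    trained_property: str
    class_labels: tuple
    ridge: float
    s_w: np.ndarray = field(repr=False)  # (k, k) regularized within-class scatter
    padding: np.ndarray | None = None    # (p, k)

    def __post_init__(self):
        if self.padding is None:
            object.__setattr__(
                self, "padding", np.zeros((0, self.directions.shape[1]))
            )

    @property
    def n_discriminants(self) -> int:
        return self.directions.shape[0]

    @property
    def n_padded(self) -> int:
        return self.padding.shape[0]

    @property
    def total_dim(self) -> int:
        return self.n_discriminants + self.n_padded

    @property
    def pca_dim(self) -> int:
        return self.directions.shape[1]

    def all_directions(self) -> np.ndarray:
        return np.vstack([self.directions, self.padding])

    def gram_sw(self) -> np.ndarray:
        """Gram matrix of all directions in the S_W metric (identity when
        the model is well formed)."""
        w = self.all_directions()
        return w @ self.s_w @ w.T


@dataclass
class ProjectedSet:
    """Sample coordinates in a (possibly padded) Fisher subspace together
    with the labeling under evaluation."""

    coordinates: np.ndarray     # (n, m + p)
    eval_labels: np.ndarray     # (n,)
    source_property: str

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.eval_labels = np.asarray(self.eval_labels)
        if self.coordinates.ndim != 2:
            raise ValueError("coordinates must be 2-D")
        if len(self.eval_labels) != self.coordinates.shape[0]:
            raise ValueError("eval_labels length != number of samples")

    @property
    def n_samples(self) -> int:
        return self.coordinates.shape[0]


# ---------------------------------------------------------------------------


def vectorize_and_center(faceset: LabeledFaceSet) -> tuple[np.ndarray, np.ndarray]:
    """Row-major concatenation of each image into a vector, minus the
    global mean face.  Returns ``(centered_matrix, mean_face)``."""
    if faceset.n_samples == 0:
        raise ValueError("faceset is empty")
    imgs = faceset.images
    x = imgs.reshape(imgs.shape[0], -1)  # row-major (C order)
    mean = x.mean(axis=0)
    return x - mean, mean


def fit_pca(faceset: LabeledFaceSet, n_components: int) -> EigenModel:
    """Top ``n_components`` eigenvectors of the sample covariance of the
    centered image vectors, via thin SVD.

    Raises
    ------
    ValueError
        if ``n_components`` exceeds ``n_samples - 1`` (the centered data
        matrix has at most that rank); consistent with the sweep omission
        rule.
    """
    n = faceset.n_samples
    if not 1 <= n_components <= n - 1:
        raise ValueError(
            f"n_components={n_components} must be in [1, n_samples-1={n - 1}]"
        )
    x, mean = vectorize_and_center(faceset)
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    eigvals = (s ** 2) / (n - 1)
    components = _fix_signs(vt[:n_components])
    return EigenModel(
        mean_face=mean,
        components=components,
        eigenvalues=eigvals[:n_components],
        image_shape=faceset.image_shape,
    )


def project_pca(model: EigenModel, faceset: LabeledFaceSet) -> np.ndarray:
    """Coordinates of each (centered) image on the Eigenface axes."""
    if faceset.image_shape != model.image_shape:
        raise ValueError(
            f"resolution {faceset.image_shape} does not match model "
            f"{model.image_shape}"
        )
    x = faceset.images.reshape(faceset.n_samples, -1)
    return (x - model.mean_face) @ model.components.T


def scatter_matrices(
    coords: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Between-class scatter (class means weighted by class size) and
    pooled within-class scatter, both (k, k)."""
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    k = coords.shape[1]
    classes, counts = np.unique(labels, return_counts=True)
    grand_mean = coords.mean(axis=0)
    s_b = np.zeros((k, k))
    s_w = np.zeros((k, k))
    for cls, n_c in zip(classes, counts):
        xc = coords[labels == cls]
        mu_c = xc.mean(axis=0)
        d = mu_c - grand_mean
        s_b += n_c * np.outer(d, d)
        r = xc - mu_c
        s_w += r.T @ r
    return s_b, s_w


def fit_lfd(
    coords: np.ndarray,
    labels: np.ndarray,
    n_directions: int | None = None,
    ridge_rel: float = 1e-8,
    trained_property: str = "unknown",
) -> FisherModel:
    """Fit the multi-class Linear Fisher Discriminant in PCA coordinates.

    Solves S_B v = lambda (S_W + ridge I) v and keeps the top
    ``min(n_directions, C - 1, k)`` generalized eigenvectors, normalized
    to v' S_W v = 1.

    Raises
    ------
    ValueError
        fewer than 2 classes, or any class with fewer than 2 samples.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    if coords.ndim != 2 or coords.shape[1] < 1:
        raise ValueError("coords must be a (n, k) matrix with k >= 1")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training requires at least 2 distinct class labels")
    small = [str(c) for c, n_c in zip(classes, counts) if n_c < 2]
    if small:
        raise ValueError(f"classes with < 2 samples: {small}")
    k = coords.shape[1]
    s_b, s_w = scatter_matrices(coords, labels)
    ridge = ridge_rel * np.trace(s_w) / k
    s_w_reg = s_w + ridge * np.eye(k)
    # symmetric-definite pencil: eigh returns V with V' S_W V = I
    w, v = scipy.linalg.eigh(s_b, s_w_reg)
    order = np.argsort(w)[::-1]
    m = min(len(classes) - 1, k)
    if n_directions is not None:
        m = min(m, int(n_directions))
    directions = _fix_signs(v[:, order[:m]].T)
    return FisherModel(
        directions=directions,
        eigenvalues=np.asarray(w)[order[:m]],
        trained_property=trained_property,
        class_labels=tuple(classes.tolist()),
        ridge=float(ridge),
        s_w=s_w_reg,
    )


def pad_orthogonal(model: FisherModel, target_dim: int, seed: int) -> FisherModel:
    """Pad the discriminant subspace with random directions up to
    ``target_dim``, orthonormal (in the S_W metric) to the existing
    directions and to each other.  ``target_dim == n_discriminants``
    returns the model unchanged (no padding added)."""
    k = model.pca_dim
    m = model.n_discriminants
    if target_dim > k:
        raise ValueError(f"target_dim={target_dim} exceeds PCA dimension {k}")
    if target_dim < m:
        raise ValueError(
            f"target_dim={target_dim} smaller than n_discriminants={m}"
        )
    p = target_dim - m
    if p == 0:
        return replace(model, padding=np.zeros((0, k)))
    # work in the S_W-whitened space where the metric is Euclidean
    evals, q = np.linalg.eigh(model.s_w)
    evals = np.clip(evals, np.finfo(float).tiny, None)
    sqrt_sw = (q * np.sqrt(evals)) @ q.T
    inv_sqrt_sw = (q / np.sqrt(evals)) @ q.T
    u_exist = sqrt_sw @ model.directions.T          # (k, m), orthonormal cols
    rng = np.random.default_rng(seed)
    r = rng.standard_normal((k, p))
    r -= u_exist @ (u_exist.T @ r)
    qb, _ = np.linalg.qr(r)
    padding = _fix_signs((inv_sqrt_sw @ qb[:, :p]).T)
    return replace(model, padding=padding)


def project_fisher(
    model: FisherModel,
    coords: np.ndarray,
    eval_labels: np.ndarray | None = None,
) -> ProjectedSet:
    """Project PCA coordinates into the (padded) Fisher subspace."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != model.pca_dim:
        raise ValueError(
            f"coords dimension {coords.shape} does not match model PCA "
            f"dimension {model.pca_dim}"
        )
    if eval_labels is None:
        eval_labels = np.full(coords.shape[0], "", dtype=object)
    return ProjectedSet(
        coordinates=coords @ model.all_directions().T,
        eval_labels=eval_labels,
        source_property=model.trained_property,
    )
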