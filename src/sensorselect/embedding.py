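"""Global and per-class principal-component embeddings.

The pipeline inspects each surviving sensor subset in the plane of the top
two principal components of the mean-centered response matrix (or on PC1
alone when it dominates).  Within every analyte class a *local* PCA of the
class scores yields the principal axes and variances of that class's
scatter — the frame in which the finite-sample variance inflation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import ClassLabeling, PipelineConfig, ResponseTable

__all__ = [
    "Embedding",
    "LocalClassFrame",
    "global_pca",
    "class_local_pca",
    "choose_dimension",
    "restrict_dimension",
]


@dataclass(frozen=True)
class Embedding:
    """Top-``d`` principal-component embedding (``d`` is 1 or 2).

    ``loadings`` is ``p x d`` with orthonormal columns, ``scores`` is
    ``n x d`` (centered data projected on the loadings), and ``ev_ratio``
    holds the explained-variance fraction of each retained component.
    """

    loadings: np.ndarray
    scores: np.ndarray
    ev_ratio: np.ndarray
    dimension: int

    def __post_init__(self) -> None:
        if self.dimension not in (1, 2):
            raise ValueError("embedding dimension must be 1 or 2")


@dataclass(frozen=True)
class LocalClassFrame:
    """Principal axes of one class's scatter in the embedding plane.

    ``rotation`` is ``d x d`` orthonormal with axes as columns;
    ``axis_variances`` are the unbiased sample variances along those axes
    (the eigenvalues of the class covariance); ``mean`` is the class
    centroid in global PC coordinates.
    """

    class_index: int
    rotation: np.ndarray
    axis_variances: np.ndarray
    mean: np.ndarray
    n_k: int


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # deterministic orientation: largest-|entry| loading of each component positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    return loadings, scores


def global_pca(table: ResponseTable) -> Embedding:
    """PCA of the (already mean-centered) response matrix, top 2 components.

    Returns 1 component when only one sensor survives.  Raises on rank-0
    data (all samples identical), where no direction of variation exists.
    """
    X = table.values - table.values.mean(axis=0, keepdims=True)
    n, p = X.shape
    total_var = np.sum(X**2) / (n - 1)
    if total_var <= 0:
        raise ValueError("rank-0 data: all samples are identical")
    d = min(2, p)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    loadings = Vt[:d].T.copy()
    scores = X @ loadings
    loadings, scores = _fix_signs(loadings, scores)
    ev_ratio = (s[:d] ** 2 / (n - 1)) / total_var
    return Embedding(loadings, scores, ev_ratio, d)


def class_local_pca(embedding: Embedding, labeling: ClassLabeling) -> list[LocalClassFrame]:
    """Per-class PCA of the embedding scores.

    Each class's scores are centered on the class mean and eigendecomposed;
    axis variances are the eigenvalues of the unbiased ``d x d`` class
    covariance, in decreasing order.  A fully degenerate class (all points
    identical) gets zero variances and the identity rotation.
    """
    d = embedding.dimension
    frames: list[LocalClassFrame] = []
    for k in range(labeling.K):
        pts = embedding.scores[labeling.labels == k]
        n_k = pts.shape[0]
        mean = pts.mean(axis=0)
        centered = pts - mean
        cov = centered.T @ centered / (n_k - 1)
        cov = np.atleast_2d(cov)
        if np.allclose(cov, 0):
            rotation = np.eye(d)
            variances = np.zeros(d)
        else:
            eigvals, eigvecs = np.linalg.eigh(cov)
            order = np.argsort(eigvals)[::-1]
            variances = np.clip(eigvals[order], 0.0, None)
            rotation = eigvecs[:, order]
            for j in range(d):  # same sign convention as the global PCA
                i = int(np.argmax(np.abs(rotation[:, j])))
                if rotation[i, j] < 0:
                    rotation[:, j] *= -1.0
        frames.append(LocalClassFrame(k, rotation, variances, np.atleast_1d(mean), n_k))
    return frames


def restrict_dimension(embedding: Embedding, d: int) -> Embedding:
    """Keep only the leading ``d`` components of an embedding."""
    if d > embedding.dimension:
        raise ValueError("cannot expand an embedding")
    if d == embedding.dimension:
        return embedding
    return Embedding(
        embedding.loadings[:, :d].copy(),
        embedding.scores[:, :d].copy(),
        embedding.ev_ratio[:d].copy(),
        d,
    )


def choose_dimension(embedding: Embedding, config: PipelineConfig) -> int:
    """Decide between the 2D plane and the PC1-only line.

    Returns 1 when a single component exists, or when the
    explained-variance flag is active and PC1 alone explains strictly more
    than ``ev_threshold`` of the variance; otherwise 2.
    """
    if embedding.dimension == 1:
        return 1
    if config.ev_flag and embedding.ev_ratio[0] > config.ev_threshold:
        return 1
    return 2
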