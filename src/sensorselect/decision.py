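"""QDA and Voronoi decision models in the embedding space.

QDA assigns a point to the class maximising the Gaussian discriminant

    g_k(x) = −½ log|Σ_k| − ½ (x−μ_k)ᵀ Σ_k⁻¹ (x−μ_k) + log π_k,

which gives curved boundaries when class covariances differ.  The Voronoi
alternative assigns the nearest class centroid (Euclidean), i.e. the
equal-isotropic-covariance special case of QDA.  A raster of the decision
regions over the populated part of the plane is available for export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .covariance import ClassGaussian

__all__ = ["DecisionModel", "RegionGrid", "fit_decision_model", "classify_points", "region_grid"]


@dataclass(frozen=True)
class DecisionModel:
    """A fitted partition of the 1D/2D embedding into class regions."""

    kind: str  # "qda" | "voronoi"
    means: np.ndarray  # K x d
    covariances: np.ndarray | None  # K x d x d (QDA only)
    priors: np.ndarray  # K, sums to 1
    dimension: int

    @property
    def n_classes(self) -> int:
        return self.means.shape[0]


@dataclass(frozen=True)
class RegionGrid:
    """Class assignment on a regular grid covering the class Gaussians."""

    axes: tuple[np.ndarray, ...]  # cell-center coordinates per axis
    assignment: np.ndarray  # resolution^d array of class indices


def fit_decision_model(
    gaussians: list[ClassGaussian],
    kind: str = "qda",
    priors: np.ndarray | None = None,
) -> DecisionModel:
    """Fit a QDA or nearest-centroid (Voronoi) model from class Gaussians.

    Priors default to uniform; screening designs use balanced replicates.
    """
    if kind not in ("qda", "voronoi"):
        raise ValueError(f"unknown decision model kind {kind!r}")
    K = len(gaussians)
    if K < 2:
        raise ValueError("need at least 2 classes")
    d = gaussians[0].dimension
    means = np.stack([g.mean for g in gaussians])
    if priors is None:
        priors = np.full(K, 1.0 / K)
    priors = np.asarray(priors, dtype=float)
    if priors.shape != (K,) or not np.isclose(priors.sum(), 1.0):
        raise ValueError("priors must be a length-K vector summing to 1")
    covs = None
    if kind == "qda":
        covs = np.stack([np.atleast_2d(g.covariance) for g in gaussians])
        for k in range(K):
            sign, _ = np.linalg.slogdet(covs[k])
            assert sign > 0, "QDA covariance must be positive definite (apply conditioning first)"
    return DecisionModel(kind, means, covs, priors, d)


def _qda_discriminants(model: DecisionModel, points: np.ndarray) -> np.ndarray:
    """n x K matrix of Gaussian discriminant values."""
    n = points.shape[0]
    K = model.n_classes
    g = np.empty((n, K))
    for k in range(K):
        cov = model.covariances[k]
        diff = points - model.means[k]
        _, logdet = np.linalg.slogdet(cov)
        sol = np.linalg.solve(cov, diff.T).T
        maha = np.einsum("ij,ij->i", diff, sol)
        g[:, k] = -0.5 * logdet - 0.5 * maha + np.log(model.priors[k])
    return g


def classify_points(model: DecisionModel, points: np.ndarray) -> np.ndarray:
    """Assign each point to a class; ties go to the lowest class index."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[1] != model.dimension:
        raise ValueError(
            f"points have dimension {points.shape[1]}, model expects {model.dimension}"
        )
    if model.kind == "qda":
        return np.argmax(_qda_discriminants(model, points), axis=1)
    d2 = ((points[:, None, :] - model.means[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def region_grid(
    model: DecisionModel,
    gaussians: list[ClassGaussian],
    resolution: int = 400,
    margin_sigmas: float = 4.0,
) -> RegionGrid:
    """Rasterise the decision regions.

    The grid spans the union over classes of mean ± ``margin_sigmas``
    standard deviations along each axis (covering >99.9% of every class
    mass), with ``resolution`` cells per axis, each labelled at its center.
    """
    if resolution < 50:
        raise ValueError("resolution must be at least 50 cells per axis")
    d = model.dimension
    lo = np.full(d, np.inf)
    hi = np.full(d, -np.inf)
    for g in gaussians:
        sd = np.sqrt(np.diag(np.atleast_2d(g.covariance)))
        lo = np.minimum(lo, g.mean - margin_sigmas * sd)
        hi = np.maximum(hi, g.mean + margin_sigmas * sd)
    axes = tuple(np.linspace(lo[i], hi[i], resolution) for i in range(d))
    if d == 1:
        pts = axes[0][:, None]
        assignment = classify_points(model, pts)
    else:
        xx, yy = np.meshgrid(axes[0], axes[1], indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        assignment = classify_points(model, pts).reshape(resolution, resolution)
    return RegionGrid(axes, assignment)
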