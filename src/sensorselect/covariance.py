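"""Finite-sample class-covariance modelling.

With 3–5 replicates per analyte, the plug-in class mean and covariance
understate how variable a *new* measurement will be.  Three corrections are
applied, in order:

1. **Predictive inflation** — along each local principal axis the sample
   variance ``s²`` is scaled by ``(1 + 1/n_k) (n_k − 1)/(n_k − 2)``, the
   posterior-predictive variance of a new draw when both the mean and the
   variance of the class are unknown.  The diagonal inflated covariance is
   rotated back to global PC coordinates, so the class ellipse grows along
   its own principal directions without changing orientation.
2. **Shrinkage** — each class covariance is blended toward the pooled
   (degree-of-freedom-weighted) covariance with a Ledoit–Wolf-style
   intensity, stabilising the off-diagonal terms that small samples
   estimate worst.
3. **Eigenvalue conditioning** — eigenvalues are floored at a small,
   scale-aware value so every covariance stays positive definite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .core_data import ClassLabeling
from .embedding import LocalClassFrame

__all__ = [
    "ClassGaussian",
    "EllipseSpec",
    "inflation_factor",
    "predictive_inflate",
    "inflate_class",
    "shrink_and_condition",
    "confidence_ellipse",
]


@dataclass(frozen=True)
class ClassGaussian:
    """One analyte class as a Gaussian in the embedding space."""

    class_index: int
    mean: np.ndarray
    covariance: np.ndarray
    raw_variances: np.ndarray
    n_k: int

    @property
    def dimension(self) -> int:
        return self.mean.shape[0]


@dataclass(frozen=True)
class EllipseSpec:
    """Parameters of a coverage ellipse in the PC plane."""

    center: np.ndarray
    semi_axes: np.ndarray  # (major, minor)
    angle: float  # radians, major axis vs PC1
    level: float


def inflation_factor(n_k: int) -> float:
    """Variance inflation for a predictive draw from ``n_k`` replicates.

    ``(1 + 1/n_k)`` accounts for the unknown mean; ``(n_k − 1)/(n_k − 2)``
    for the unknown variance (finite only for ``n_k > 2``).  With exactly
    two replicates only the mean term is applied; the shrinkage and
    eigenvalue floor downstream absorb the remaining variance uncertainty.
    """
    if n_k < 2:
        raise ValueError(f"need at least 2 replicates, got {n_k}")
    if n_k == 2:
        return 1.0 + 1.0 / n_k
    return (1.0 + 1.0 / n_k) * (n_k - 1.0) / (n_k - 2.0)


def predictive_inflate(s2: float, n_k: int) -> float:
    """Inflate a sample variance ``s2`` along one local axis."""
    if s2 < 0:
        raise ValueError("variance must be non-negative")
    return float(s2) * inflation_factor(n_k)


def inflate_class(frame: LocalClassFrame, adjusted: bool = True) -> ClassGaussian:
    """Build the class Gaussian from its local frame.

    The covariance is ``R diag(σ̃²) Rᵀ`` with ``σ̃²`` the per-axis inflated
    variances; when ``adjusted`` is False the raw sample variances are used
    and the covariance equals the class scatter.
    """
    if adjusted:
        variances = np.array([predictive_inflate(s2, frame.n_k) for s2 in frame.axis_variances])
    else:
        variances = np.asarray(frame.axis_variances, dtype=float)
    R = frame.rotation
    cov = R @ np.diag(variances) @ R.T
    cov = 0.5 * (cov + cov.T)
    return ClassGaussian(
        frame.class_index, np.asarray(frame.mean, dtype=float), cov,
        np.asarray(frame.axis_variances, dtype=float), frame.n_k,
    )


def _lw_intensity(cov: np.ndarray, target: np.ndarray, n_k: int) -> float:
    # Ledoit-Wolf-style: estimated sampling variance of the covariance entries
    # over the squared distance to the target, clipped to [0, 1].
    diff2 = float(np.sum((cov - target) ** 2))
    if diff2 <= 1e-300:
        return 0.0
    v = np.diag(cov)
    beta2 = float(np.sum(np.outer(v, v) + cov**2)) / n_k
    return float(np.clip(beta2 / diff2, 0.0, 1.0))


def shrink_and_condition(
    gaussians: list[ClassGaussian],
    labeling: ClassLabeling,
    floor_rel: float = 1e-6,
    floor_abs: float = 1e-12,
) -> list[ClassGaussian]:
    """Shrink each class covariance toward the pooled target and floor it.

    The pooled covariance weights classes by their ``n_k − 1`` degrees of
    freedom.  Each class is replaced by ``(1−λ_k) Σ_k + λ_k Σ_pooled`` with a
    per-class Ledoit–Wolf-style intensity ``λ_k``, then eigenvalues are
    clipped from below at ``max(floor_rel · λ_max(Σ_pooled), floor_abs)``.
    Output covariances are symmetric positive definite.
    """
    if len(gaussians) < 2:
        raise ValueError("need at least 2 classes to pool")
    counts = labeling.counts
    dof = np.array([counts[g.class_index] - 1 for g in gaussians], dtype=float)
    pooled = sum(w * g.covariance for w, g in zip(dof, gaussians)) / dof.sum()
    pooled_eigs = np.linalg.eigvalsh(pooled)
    floor = max(floor_rel * float(pooled_eigs.max()), floor_abs)
    out = []
    for g in gaussians:
        lam = _lw_intensity(g.covariance, pooled, g.n_k)
        cov = (1.0 - lam) * g.covariance + lam * pooled
        cov = 0.5 * (cov + cov.T)
        eigvals, eigvecs = np.linalg.eigh(cov)
        eigvals = np.clip(eigvals, floor, None)
        cov = eigvecs @ np.diag(eigvals) @ eigvecs.T
        out.append(replace(g, covariance=0.5 * (cov + cov.T)))
    return out


def confidence_ellipse(g: ClassGaussian, level: float = 0.95) -> EllipseSpec:
    """Coverage ellipse of a 2D class Gaussian.

    Semi-axes are ``sqrt(q λ_i)`` with ``q`` the chi-squared(2 dof)
    quantile at ``level`` and ``λ_i`` the covariance eigenvalues; the angle
    is that of the leading eigenvector.
    """
    if g.dimension != 2:
        raise ValueError("confidence ellipses are defined for 2D Gaussians")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    eigvals, eigvecs = np.linalg.eigh(g.covariance)
    if eigvals.min() <= 0:
        raise ValueError("covariance must be positive definite")
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    q = stats.chi2.ppf(level, df=2)
    angle = float(np.arctan2(eigvecs[1, 0], eigvecs[0, 0]))
    return EllipseSpec(g.mean.copy(), np.sqrt(q * eigvals), angle, level)
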