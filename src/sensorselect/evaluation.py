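"""Per-iteration performance metrics.

No hold-out set exists in the screening regime, so classification error is
estimated parametrically: Monte-Carlo samples are drawn from each class's
(inflated, regularised) Gaussian and the fraction landing outside the
class's own decision region is that class's error.  Alongside the mean
error, each iteration records the adjusted Rand index of the classifier on
the measured samples and the mean pairwise distance between class
centroids in the embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .covariance import ClassGaussian
from .decision import DecisionModel, classify_points

__all__ = [
    "PerformanceRecord",
    "estimate_class_error",
    "mean_error",
    "adjusted_rand_index",
    "mean_separation",
]


@dataclass(frozen=True)
class PerformanceRecord:
    """Metrics of one elimination iteration (``n_sensors`` survivors)."""

    n_sensors: int
    per_class_error: tuple[float, ...]  # fractions in [0, 1]
    mean_error: float  # percent
    ari: float
    mean_separation: float
    ev_ratio: tuple[float, ...]
    dimension: int


def estimate_class_error(
    g: ClassGaussian,
    model: DecisionModel,
    mc_samples: int = 100_000,
    seed: int | np.random.SeedSequence = 0,
) -> float:
    """Monte-Carlo misclassification probability of one class.

    Draws ``mc_samples`` points from the class Gaussian, classifies them
    with the decision model, and returns the fraction assigned to any
    other class.  Reproducible for a given seed.
    """
    if mc_samples < 1_000:
        raise ValueError("mc_samples must be at least 1000")
    rng = np.random.default_rng(seed)
    if g.dimension == 1:
        draws = rng.normal(g.mean[0], np.sqrt(g.covariance[0, 0]), size=(mc_samples, 1))
    else:
        draws = rng.multivariate_normal(g.mean, g.covariance, size=mc_samples)
    predicted = classify_points(model, draws)
    return float(np.mean(predicted != g.class_index))


def mean_error(per_class: list[float] | tuple[float, ...]) -> float:
    """Unweighted mean of per-class error fractions, in percent."""
    per_class = np.asarray(per_class, dtype=float)
    if per_class.size == 0:
        raise ValueError("per-class error list is empty")
    return float(100.0 * per_class.mean())


def adjusted_rand_index(true_labels: np.ndarray, predicted_labels: np.ndarray) -> float:
    """Chance-corrected agreement between two labelings of the same samples."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label vectors must have equal length")
    if true_labels.size < 2:
        raise ValueError("need at least 2 samples")
    return float(adjusted_rand_score(true_labels, predicted_labels))


def mean_separation(gaussians: list[ClassGaussian]) -> float:
    """Mean Euclidean distance between class centroids over all pairs."""
    if len(gaussians) < 2:
        raise ValueError("need at least 2 classes")
    means = np.stack([g.mean for g in gaussians])
    dists = [
        float(np.linalg.norm(means[i] - means[j]))
        for i in range(len(means))
        for j in range(i + 1, len(means))
    ]
    return float(np.mean(dists))
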