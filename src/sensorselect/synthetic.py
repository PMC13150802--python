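"""Synthetic Gaussian screening datasets.

Emulates the screening regime the pipeline is built for: K = 3–6 analyte
classes, p = 10–30 sensors, 3–5 replicates per class, each class a
Gaussian in sensor space with partial overlap between classes.  Also
provides the variance-inflation stress protocol (resampling each class
with its covariance scaled by the square of a chosen factor, means
unchanged) and a planted-recovery fixture with a known informative sensor
subset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core_data import ClassLabeling, ResponseTable

__all__ = [
    "SyntheticSpec",
    "generate_dataset",
    "inflate_stress_dataset",
    "planted_recovery_spec",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Per-class Gaussian description of a synthetic screening experiment.

    ``means`` is ``K x p`` (class means per sensor); ``covariances`` is
    ``K x p x p`` (or ``K x p`` diagonals, expanded on validation);
    ``informative`` lists the sensors whose means differ across classes.
    """

    means: np.ndarray
    covariances: np.ndarray
    n_k: tuple[int, ...]
    class_names: tuple[str, ...] = ()
    sensor_ids: tuple[str, ...] = ()
    informative: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        means = np.atleast_2d(np.asarray(self.means, dtype=float))
        covs = np.asarray(self.covariances, dtype=float)
        K, p = means.shape
        if covs.shape == (K, p):  # diagonal shorthand
            covs = np.stack([np.diag(c) for c in covs])
        if covs.shape != (K, p, p):
            raise ValueError(f"covariances must be K x p x p, got {covs.shape}")
        eigs = np.linalg.eigvalsh(covs)
        if np.any(eigs < -1e-10):
            raise ValueError("class covariances must be positive semi-definite")
        n_k = tuple(int(n) for n in self.n_k)
        if len(n_k) != K or any(n < 2 for n in n_k):
            raise ValueError("need one replicate count >= 2 per class")
        class_names = self.class_names or tuple(f"class{k+1}" for k in range(K))
        sensor_ids = self.sensor_ids or tuple(f"S{j+1}" for j in range(p))
        if len(class_names) != K or len(sensor_ids) != p:
            raise ValueError("class_names/sensor_ids lengths inconsistent with means")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "covariances", covs)
        object.__setattr__(self, "n_k", n_k)
        object.__setattr__(self, "class_names", tuple(class_names))
        object.__setattr__(self, "sensor_ids", tuple(sensor_ids))
        object.__setattr__(self, "informative", tuple(self.informative))

    @property
    def K(self) -> int:
        return self.means.shape[0]

    @property
    def p(self) -> int:
        return self.means.shape[1]


def generate_dataset(spec: SyntheticSpec) -> tuple[ResponseTable, ClassLabeling]:
    """Draw replicate samples class-by-class from the spec's Gaussians."""
    rng = np.random.default_rng(spec.seed)
    rows, labels, sample_ids = [], [], []
    for k in range(spec.K):
        draws = rng.multivariate_normal(
            spec.means[k], spec.covariances[k], size=spec.n_k[k], method="svd"
        )
        rows.append(draws)
        labels.extend([k] * spec.n_k[k])
        sample_ids.extend(f"{spec.class_names[k]}_r{i+1}" for i in range(spec.n_k[k]))
    table = ResponseTable(np.vstack(rows), spec.sensor_ids, tuple(sample_ids))
    labeling = ClassLabeling(np.array(labels), spec.class_names)
    return table, labeling


def inflate_stress_dataset(
    baseline: SyntheticSpec,
    factor: float,
    samples_per_class: int = 50,
    seed: int = 0,
) -> tuple[ResponseTable, ClassLabeling]:
    """Resample a baseline with standard deviations scaled by ``factor``.

    Means are unchanged and every class covariance is multiplied by
    ``factor**2``; 50 replicates per class by default.  Factors 1 (control),
    2, 5, and 10 make up the standard stress sweep.
    """
    if factor < 1:
        raise ValueError("inflation factor must be >= 1")
    stressed = replace(
        baseline,
        covariances=baseline.covariances * factor**2,
        n_k=tuple(samples_per_class for _ in baseline.n_k),
        seed=seed,
    )
    return generate_dataset(stressed)


def planted_recovery_spec(
    K: int = 5,
    p: int = 10,
    n_informative: int = 2,
    separation: float = 5.0,
    noise_variance: float = 1.0,
    n_k: int = 5,
    seed: int = 0,
) -> SyntheticSpec:
    """A spec with a known informative sensor pair planted among noise.

    The ``n_informative`` leading sensors carry class-dependent means —
    classes sit on a circle (or line, if only one informative sensor) with
    nearest-neighbour distance ``separation`` — while the remaining
    sensors respond identically to every class (pure noise, variance
    ``noise_variance``).  Recovering the planted sensors as the last
    survivors of the elimination loop is the canonical correctness check.
    """
    if not 0 <= n_informative <= p:
        raise ValueError("n_informative must lie in [0, p]")
    means = np.zeros((K, p))
    if n_informative == 1:
        means[:, 0] = separation * np.arange(K)
    elif n_informative >= 2:
        radius = separation / (2.0 * np.sin(np.pi / K))
        phase = 0.7  # avoid axis-aligned symmetry so 1D projections stay distinct
        angles = 2.0 * np.pi * np.arange(K) / K + phase
        for j in range(n_informative):
            axis = np.cos(angles) if j % 2 == 0 else np.sin(angles)
            means[:, j] = radius * axis
    covs = np.full((K, p), noise_variance)
    sensor_ids = tuple(f"S{j+1}" for j in range(p))
    return SyntheticSpec(
        means=means,
        covariances=covs,
        n_k=tuple(n_k for _ in range(K)),
        sensor_ids=sensor_ids,
        informative=sensor_ids[:n_informative],
        seed=seed,
    )
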