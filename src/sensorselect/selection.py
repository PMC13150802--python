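"""Decision-aware sensor ranking, backward elimination, and working points.

Each sensor is scored on its own axis: the classes are ordered by their
mean response on that sensor, pairwise decision thresholds between
consecutive classes (Voronoi midpoints, or 1D QDA roots when the QDA
classifier is active) form a sensor-specific "ruler", and all readings are
discretised by the ruler's intervals.  Pearson's chi-squared between the
resulting bins and the true labels measures the sensor's stand-alone
discriminative power.  The weighted variant recomputes the statistic per
class pair and averages with weights inversely proportional to the pair's
separation along the sensor axis, emphasising confusable analytes.

Backward elimination drops the lowest-scoring sensor each iteration,
re-fitting the whole embedding/classifier stack on the survivors, until a
single sensor remains.  The working point l* then minimises the cost
J(l) = e(l) + eta*l, trading mean error (percent) against array size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2_contingency

from .core_data import ClassLabeling, PipelineConfig, ResponseTable, mean_center
from .covariance import ClassGaussian, inflate_class, predictive_inflate, shrink_and_condition
from .decision import classify_points, fit_decision_model
from .embedding import choose_dimension, class_local_pca, global_pca, restrict_dimension
from .evaluation import (
    PerformanceRecord,
    adjusted_rand_index,
    estimate_class_error,
    mean_error,
    mean_separation,
)

__all__ = [
    "SensorRuler",
    "PairwiseScore",
    "IterationRecord",
    "EliminationTrace",
    "WorkingPoint",
    "build_ruler",
    "discretize",
    "chi_squared_score",
    "pairwise_deltas",
    "weighted_chi_squared_score",
    "eliminate_one",
    "run_elimination",
    "select_working_point",
    "eta_sweep",
]


@dataclass(frozen=True)
class SensorRuler:
    """Decision-aware discretisation of one sensor's axis.

    ``class_order`` lists class indices by increasing class mean;
    ``thresholds`` are the (strictly increasing, deduplicated) pairwise
    decision boundaries; interval ``i`` spans ``(t[i-1], t[i]]`` and maps
    to ``interval_classes[i]``.
    """

    sensor_id: str
    class_order: tuple[int, ...]
    thresholds: np.ndarray
    interval_classes: tuple[int, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        object.__setattr__(self, "thresholds", t)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("ruler thresholds must be strictly increasing")
        if len(self.interval_classes) != t.size + 1:
            raise ValueError("need one interval class per threshold gap")


@dataclass(frozen=True)
class PairwiseScore:
    """Chi-squared contribution of one class pair on one sensor."""

    pair: tuple[int, int]
    chi2: float
    delta: float
    weight: float


@dataclass(frozen=True)
class IterationRecord:
    """One elimination iteration: metrics, survivors, and the removal."""

    iteration: int
    n_sensors: int
    surviving: tuple[str, ...]
    removed: str | None  # None on the final single-sensor iteration
    record: PerformanceRecord
    scores: dict[str, float] | None = None


@dataclass(frozen=True)
class EliminationTrace:
    """Full backward-elimination history, from ``p`` sensors down to one."""

    iterations: tuple[IterationRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "iterations", tuple(self.iterations))
        ns = [it.n_sensors for it in self.iterations]
        if ns != list(range(ns[0], 0, -1)):
            raise ValueError("trace must step down one sensor per iteration to 1")

    @property
    def p(self) -> int:
        return self.iterations[0].n_sensors

    def errors_by_count(self) -> dict[int, float]:
        """Mean error e(l) in percent, keyed by sensor count l."""
        return {it.n_sensors: it.record.mean_error for it in self.iterations}

    def surviving_at(self, l: int) -> tuple[str, ...]:
        for it in self.iterations:
            if it.n_sensors == l:
                return it.surviving
        raise KeyError(f"no iteration with {l} sensors")


@dataclass(frozen=True)
class WorkingPoint:
    """Sensor count minimising J(l) = e(l) + eta*l for one penalty eta."""

    eta: float
    l_star: int
    cost: dict[int, float]  # J(l) per sensor count
    sensor_ids: tuple[str, ...]
    error: float  # e(l*) in percent


def _qda_1d_threshold(mu_a: float, s2_a: float, mu_b: float, s2_b: float) -> float:
    """Boundary between two 1D Gaussians with uniform priors.

    Solves g_a(x) = g_b(x); returns the real root strictly between the two
    means, falling back to the midpoint when none exists (e.g. one class's
    variance so large that its density dominates everywhere between them).
    """
    mid = 0.5 * (mu_a + mu_b)
    if np.isclose(s2_a, s2_b):
        return mid
    a2 = 1.0 / s2_a - 1.0 / s2_b
    a1 = -2.0 * mu_a / s2_a + 2.0 * mu_b / s2_b
    a0 = mu_a**2 / s2_a - mu_b**2 / s2_b + np.log(s2_a / s2_b)
    roots = np.roots([a2, a1, a0])
    lo, hi = min(mu_a, mu_b), max(mu_a, mu_b)
    for r in roots:
        if abs(r.imag) < 1e-12 and lo < r.real < hi:
            return float(r.real)
    return mid


def build_ruler(
    sensor_values: np.ndarray,
    labeling: ClassLabeling,
    sensor_id: str = "",
    mode: str = "voronoi",
    inflation: str = "adjusted",
) -> SensorRuler:
    """Derive a sensor's decision-aware thresholds from its class marginals.

    Classes are ordered by increasing mean on this sensor.  Between each
    consecutive pair the threshold is the midpoint of the means (``mode
    "voronoi"``) or the 1D QDA boundary (``mode "qda1d"``), the latter
    computed from per-class variances inflated for finite samples (when
    ``inflation`` is adjusted) and regularised by pooled shrinkage with an
    eigenvalue floor.  Coincident thresholds are deduplicated; the merged
    classes then share one interval.
    """
    if mode not in ("voronoi", "qda1d"):
        raise ValueError(f"unknown ruler mode {mode!r}")
    values = np.asarray(sensor_values, dtype=float)
    labels = labeling.labels
    K = labeling.K
    means = np.array([values[labels == k].mean() for k in range(K)])
    order = tuple(int(k) for k in np.argsort(means, kind="stable"))
    if mode == "qda1d":
        variances = np.array([values[labels == k].var(ddof=1) for k in range(K)])
        counts = labeling.counts
        if inflation == "adjusted":
            variances = np.array(
                [predictive_inflate(s2, int(n)) for s2, n in zip(variances, counts)]
            )
        gaussians = [
            ClassGaussian(k, np.array([means[k]]), np.array([[variances[k]]]),
                          np.array([variances[k]]), int(counts[k]))
            for k in range(K)
        ]
        gaussians = shrink_and_condition(gaussians, labeling)
        variances = np.array([g.covariance[0, 0] for g in gaussians])
    thresholds: list[float] = []
    interval_classes: list[int] = [order[0]]
    for a, b in zip(order[:-1], order[1:]):
        if mode == "voronoi":
            t = 0.5 * (means[a] + means[b])
        else:
            t = _qda_1d_threshold(means[a], variances[a], means[b], variances[b])
        if thresholds and t <= thresholds[-1]:
            continue  # degenerate pair: class b shares the previous interval
        thresholds.append(float(t))
        interval_classes.append(b)
    return SensorRuler(sensor_id, order, np.array(thresholds), tuple(interval_classes))


def discretize(values: np.ndarray, ruler: SensorRuler) -> np.ndarray:
    """Map each reading to its ruler interval (bin ``i`` is ``(t[i-1], t[i]]``).

    A value landing exactly on a threshold goes to the left interval.
    """
    return np.searchsorted(ruler.thresholds, np.asarray(values, dtype=float), side="left")


def _pearson_chi2(bins: np.ndarray, labels: np.ndarray) -> float:
    """Pearson chi-squared of the bin x label contingency, no correction.

    Degenerate tables (a single nonempty bin or label) carry no
    association signal and score 0.
    """
    bins = np.asarray(bins)
    labels = np.asarray(labels)
    if bins.shape != labels.shape:
        raise ValueError("bins and labels must have equal length")
    b_codes = np.unique(bins, return_inverse=True)[1]
    l_codes = np.unique(labels, return_inverse=True)[1]
    table = np.zeros((b_codes.max() + 1, l_codes.max() + 1))
    np.add.at(table, (b_codes, l_codes), 1)
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0
    return float(chi2_contingency(table, correction=False).statistic)


def chi_squared_score(bins: np.ndarray, labels: np.ndarray) -> float:
    """Uniform (uFS) sensor score: one chi-squared over all classes."""
    return _pearson_chi2(bins, labels)


def pairwise_deltas(sensor_values: np.ndarray, labeling: ClassLabeling) -> dict[tuple[int, int], float]:
    """Distance between class sample centroids along the sensor axis."""
    values = np.asarray(sensor_values, dtype=float)
    means = np.array([values[labeling.labels == k].mean() for k in range(labeling.K)])
    return {
        (a, b): float(abs(means[a] - means[b]))
        for a in range(labeling.K)
        for b in range(a + 1, labeling.K)
    }


def weighted_chi_squared_score(
    bins: np.ndarray,
    labels: np.ndarray,
    deltas: dict[tuple[int, int], float],
    scale: float | None = None,
    return_details: bool = False,
) -> float | tuple[float, list[PairwiseScore]]:
    """Weighted (wFS) sensor score emphasising confusable class pairs.

    For every class pair ``(a, b)`` the chi-squared statistic is recomputed
    on the restriction to those classes (keeping the same bins) and the
    pairwise statistics are averaged with weights ``w(a,b) ∝ 1/Δ(a,b)``,
    normalised to sum to 1.  Zero separations are clipped at
    ``1e-9 * scale`` so coincident pairs get a large but finite weight.
    """
    bins = np.asarray(bins)
    labels = np.asarray(labels)
    pairs = sorted(deltas)
    if scale is None:
        scale = max(deltas.values()) or 1.0
    eps = 1e-9 * scale
    inv = np.array([1.0 / max(deltas[p], eps) for p in pairs])
    weights = inv / inv.sum()
    details: list[PairwiseScore] = []
    total = 0.0
    for (a, b), w in zip(pairs, weights):
        mask = (labels == a) | (labels == b)
        chi2_ab = _pearson_chi2(bins[mask], labels[mask])
        total += w * chi2_ab
        details.append(PairwiseScore((a, b), chi2_ab, deltas[(a, b)], float(w)))
    if return_details:
        return total, details
    return total


def eliminate_one(scores: dict[str, float]) -> str:
    """Pick the sensor to drop: minimum score, ties to the earliest sensor."""
    if len(scores) < 2:
        raise ValueError("elimination requires at least 2 surviving sensors")
    best_id, best_score = None, np.inf
    for sensor_id, score in scores.items():
        if score < best_score:
            best_id, best_score = sensor_id, score
    return best_id


def _score_sensors(
    sub: ResponseTable, labeling: ClassLabeling, config: PipelineConfig
) -> dict[str, float]:
    mode = "qda1d" if config.classifier == "qda" else "voronoi"
    scores: dict[str, float] = {}
    for j, sensor_id in enumerate(sub.sensor_ids):
        col = sub.values[:, j]
        ruler = build_ruler(col, labeling, sensor_id, mode=mode, inflation=config.inflation)
        bins = discretize(col, ruler)
        if config.fs_mode == "uniform":
            scores[sensor_id] = chi_squared_score(bins, labeling.labels)
        else:
            deltas = pairwise_deltas(col, labeling)
            scores[sensor_id] = weighted_chi_squared_score(
                bins, labeling.labels, deltas, scale=float(np.ptp(col)) or 1.0
            )
    return scores


def fit_iteration(
    sub: ResponseTable,
    labeling: ClassLabeling,
    config: PipelineConfig,
):
    """Fit embedding, class Gaussians, and decision model for one subset.

    Returns ``(embedding, gaussians, model)`` — the per-iteration modelling
    stack shared by the elimination loop and the reporting layer.
    """
    emb = global_pca(mean_center(sub))
    emb = restrict_dimension(emb, choose_dimension(emb, config))
    frames = class_local_pca(emb, labeling)
    gaussians = [inflate_class(f, adjusted=(config.inflation == "adjusted")) for f in frames]
    gaussians = shrink_and_condition(gaussians, labeling)
    model = fit_decision_model(gaussians, kind=config.classifier)
    return emb, gaussians, model


def run_elimination(
    table: ResponseTable, labeling: ClassLabeling, config: PipelineConfig
) -> EliminationTrace:
    """Backward-eliminate sensors one at a time down to a single survivor.

    Every iteration refits PCA, class Gaussians, and the decision model on
    the surviving subset, records the Monte-Carlo error, ARI, and mean
    centroid separation, then drops the lowest-chi-squared sensor.  Fully
    deterministic for a given ``config.seed``.
    """
    surviving = list(table.sensor_ids)
    iterations: list[IterationRecord] = []
    for iteration in range(table.p):
        sub = table.subset(surviving)
        emb, gaussians, model = fit_iteration(sub, labeling, config)
        errors = tuple(
            estimate_class_error(
                g, model, config.mc_samples,
                seed=np.random.SeedSequence(config.seed, spawn_key=(iteration, k)),
            )
            for k, g in enumerate(gaussians)
        )
        predicted = classify_points(model, emb.scores)
        record = PerformanceRecord(
            n_sensors=len(surviving),
            per_class_error=errors,
            mean_error=mean_error(errors),
            ari=adjusted_rand_index(labeling.labels, predicted),
            mean_separation=mean_separation(gaussians),
            ev_ratio=tuple(float(r) for r in emb.ev_ratio),
            dimension=emb.dimension,
        )
        if len(surviving) == 1:
            iterations.append(
                IterationRecord(iteration, 1, tuple(surviving), None, record, None)
            )
            break
        scores = _score_sensors(sub, labeling, config)
        removed = eliminate_one(scores)
        iterations.append(
            IterationRecord(iteration, len(surviving), tuple(surviving), removed, record, scores)
        )
        surviving.remove(removed)
    return EliminationTrace(tuple(iterations))


def select_working_point(trace: EliminationTrace, eta: float) -> WorkingPoint:
    """Minimise J(l) = e(l) + eta*l over l = 1..p; ties go to smaller l."""
    if eta < 0:
        raise ValueError("eta must be non-negative")
    errors = trace.errors_by_count()
    cost = {l: errors[l] + eta * l for l in sorted(errors)}
    l_star = min(cost, key=lambda l: (cost[l], l))
    return WorkingPoint(
        eta=float(eta),
        l_star=int(l_star),
        cost=cost,
        sensor_ids=trace.surviving_at(l_star),
        error=errors[l_star],
    )


def eta_sweep(
    trace: EliminationTrace, lo: float, hi: float, step: float
) -> list[tuple[float, int]]:
    """Selected sensor count l*(eta) over a grid of penalties."""
    if step <= 0:
        raise ValueError("step must be positive")
    etas = np.arange(lo, hi + 0.5 * step, step)
    return [(float(e), select_working_point(trace, float(e)).l_star) for e in etas]
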