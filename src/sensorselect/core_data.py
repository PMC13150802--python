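"""Screening-table containers, validation, and response preprocessing.

A screening experiment produces a small table of sensor responses: rows are
replicate measurements of a known analyte, columns are sensors.  This module
holds that table (:class:`ResponseTable`), its analyte labels
(:class:`ClassLabeling`), and the run configuration
(:class:`PipelineConfig`), plus the two preprocessing steps the pipeline
applies before any embedding: fractional-response normalisation and
per-sensor mean-centering.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ResponseTable",
    "ClassLabeling",
    "PipelineConfig",
    "load_response_table",
    "fractional_response",
    "mean_center",
    "load_config",
]


@dataclass(frozen=True)
class ResponseTable:
    """An ``n x p`` matrix of unitless sensor responses.

    Parameters
    ----------
    values
        Real matrix, one row per replicate sample, one column per sensor.
    sensor_ids
        Ordered, unique sensor identifiers (column names).
    sample_ids
        Ordered sample identifiers (row names).
    """

    values: np.ndarray
    sensor_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sensor_ids", tuple(str(s) for s in self.sensor_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if values.ndim != 2:
            raise ValueError("response values must be a 2D matrix")
        n, p = values.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if p < 1:
            raise ValueError("need at least 1 sensor")
        if len(self.sensor_ids) != p:
            raise ValueError("sensor_ids length does not match number of columns")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of rows")
        if len(set(self.sensor_ids)) != p:
            raise ValueError("sensor_ids must be unique")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[bad[0]]!r}, "
                f"sensor {self.sensor_ids[bad[1]]!r}"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def subset(self, sensor_ids: Sequence[str]) -> "ResponseTable":
        """Return a new table restricted to ``sensor_ids`` (order preserved)."""
        idx = [self.sensor_ids.index(s) for s in sensor_ids]
        return ResponseTable(self.values[:, idx], tuple(sensor_ids), self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.sensor_ids)
        )


@dataclass(frozen=True)
class ClassLabeling:
    """Per-sample analyte class assignment.

    ``labels`` holds 0-based class indices into ``class_names``; ``counts``
    is the replicate count per class.  Every class needs at least two
    replicates, since class variances are estimated from them.
    """

    labels: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "class_names", tuple(str(c) for c in self.class_names))
        if labels.ndim != 1:
            raise ValueError("labels must be a 1D vector")
        K = len(self.class_names)
        if K < 2:
            raise ValueError(f"need at least 2 classes, got {K}")
        if labels.min() < 0 or labels.max() >= K:
            raise ValueError("label index out of range")
        counts = np.bincount(labels, minlength=K)
        for k, c in enumerate(counts):
            if c < 2:
                raise ValueError(
                    f"class {self.class_names[k]!r} has {c} replicate(s); "
                    "at least 2 samples per class are required for variance "
                    "estimation"
                )

    @property
    def K(self) -> int:
        return len(self.class_names)

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.K)

    @property
    def n(self) -> int:
        return self.labels.shape[0]


@dataclass
class PipelineConfig:
    """Tunable parameters of the selection pipeline.

    classifier
        ``"qda"`` (default; curved per-class boundaries) or ``"voronoi"``
        (nearest-centroid, piecewise-linear).
    fs_mode
        ``"uniform"`` scores each sensor by one chi-squared statistic;
        ``"weighted"`` averages pairwise chi-squared statistics with weights
        inversely proportional to class-pair separation.
    inflation
        ``"adjusted"`` applies the finite-sample predictive-variance
        inflation to class covariances; ``"unadjusted"`` uses the raw
        sample scatter.
    ev_flag / ev_threshold
        When the flag is on and PC1 alone explains more than
        ``ev_threshold`` of the variance, the decision model drops to 1D.
    etas
        Working-point penalties in percent error per sensor.
    mc_samples
        Monte-Carlo draws per class for error estimation.
    grid_resolution
        Cells per axis when rasterising decision regions.
    ellipse_level
        Coverage level of the per-class confidence ellipses.
    """

    classifier: str = "qda"
    fs_mode: str = "uniform"
    inflation: str = "adjusted"
    ev_flag: bool = False
    ev_threshold: float = 0.95
    etas: tuple[float, ...] = (3.0, 0.5)
    mc_samples: int = 100_000
    grid_resolution: int = 400
    seed: int = 0
    ellipse_level: float = 0.95

    def __post_init__(self) -> None:
        if self.classifier not in ("qda", "voronoi"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.fs_mode not in ("uniform", "weighted"):
            raise ValueError(f"unknown fs_mode {self.fs_mode!r}")
        if self.inflation not in ("adjusted", "unadjusted"):
            raise ValueError(f"unknown inflation mode {self.inflation!r}")
        if not 0.0 < self.ev_threshold < 1.0:
            raise ValueError("ev_threshold must lie in (0, 1)")
        self.etas = tuple(float(e) for e in self.etas)
        if any(e < 0 for e in self.etas):
            raise ValueError("etas must be non-negative")
        if self.mc_samples < 1_000:
            raise ValueError("mc_samples must be at least 1000")
        if not 0.0 < self.ellipse_level < 1.0:
            raise ValueError("ellipse_level must lie in (0, 1)")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["etas"] = list(self.etas)
        return d


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML key-value file overriding any :class:`PipelineConfig` field."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def load_response_table(
    path: str | Path, label_column: str = "label"
) -> tuple[ResponseTable, ClassLabeling]:
    """Load a delimited screening table with one label column.

    The delimiter is taken from the extension (``.tsv`` -> tab, else comma).
    All non-label columns must be numeric sensor responses; row order is
    preserved, and class names keep first-appearance order.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if label_column not in df.columns:
        raise ValueError(
            f"label column {label_column!r} not found in {path.name} "
            f"(columns: {list(df.columns)})"
        )
    labels_raw = df[label_column].astype(str)
    sensors = df.drop(columns=[label_column])
    for col in sensors.columns:
        numeric = pd.to_numeric(sensors[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise ValueError(
                f"non-numeric value in sensor column {col!r} at row {row}: "
                f"{sensors[col].iloc[row]!r}"
            )
        sensors[col] = numeric
    sample_ids = tuple(str(i) for i in df.index)
    table = ResponseTable(
        sensors.to_numpy(dtype=float), tuple(sensors.columns), sample_ids
    )
    class_names = tuple(dict.fromkeys(labels_raw))
    name_to_idx = {c: i for i, c in enumerate(class_names)}
    labeling = ClassLabeling(
        np.array([name_to_idx[c] for c in labels_raw]), class_names
    )
    return table, labeling


def fractional_response(intensity: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Elementwise fractional response ``(I - I0) / I0``.

    ``intensity`` and ``baseline`` must have identical shapes and the
    baseline must be nonzero everywhere.
    """
    intensity = np.asarray(intensity, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if intensity.shape != baseline.shape:
        raise ValueError(
            f"shape mismatch: intensity {intensity.shape} vs baseline {baseline.shape}"
        )
    if np.any(baseline == 0):
        bad = np.argwhere(np.atleast_1d(baseline) == 0)[0]
        raise ValueError(f"zero baseline entry at index {tuple(bad)}")
    return (intensity - baseline) / baseline


def mean_center(table: ResponseTable) -> ResponseTable:
    """Subtract each sensor's mean response; variances are unchanged."""
    centered = table.values - table.values.mean(axis=0, keepdims=True)
    return ResponseTable(centered, table.sensor_ids, table.sample_ids)
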