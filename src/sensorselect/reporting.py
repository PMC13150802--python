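"""End-to-end pipeline driver and table/raster export.

``run_pipeline`` executes the full reduction on a screening table and
writes every artifact needed to audit the greedy path and regenerate the
standard figure panels: the per-iteration performance trace, elimination
order, working-point summary, per-iteration confidence-ellipse parameters,
and decision-region rasters (first iteration and each working point).
A ``RunManifest`` records the configuration, seed, input hash, and output
files, making runs reproducible and comparable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import ClassLabeling, PipelineConfig, ResponseTable
from .covariance import confidence_ellipse
from .decision import region_grid
from .selection import (
    EliminationTrace,
    WorkingPoint,
    eta_sweep,
    fit_iteration,
    run_elimination,
    select_working_point,
)

__all__ = ["RunManifest", "run_pipeline", "run_pipeline_from_files", "emit_report"]


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config: dict
    seed: int
    input_hash: str
    outputs: list[str] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _hash_table(table: ResponseTable, labeling: ClassLabeling) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(table.values).tobytes())
    h.update(",".join(table.sensor_ids).encode())
    h.update(labeling.labels.astype(np.int64).tobytes())
    return h.hexdigest()


def _write_trace(trace: EliminationTrace, outdir: Path) -> list[Path]:
    rows = []
    for it in trace.iterations:
        ev = list(it.record.ev_ratio) + [np.nan]
        rows.append(
            {
                "n_sensors": it.n_sensors,
                "mean_error": it.record.mean_error,
                "ari": it.record.ari,
                "mean_separation": it.record.mean_separation,
                "ev1": ev[0],
                "ev2": ev[1],
                "dimension": it.record.dimension,
                **{
                    f"error_class{k+1}": e
                    for k, e in enumerate(it.record.per_class_error)
                },
            }
        )
    trace_path = outdir / "trace.csv"
    pd.DataFrame(rows).to_csv(trace_path, index=False, float_format="%.10g")
    order_rows = [
        {"iteration": it.iteration + 1, "removed_sensor": it.removed}
        for it in trace.iterations
        if it.removed is not None
    ]
    order_path = outdir / "elimination_order.csv"
    pd.DataFrame(order_rows).to_csv(order_path, index=False)
    return [trace_path, order_path]


def _write_ellipses(
    trace: EliminationTrace,
    table: ResponseTable,
    labeling: ClassLabeling,
    config: PipelineConfig,
    outdir: Path,
) -> list[Path]:
    rows = []
    for it in trace.iterations:
        _, gaussians, _ = fit_iteration(table.subset(it.surviving), labeling, config)
        if gaussians[0].dimension != 2:
            continue
        for g in gaussians:
            e = confidence_ellipse(g, config.ellipse_level)
            rows.append(
                {
                    "n_sensors": it.n_sensors,
                    "class": labeling.class_names[g.class_index],
                    "center_pc1": e.center[0],
                    "center_pc2": e.center[1],
                    "semi_major": e.semi_axes[0],
                    "semi_minor": e.semi_axes[1],
                    "angle_rad": e.angle,
                    "level": e.level,
                }
            )
    path = outdir / "ellipses.csv"
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
    return [path]


def _write_raster(
    table: ResponseTable,
    labeling: ClassLabeling,
    config: PipelineConfig,
    surviving: tuple[str, ...],
    path: Path,
) -> Path:
    _, gaussians, model = fit_iteration(table.subset(surviving), labeling, config)
    grid = region_grid(model, gaussians, resolution=config.grid_resolution)
    if model.dimension == 1:
        df = pd.DataFrame(
            {
                "pc1": grid.axes[0],
                "class": [labeling.class_names[c] for c in grid.assignment],
            }
        )
    else:
        xx, yy = np.meshgrid(grid.axes[0], grid.axes[1], indexing="ij")
        df = pd.DataFrame(
            {
                "pc1": xx.ravel(),
                "pc2": yy.ravel(),
                "class": [labeling.class_names[c] for c in grid.assignment.ravel()],
            }
        )
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def run_pipeline(
    table: ResponseTable,
    labeling: ClassLabeling,
    config: PipelineConfig,
    outdir: str | Path,
    sweep: tuple[float, float, float] | None = None,
) -> tuple[EliminationTrace, list[WorkingPoint], RunManifest]:
    """Run the full reduction and write all artifacts to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(), seed=config.seed, input_hash=_hash_table(table, labeling)
    )
    t0 = time.perf_counter()
    trace = run_elimination(table, labeling, config)
    manifest.timings["elimination_s"] = round(time.perf_counter() - t0, 3)

    outputs = _write_trace(trace, outdir)
    outputs += _write_ellipses(trace, table, labeling, config, outdir)

    working_points = [select_working_point(trace, eta) for eta in config.etas]
    wp_rows = [
        {
            "eta": wp.eta,
            "l_star": wp.l_star,
            "mean_error": wp.error,
            "sensor_ids": ";".join(wp.sensor_ids),
        }
        for wp in working_points
    ]
    wp_path = outdir / "working_points.csv"
    pd.DataFrame(wp_rows).to_csv(wp_path, index=False, float_format="%.10g")
    outputs.append(wp_path)

    t0 = time.perf_counter()
    outputs.append(
        _write_raster(table, labeling, config, trace.iterations[0].surviving,
                      outdir / "region_first.csv")
    )
    for wp in working_points:
        outputs.append(
            _write_raster(table, labeling, config, wp.sensor_ids,
                          outdir / f"region_wp_eta{wp.eta:g}.csv")
        )
    manifest.timings["rasters_s"] = round(time.perf_counter() - t0, 3)

    if sweep is not None:
        lo, hi, step = sweep
        sweep_rows = [{"eta": e, "l_star": l} for e, l in eta_sweep(trace, lo, hi, step)]
        sweep_path = outdir / "eta_sweep.csv"
        pd.DataFrame(sweep_rows).to_csv(sweep_path, index=False, float_format="%.10g")
        outputs.append(sweep_path)

    manifest.outputs = sorted(str(p.name) for p in outputs) + ["manifest.json"]
    manifest.write(outdir / "manifest.json")
    return trace, working_points, manifest


def run_pipeline_from_files(
    input_path: str | Path,
    output_dir: str | Path,
    config: PipelineConfig | None = None,
    config_path: str | Path | None = None,
    label_column: str = "label",
    sweep: tuple[float, float, float] | None = None,
):
    """File-based front end: load table and config, run, write artifacts."""
    from .core_data import load_config, load_response_table

    if config is None:
        config = load_config(config_path) if config_path else PipelineConfig()
    table, labeling = load_response_table(input_path, label_column)
    return run_pipeline(table, labeling, config, output_dir, sweep=sweep)


def emit_report(trace: EliminationTrace, working_points: list[WorkingPoint]) -> str:
    """Human-readable per-iteration table with working points marked."""
    lines = [
        f"{'l':>4} {'e(l) %':>10} {'ARI':>8} {'<D>':>10} {'removed':>12}",
    ]
    marks = {wp.l_star: [] for wp in working_points}
    for wp in working_points:
        marks[wp.l_star].append(f"eta={wp.eta:g}")
    for it in trace.iterations:
        r = it.record
        mark = "  <= " + ", ".join(marks[it.n_sensors]) if it.n_sensors in marks else ""
        lines.append(
            f"{it.n_sensors:>4} {r.mean_error:>10.4f} {r.ari:>8.4f} "
            f"{r.mean_separation:>10.4f} {str(it.removed or '-'):>12}{mark}"
        )
    if not working_points:
        lines.append("warning: no working-point penalties configured")
    else:
        for wp in working_points:
            lines.append(
                f"working point eta={wp.eta:g}%: l*={wp.l_star}, "
                f"e={wp.error:.4f}%, sensors: {', '.join(wp.sensor_ids)}"
            )
    return "\n".join(lines)
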