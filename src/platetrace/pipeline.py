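"""Settings-driven pipeline: chain analysis stages, write per-stage outputs.

The legal stage order is fixed — formatting → sensor correction →
reference normalization → replicate aggregation → smoothing → slope — with
the time-resolved IC50 branching off the aggregated data; any suffix of
the chain may be skipped.  Each run writes its outputs, the resolved
settings and a log into a fresh run directory (never silently overwriting
a previous one), so a run is fully reconstructible from what it leaves on
disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import viz
from .dose_response import IC50Trajectory, fit_ic50_over_time
from .plate_io import (
    AnalysisSettings,
    AssayTable,
    PlateLayout,
    read_assay_csv,
    read_layout,
    save_settings,
    write_table_csv,
)
from .preprocess import convert_time_units, scale_values, shift_time_origin, trim_time_range
from .sensor_correction import CalibrationModel, correct_sensors
from .timeseries_stats import (
    AggregatedTable,
    SlopeTable,
    aggregate_replicates,
    normalize_to_reference,
    smooth,
    windowed_slope,
)

__all__ = ["PipelineResult", "validate_stage_order", "run_pipeline"]


@dataclass
class PipelineResult:
    """Handles to everything a pipeline run produced."""

    run_dir: Path
    outputs: dict[str, Path] = field(default_factory=dict)
    table: AssayTable | None = None
    aggregated: AggregatedTable | None = None
    slopes: SlopeTable | None = None
    trajectory: IC50Trajectory | None = None
    log: list[str] = field(default_factory=list)


def validate_stage_order(settings: AnalysisSettings) -> list[str]:
    """Check stage dependencies before any computation; return active stages."""
    stages = []
    if settings.formatting is not None:
        stages.append("formatting")
    if settings.correction is not None:
        stages.append("correction")
    if settings.normalize_target is not None:
        stages.append("normalization")
    if settings.aggregate:
        stages.append("aggregation")
    if settings.smooth_n is not None:
        stages.append("smoothing")
    if settings.slope_n is not None:
        stages.append("slope")
    if settings.ic50 is not None:
        stages.append("ic50")
    if not stages:
        raise ValueError("settings select no analysis stage")
    if "slope" in stages and "smoothing" not in stages:
        raise ValueError("slope calculation requires the smoothing stage")
    if "ic50" in stages and "aggregation" not in stages and not (
        settings.ic50 and settings.ic50.use_replicates
    ):
        raise ValueError(
            "the IC50 stage fits averaged data and requires the aggregation "
            "stage (or use_replicates)"
        )
    needs_layout = {"normalization", "aggregation", "ic50"} & set(stages)
    if needs_layout and settings.layout is None:
        raise ValueError(f"stage(s) {sorted(needs_layout)} require a plate layout")
    return stages


def _next_run_dir(base: Path) -> Path:
    base.mkdir(parents=True, exist_ok=True)
    i = 1
    while (base / f"run_{i:03d}").exists():
        i += 1
    out = base / f"run_{i:03d}"
    out.mkdir()
    return out


def run_pipeline(
    settings: AnalysisSettings | str | Path,
    output_base: str | Path = "platetrace_runs",
) -> PipelineResult:
    """Execute the configured stages on the configured inputs.

    The pipeline is a pure function of (input files, settings): identical
    inputs yield identical outputs, written to a fresh run directory.
    """
    from .plate_io import load_settings

    if not isinstance(settings, AnalysisSettings):
        settings = load_settings(settings)
    stages = validate_stage_order(settings)
    if not settings.inputs:
        raise ValueError("settings name no input files")

    run_dir = _next_run_dir(Path(output_base))
    result = PipelineResult(run_dir=run_dir)
    log = result.log
    step = 0

    def emit_table(name: str, table: AssayTable) -> None:
        nonlocal step
        step += 1
        path = run_dir / f"{step:02d}_{name}.csv"
        write_table_csv(table, path)
        result.outputs[name] = path
        log.append(
            f"{name}: {table.n_points} rows x {len(table.columns)} columns -> {path.name}"
        )

    def emit_frame(name: str, frame, unit_note: str = "") -> None:
        nonlocal step
        step += 1
        path = run_dir / f"{step:02d}_{name}.csv"
        frame.to_csv(path, index=False)
        result.outputs[name] = path
        log.append(f"{name}: {len(frame)} rows -> {path.name} {unit_note}".rstrip())

    table = read_assay_csv(settings.inputs, value_unit=settings.value_unit)
    log.append(
        f"input: {len(settings.inputs)} file(s), {table.n_points} rows x "
        f"{len(table.columns)} columns"
    )
    layout: PlateLayout | None = None
    if settings.layout is not None:
        layout = read_layout(settings.layout)
        layout.validate_against(table)
        log.append(f"layout: {len(layout.wells)} columns, {len(layout.groups())} groups")

    if "formatting" in stages:
        f = settings.formatting
        if f.convert_from and f.convert_to:
            table = convert_time_units(table, f.convert_from, f.convert_to)
            log.append(f"convert: {f.convert_from} -> {f.convert_to}")
        if f.trim_min is not None or f.trim_max is not None:
            lo = f.trim_min if f.trim_min is not None else table.time[0]
            hi = f.trim_max if f.trim_max is not None else table.time[-1]
            table = trim_time_range(table, lo, hi)
            log.append(f"trim: [{lo}, {hi}] -> {table.n_points} rows")
        if f.shift is not None:
            table = shift_time_origin(table, f.shift)
            log.append(f"shift: offset {f.shift}")
        if f.scale_factor is not None:
            table = scale_values(table, f.scale_factor, f.scaled_unit)
            log.append(f"scale: factor {f.scale_factor}")
        emit_table("formatted", table)

    if "correction" in stages:
        c = settings.correction
        calib = CalibrationModel(
            plateau=c.plateau, span=c.span, alpha=c.alpha, window=tuple(c.window)
        )
        if c.target is None:
            raise ValueError("sensor correction requires a target value")
        table, factors = correct_sensors(
            table, calib, c.target, clip_epsilon=c.clip_epsilon
        )
        log.append(
            f"correction: window {c.window}, target {c.target}, "
            f"factors in [{factors.factors.min():.6g}, {factors.factors.max():.6g}]"
        )
        emit_table("corrected", table)

    if "normalization" in stages:
        table = normalize_to_reference(table, layout, settings.normalize_target)
        log.append(f"normalization: target {settings.normalize_target}")
        emit_table("normalized", table)

    agg = None
    if "aggregation" in stages:
        agg = aggregate_replicates(table, layout)
        result.aggregated = agg
        emit_frame("aggregated", agg.as_frame())

    post = agg.to_table() if agg is not None else table
    if "smoothing" in stages:
        post = smooth(post, settings.smooth_n)
        log.append(f"smoothing: n={settings.smooth_n} -> {post.n_points} rows")
        emit_table("smoothed", post)

    if "slope" in stages:
        slopes = windowed_slope(post, settings.slope_n)
        result.slopes = slopes
        log.append(f"slope: n={settings.slope_n} per side -> {slopes.time.size} rows")
        emit_frame("slope", slopes.as_frame())

    if "ic50" in stages:
        ic = settings.ic50
        window = tuple(ic.window) if ic.window is not None else None
        traj, fits = fit_ic50_over_time(
            table,
            layout,
            family=ic.family,
            time_window=window,
            stride=ic.stride,
            use_replicates=ic.use_replicates,
        )
        result.trajectory = traj
        n_ok = int(traj.converged.sum())
        log.append(
            f"ic50: family {ic.family}, {traj.time.size} fits ({n_ok} converged)"
        )
        emit_frame("ic50_trajectory", traj.as_frame())
        import pandas as pd

        rows = []
        for f_ in fits:
            row = {"time": f_.time, "converged": f_.converged, "rse": f_.rse}
            row.update(f_.params)
            row.update({f"{k}_se": v for k, v in f_.se.items()})
            rows.append(row)
        emit_frame("ic50_fits", pd.DataFrame(rows))

    if settings.plots:
        fmt = settings.plot_format
        step += 1
        ppath = run_dir / f"{step:02d}_curves.{fmt}"
        viz.plot_curves(table, layout, ppath)
        result.outputs["plot_curves"] = ppath
        if result.aggregated is not None:
            step += 1
            apath = run_dir / f"{step:02d}_aggregated.{fmt}"
            viz.plot_aggregated(result.aggregated, apath)
            result.outputs["plot_aggregated"] = apath
        if result.slopes is not None:
            step += 1
            spath = run_dir / f"{step:02d}_slope.{fmt}"
            viz.plot_slopes(result.slopes, spath)
            result.outputs["plot_slope"] = spath
        if result.trajectory is not None:
            step += 1
            tpath = run_dir / f"{step:02d}_ic50.{fmt}"
            viz.plot_trajectory(result.trajectory, tpath)
            result.outputs["plot_ic50"] = tpath

    result.table = table
    save_settings(settings, run_dir / "settings.yaml")
    (run_dir / "run.log").write_text("\n".join(log) + "\n")
    return result
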