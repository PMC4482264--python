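"""Static plot export: curves with ribbons, fit snapshots, IC50 trajectory."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .dose_response import DoseResponseFit, IC50Trajectory
from .plate_io import AssayTable, PlateLayout
from .timeseries_stats import AggregatedTable, SlopeTable

__all__ = ["plot_curves", "plot_aggregated", "plot_slopes", "plot_fit_snapshots", "plot_trajectory"]

_FORMATS = ("png", "svg", "pdf")

_LINESTYLES = {"solid": "-", "dashed": "--", "dotted": ":", "dashdot": "-."}


def _check_format(path: Path) -> None:
    fmt = path.suffix.lstrip(".").lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown image format {fmt!r}; expected one of {_FORMATS}")


def _style(layout: PlateLayout | None, col: str) -> dict:
    if layout is None or col not in layout.wells:
        return {"label": col}
    s = layout.wells[col]
    kw = {"label": s.legend or s.label or col}
    if s.color:
        kw["color"] = s.color
    kw["linestyle"] = _LINESTYLES.get(s.linetype, s.linetype or "-")
    return kw


def _finish(fig, ax, xlabel: str, ylabel: str, path: str | Path) -> Path:
    path = Path(path)
    _check_format(path)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    handles, labels = ax.get_legend_handles_labels()
    seen, h2, l2 = set(), [], []
    for h, l in zip(handles, labels):
        if l not in seen:
            seen.add(l)
            h2.append(h)
            l2.append(l)
    if l2:
        ax.legend(h2, l2, fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_curves(
    table: AssayTable, layout: PlateLayout | None, path: str | Path
) -> Path:
    """One line per column, styled per the layout."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for col in table.columns:
        if layout is not None and layout.wells.get(col) is not None:
            if layout.wells[col].role == "excluded":
                continue
        ax.plot(table.time, table.data[col], lw=0.8, **_style(layout, col))
    return _finish(fig, ax, f"time [{table.time_unit}]", table.value_unit or "value", path)


def plot_aggregated(agg: AggregatedTable, path: str | Path) -> Path:
    """Replicate-group means with the SD as a grey ribbon behind each curve."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for g in agg.groups:
        m = agg.means[g].to_numpy()
        sd = agg.sds[g].to_numpy()
        if np.isfinite(sd).any():
            ax.fill_between(agg.time, m - sd, m + sd, color="0.6", alpha=0.35, lw=0)
        ax.plot(agg.time, m, lw=1.0, label=g)
    return _finish(fig, ax, f"time [{agg.time_unit}]", agg.value_unit or "value", path)


def plot_slopes(slopes: SlopeTable, path: str | Path) -> Path:
    """Local slopes with the residual standard error as a grey ribbon."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for c in slopes.slopes.columns:
        m = slopes.slopes[c].to_numpy()
        r = slopes.residuals[c].to_numpy()
        if np.isfinite(r).any():
            ax.fill_between(slopes.time, m - r, m + r, color="0.6", alpha=0.35, lw=0)
        ax.plot(slopes.time, m, lw=1.0, label=c)
    unit = f"{slopes.value_unit}/{slopes.time_unit}".strip("/")
    return _finish(fig, ax, f"time [{slopes.time_unit}]", f"slope [{unit}]", path)


def plot_fit_snapshots(
    fits: Sequence[DoseResponseFit],
    doses: np.ndarray,
    responses: np.ndarray,
    path: str | Path,
    dose_unit: str = "",
) -> Path:
    """Measured responses and fitted sigmoids for a few selected time points.

    ``responses`` has one row per fit (same order), one column per dose.
    Doses are drawn on a log axis; the zero dose is placed at a pseudo-dose
    one decade below the smallest nonzero dose.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    pos = doses[doses > 0]
    x0 = pos.min() / 10.0 if pos.size else 1.0
    xplot = np.where(doses > 0, doses, x0)
    grid = np.geomspace(x0, max(pos.max() if pos.size else 1.0, x0 * 10), 200)
    cmap = plt.get_cmap("viridis")
    for i, fit in enumerate(fits):
        color = cmap(i / max(len(fits) - 1, 1))
        label = f"t={fit.time:g}" if fit.time is not None else f"fit {i}"
        ax.scatter(xplot, responses[i], s=12, color=color)
        if fit.converged:
            ax.plot(grid, fit.model().predict(grid), color=color, lw=1.2, label=label)
    ax.set_xscale("log")
    return _finish(fig, ax, f"dose [{dose_unit}]" if dose_unit else "dose", "response", path)


def plot_trajectory(traj: IC50Trajectory, path: str | Path) -> Path:
    """IC50 over time with the per-fit standard error as a grey ribbon."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ok = traj.converged & np.isfinite(traj.e)
    t, e, se = traj.time[ok], traj.e[ok], traj.se[ok]
    if np.isfinite(se).any():
        ax.fill_between(t, e - se, e + se, color="0.6", alpha=0.4, lw=0)
    ax.plot(t, e, color="crimson", lw=1.2, label="IC50")
    label = f"IC50 [{traj.dose_unit}]" if traj.dose_unit else "IC50"
    return _finish(fig, ax, f"time [{traj.time_unit}]", label, path)
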