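"""Reference normalization, replicate aggregation, smoothing and slopes."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .plate_io import AssayTable, PlateLayout

__all__ = [
    "AggregatedTable",
    "SlopeTable",
    "normalize_to_reference",
    "aggregate_replicates",
    "smooth",
    "windowed_slope",
]


@dataclass(eq=False)
class AggregatedTable:
    """Per-replicate-group mean and sample standard deviation over time."""

    time: np.ndarray
    means: pd.DataFrame
    sds: pd.DataFrame
    counts: pd.DataFrame
    singleton_groups: list[str]
    time_unit: str = "s"
    value_unit: str = ""

    @property
    def groups(self) -> list[str]:
        return list(self.means.columns)

    def to_table(self) -> AssayTable:
        """Group means as a plain AssayTable for downstream stages."""
        return AssayTable(
            time=self.time,
            data=self.means.copy(),
            time_unit=self.time_unit,
            value_unit=self.value_unit,
        )

    def as_frame(self) -> pd.DataFrame:
        """Long-ish export frame: mean columns plus ``<group>__sd`` companions."""
        out = {f"time [{self.time_unit}]": self.time}
        for g in self.groups:
            out[g] = self.means[g].to_numpy()
            out[f"{g}__sd"] = self.sds[g].to_numpy()
        return pd.DataFrame(out)


@dataclass(eq=False)
class SlopeTable:
    """Local OLS slope and residual standard error per column over time."""

    time: np.ndarray
    slopes: pd.DataFrame
    residuals: pd.DataFrame
    window: int  # points per side
    time_unit: str = "s"
    value_unit: str = ""

    def to_table(self) -> AssayTable:
        return AssayTable(
            time=self.time,
            data=self.slopes.copy(),
            time_unit=self.time_unit,
            value_unit=f"{self.value_unit}/{self.time_unit}".strip("/"),
        )

    def as_frame(self) -> pd.DataFrame:
        out = {f"time [{self.time_unit}]": self.time}
        for c in self.slopes.columns:
            out[c] = self.slopes[c].to_numpy()
            out[f"{c}__residual"] = self.residuals[c].to_numpy()
        return pd.DataFrame(out)


def normalize_to_reference(
    table: AssayTable, layout: PlateLayout, target: float
) -> AssayTable:
    """Divide every value by the time-matched reference mean, times target.

    The reference condition is the set of columns whose role is
    ``reference`` or ``medium_control``; after normalization their mean is
    exactly ``target`` at every time point.
    """
    layout.validate_against(table)
    refs = [c for c in layout.reference_columns() if c in table.data.columns]
    if not refs:
        raise ValueError("no reference/medium_control columns in layout")
    m_t = table.data[refs].mean(axis=1, skipna=True).to_numpy()
    bad = ~np.isfinite(m_t) | (m_t == 0.0)
    if bad.any():
        ts = table.time[bad][:10].tolist()
        raise ValueError(f"reference mean zero/undefined at time point(s) {ts}")
    scaled = table.values() / m_t[:, None] * float(target)
    out = table.data.copy()
    out.iloc[:, :] = scaled
    return table.replace(data=out)


def aggregate_replicates(table: AssayTable, layout: PlateLayout) -> AggregatedTable:
    """Mean and sample SD (ddof=1) of technical replicates per time point.

    Missing values are excluded pairwise; a time point where a whole group
    is missing yields missing outputs there.  Groups of size 1 get SD 0 and
    are reported in ``singleton_groups``.
    """
    layout.validate_against(table)
    groups = layout.groups()
    if not groups:
        raise ValueError("layout defines no replicate groups")
    means, sds, counts = {}, {}, {}
    singletons = []
    for g, cols in groups.items():
        block = table.data[cols]
        means[g] = block.mean(axis=1, skipna=True)
        counts[g] = block.notna().sum(axis=1)
        if len(cols) == 1:
            singletons.append(g)
            sds[g] = pd.Series(np.where(counts[g] > 0, 0.0, np.nan))
        else:
            sd = block.std(axis=1, ddof=1, skipna=True)
            sds[g] = sd.where(counts[g] != 1, 0.0)
    return AggregatedTable(
        time=table.time.copy(),
        means=pd.DataFrame(means),
        sds=pd.DataFrame(sds),
        counts=pd.DataFrame(counts),
        singleton_groups=singletons,
        time_unit=table.time_unit,
        value_unit=table.value_unit,
    )


def smooth(table: AssayTable, n: int) -> AssayTable:
    """Centered moving average over n neighbouring points.

    n must be odd (a data point plus (n−1)/2 neighbours per side) and the
    output loses (n−1)/2 points at each end; the time vector is trimmed to
    match.  Missing values are excluded from each window mean.
    """
    n = int(n)
    if n % 2 == 0:
        raise ValueError(f"smoothing window n must be an uneven number, got {n}")
    if n < 3:
        raise ValueError("smoothing window n must be >= 3")
    if n > table.n_points:
        raise ValueError(
            f"smoothing window n={n} exceeds series length {table.n_points}"
        )
    k = (n - 1) // 2
    wins = sliding_window_view(table.values(), n, axis=0)  # (T-n+1, C, n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        sm = np.nanmean(wins, axis=2)
    data = pd.DataFrame(sm, columns=table.data.columns)
    return table.replace(time=table.time[k:-k].copy(), data=data)


def windowed_slope(table: AssayTable, n: int) -> SlopeTable:
    """Moving-window OLS slope with n points on either side (2n+1 total).

    At each interior time point an ordinary least-squares line is fitted
    through the point and its n neighbours per side, using the actual time
    stamps (irregular spacing supported).  The slope is in value units per
    time unit; the residual is the residual standard error
    sqrt(SSE/(2n+1−2)) of the local fit.  n points are lost at each end.
    """
    n = int(n)
    if n < 1:
        raise ValueError("slope window half-width n must be >= 1")
    w = 2 * n + 1
    if table.n_points < w:
        raise ValueError(
            f"series length {table.n_points} too short for slope window 2*{n}+1={w}"
        )
    y = table.values()  # (T, C)
    tw = sliding_window_view(table.time, w)  # (W, w)
    yw = sliding_window_view(y, w, axis=0)  # (W, C, w)
    mask = np.isfinite(yw)
    cnt = mask.sum(axis=2)  # (W, C)
    tfull = np.broadcast_to(tw[:, None, :], yw.shape)
    tm = np.where(mask, tfull, 0.0).sum(axis=2) / np.maximum(cnt, 1)
    ym = np.where(mask, yw, 0.0).sum(axis=2) / np.maximum(cnt, 1)
    dt = np.where(mask, tfull - tm[:, :, None], 0.0)
    dy = np.where(mask, yw - ym[:, :, None], 0.0)
    sxx = (dt * dt).sum(axis=2)
    sxy = (dt * dy).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
    resid2 = ((dy - slope[:, :, None] * dt) ** 2 * mask).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        rse = np.sqrt(np.maximum(resid2, 0.0) / (cnt - 2))
    slope = np.where(cnt >= 2, slope, np.nan)
    rse = np.where(cnt >= 3, rse, np.where(cnt == 2, 0.0, np.nan))
    cols = table.data.columns
    return SlopeTable(
        time=table.time[n:-n].copy(),
        slopes=pd.DataFrame(slope, columns=cols),
        residuals=pd.DataFrame(rse, columns=cols),
        window=n,
        time_unit=table.time_unit,
        value_unit=table.value_unit,
    )
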