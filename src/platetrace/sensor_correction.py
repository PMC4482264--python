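"""Two-step correction for sensors with an exponential calibration curve.

Optical sensors (e.g. luminescence-quenching dissolved-oxygen spots) whose
read-out x relates to the measured analyte y through x = P + S·e^(αy)
cannot be corrected by the classical divide-by-control/multiply-by-target
scheme: that is only exact for a linear calibration.  Instead the read-out
is first moved to the log domain, z = ln((x − P)/S), where per-sensor
miscalibration is (to good approximation) a multiplicative gain.

Step 1 (logarithmic recalibration) equalizes the gains: over a calibration
window where all sensors see the same, stable true value, the per-sensor
log-domain mean m_s and the plate mean m_p (mean of the m_s) are computed,
and every value is rescaled as

    x'_{t,s} = P + S · exp((m_p / m_s) · z_{t,s})

Step 2 (linear normalization) multiplies each recalibrated sensor by
target / (its calibration-window mean) so that every sensor reads exactly
the known target value over the window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .plate_io import AssayTable

__all__ = [
    "CalibrationModel",
    "CorrectionFactors",
    "to_log_domain",
    "from_log_domain",
    "compute_factors",
    "recalibrate",
    "normalize_to_target",
    "correct_sensors",
    "estimate_calibration",
    "CalibrationDegenerateWarning",
]


class CalibrationDegenerateWarning(UserWarning):
    """The exponential calibration fit is indistinguishable from linear."""


@dataclass
class CalibrationModel:
    """Exponential calibration curve x = P + S·e^(αy).

    plateau (P) and span (S) share the measurement unit; alpha (α, per
    inverse analyte unit) is only needed when mapping read-out to analyte,
    not for the correction itself, where it cancels.  ``window`` is the
    [t_start, t_end] calibration interval with a stable true value.
    """

    plateau: float
    span: float
    alpha: float | None = None
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.plateau = float(self.plateau)
        self.span = float(self.span)
        if self.span == 0.0:
            raise ValueError("span S must be nonzero")
        if self.window is not None:
            t0, t1 = self.window
            if not t0 < t1:
                raise ValueError("calibration window must satisfy t_start < t_end")
            self.window = (float(t0), float(t1))

    def window_mask(self, time: np.ndarray, min_points: int = 2) -> np.ndarray:
        if self.window is None:
            raise ValueError("calibration model has no time window set")
        t0, t1 = self.window
        mask = (time >= t0) & (time <= t1)
        if mask.sum() < min_points:
            raise ValueError(
                f"calibration window [{t0}, {t1}] selects {int(mask.sum())} "
                f"time point(s); need at least {min_points}"
            )
        return mask


@dataclass
class CorrectionFactors:
    """Per-sensor log-domain means and the derived correction factors."""

    sensors: list[str]
    m_s: np.ndarray
    m_p: float
    n_window: int

    factors: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.m_s = np.asarray(self.m_s, dtype=float)
        if not np.all(np.isfinite(self.m_s)):
            raise ValueError("non-finite per-sensor log-domain mean")
        if np.any(self.m_s == 0.0):
            bad = [s for s, m in zip(self.sensors, self.m_s) if m == 0.0]
            raise ValueError(
                f"zero log-domain mean for sensor(s) {bad}; correction factor undefined"
            )
        self.factors = self.m_p / self.m_s


def _log_args(
    x: np.ndarray, calib: CalibrationModel, clip_epsilon: float | None,
    time: np.ndarray | None = None, sensors: list[str] | None = None,
) -> np.ndarray:
    u = (x - calib.plateau) / calib.span
    bad = u <= 0
    if bad.any():
        if clip_epsilon is not None:
            return np.maximum(u, clip_epsilon)
        cells = []
        idx = np.argwhere(bad)
        for i, j in idx[:10]:
            t = time[i] if time is not None else i
            s = sensors[j] if sensors is not None else j
            cells.append(f"(t={t}, sensor={s})")
        raise ValueError(
            f"{int(bad.sum())} value(s) at or below the calibration plateau; "
            f"log transform undefined at {', '.join(cells)}"
            + (" ..." if len(idx) > 10 else "")
        )
    return u


def to_log_domain(
    table: AssayTable, calib: CalibrationModel, *, clip_epsilon: float | None = None
) -> AssayTable:
    """z = ln((x − P)/S) elementwise.

    Values with (x − P)/S <= 0 raise, listing the offending (time, sensor)
    cells, unless ``clip_epsilon`` is given (the ratio is then clipped).
    """
    x = table.values()
    u = _log_args(x, calib, clip_epsilon, table.time, table.columns)
    z = np.log(u)
    return table.replace(data=pd.DataFrame(z, columns=table.data.columns))


def from_log_domain(table: AssayTable, calib: CalibrationModel) -> AssayTable:
    """Inverse of to_log_domain: x = P + S·e^z."""
    x = calib.plateau + calib.span * np.exp(table.values())
    return table.replace(data=pd.DataFrame(x, columns=table.data.columns))


def compute_factors(
    table: AssayTable, calib: CalibrationModel, *, clip_epsilon: float | None = None
) -> CorrectionFactors:
    """Per-sensor log-domain means over the calibration window and factors m_p/m_s."""
    mask = calib.window_mask(table.time)
    x = table.values()[mask]
    u = _log_args(x, calib, clip_epsilon, table.time[mask], table.columns)
    z = np.log(u)
    m_s = np.nanmean(z, axis=0)
    m_p = float(np.mean(m_s))
    return CorrectionFactors(
        sensors=table.columns, m_s=m_s, m_p=m_p, n_window=int(mask.sum())
    )


def recalibrate(
    table: AssayTable,
    calib: CalibrationModel,
    factors: CorrectionFactors,
    *,
    clip_epsilon: float | None = None,
) -> AssayTable:
    """Step 1: x' = P + S·exp((m_p/m_s)·z) elementwise."""
    if factors.sensors != table.columns:
        raise ValueError("correction factors were computed for different sensors")
    x = table.values()
    u = _log_args(x, calib, clip_epsilon, table.time, table.columns)
    z = np.log(u)
    x_corr = calib.plateau + calib.span * np.exp(factors.factors[None, :] * z)
    out = table.data.copy()
    out.iloc[:, :] = x_corr
    return table.replace(data=out)


def normalize_to_target(
    table: AssayTable, calib: CalibrationModel, target: float
) -> AssayTable:
    """Step 2: scale each sensor so its calibration-window mean equals target."""
    mask = calib.window_mask(table.time)
    means = np.nanmean(table.values()[mask], axis=0)
    if np.any(~np.isfinite(means)) or np.any(means == 0.0):
        bad = [
            s for s, m in zip(table.columns, means) if not np.isfinite(m) or m == 0.0
        ]
        raise ValueError(f"zero/undefined calibration-window mean for sensor(s) {bad}")
    scaled = table.values() * (float(target) / means)[None, :]
    out = table.data.copy()
    out.iloc[:, :] = scaled
    return table.replace(data=out)


def correct_sensors(
    table: AssayTable,
    calib: CalibrationModel,
    target: float,
    *,
    clip_epsilon: float | None = None,
) -> tuple[AssayTable, CorrectionFactors]:
    """Full two-step correction: recalibrate, then normalize to the target."""
    factors = compute_factors(table, calib, clip_epsilon=clip_epsilon)
    recal = recalibrate(table, calib, factors, clip_epsilon=clip_epsilon)
    return normalize_to_target(recal, calib, target), factors


# ---------------------------------------------------------------------------
# Calibration-curve estimation
# ---------------------------------------------------------------------------


def estimate_calibration(
    levels: list[tuple[float, np.ndarray]],
    *,
    degeneracy_rel_alpha: float = 1e-2,
) -> CalibrationModel:
    """Least-squares fit of x = P + S·e^(αy) to (true value, readings) pairs.

    ``levels`` holds at least 3 distinct true values y with the read-outs x
    observed there.  For fixed α the model is linear in (P, S), so α is
    profiled first on a coarse grid, refined by a scalar minimization, and
    the result polished by full nonlinear least squares.  Near-linear data
    (α·span(y) ≈ 0) triggers a degeneracy warning.
    """
    ys, xs = [], []
    for y, readings in levels:
        readings = np.asarray(readings, dtype=float).ravel()
        ys.append(np.full(readings.size, float(y)))
        xs.append(readings)
    y_all = np.concatenate(ys)
    x_all = np.concatenate(xs)
    n_levels = np.unique(y_all).size
    if n_levels < 3:
        raise ValueError(
            f"need >= 3 distinct calibration levels to estimate (P, S, alpha); got {n_levels}"
        )
    yspan = float(y_all.max() - y_all.min())

    def profile(alpha: float) -> tuple[float, float, float]:
        design = np.column_stack([np.ones_like(y_all), np.exp(alpha * y_all)])
        coef, *_ = np.linalg.lstsq(design, x_all, rcond=None)
        resid = x_all - design @ coef
        return float(resid @ resid), float(coef[0]), float(coef[1])

    grid = np.concatenate([-np.geomspace(20 / yspan, 1e-4 / yspan, 60),
                           np.geomspace(1e-4 / yspan, 20 / yspan, 60)])
    sses = [profile(a)[0] for a in grid]
    i = int(np.argmin(sses))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda a: profile(a)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12 / yspan},
    )
    alpha = float(res.x)
    _, P, S = profile(alpha)

    def model(y, P, S, alpha):
        return P + S * np.exp(alpha * y)

    if not np.isfinite([P, S, alpha]).all():
        raise RuntimeError(
            "calibration fit did not converge; enter plateau P and span S manually"
        )
    try:
        popt, _ = optimize.curve_fit(
            model, y_all, x_all, p0=[P, S, alpha], maxfev=20000
        )
        if np.isfinite(popt).all():
            P, S, alpha = map(float, popt)
    except RuntimeError:
        # keep the (already least-squares-optimal) profiled solution
        pass

    if abs(alpha) * yspan < degeneracy_rel_alpha:
        warnings.warn(
            "calibration data is consistent with a linear relationship "
            f"(|alpha|*range(y) = {abs(alpha) * yspan:.2e}); exponential "
            "correction is unnecessary or ill-determined",
            CalibrationDegenerateWarning,
            stacklevel=2,
        )
    return CalibrationModel(plateau=P, span=S, alpha=alpha)
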