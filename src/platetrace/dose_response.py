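"""Log-logistic dose-response fitting and the time-resolved IC50/EC50.

The model family is the standard log-logistic sigmoid

    f(x) = c + (d - c) / (1 + (x/e)^b)^g

with slope b, lower limit c, upper limit d, inflection e (the IC50/EC50)
and asymmetry g.  Members: LL2 fixes c=0, d=1, g=1; LL3 fixes c=0, g=1;
LL4 fixes g=1 (the common four-parameter logistic); LL5 frees all five.
Writing (x/e)^b instead of exp(b(log x − log e)) makes the model total on
x >= 0: at dose zero the limit is d for b > 0 and c for b < 0, so untreated
wells enter the fit without ever taking log(0).

A time-resolved IC50 is obtained by fitting the chosen family to the
responses of all dose groups at every selected time point and tracing the
fitted e parameter over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .plate_io import AssayTable, PlateLayout

__all__ = [
    "FAMILIES",
    "LogLogisticModel",
    "DoseResponseFit",
    "IC50Trajectory",
    "loglogistic_eval",
    "fit_dose_response",
    "fit_ic50_over_time",
]

# free parameters per family; the rest are fixed (c=0, d=1, g=1)
FAMILIES: dict[str, tuple[str, ...]] = {
    "LL2": ("b", "e"),
    "LL3": ("b", "d", "e"),
    "LL4": ("b", "c", "d", "e"),
    "LL5": ("b", "c", "d", "e", "g"),
}

_FIXED = {"b": None, "c": 0.0, "d": 1.0, "e": None, "g": 1.0}


def loglogistic_eval(
    x, b: float, c: float, d: float, e: float, g: float = 1.0
) -> np.ndarray | float:
    """Evaluate f(x) = c + (d−c)/(1+(x/e)^b)^g, total on x >= 0."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any(x < 0):
        raise ValueError("doses must be nonnegative")
    if e <= 0:
        raise ValueError("inflection e must be positive")
    out = np.empty_like(x)
    zero = x == 0.0
    if b > 0:
        out[zero] = d
    elif b < 0:
        out[zero] = c
    else:
        out[zero] = c + (d - c) / 2.0 ** g
    pos = ~zero
    with np.errstate(over="ignore"):
        ratio = (x[pos] / e) ** b
    out[pos] = c + (d - c) / (1.0 + ratio) ** g
    return float(out[0]) if scalar else out


@dataclass
class LogLogisticModel:
    """A fully specified member of the log-logistic family."""

    family: str = "LL4"
    b: float = 1.0
    c: float = 0.0
    d: float = 1.0
    e: float = 1.0
    g: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected {list(FAMILIES)}")
        if self.e <= 0:
            raise ValueError("inflection e must be positive")
        if self.family == "LL5" and self.g <= 0:
            raise ValueError("asymmetry g must be positive")

    def predict(self, x) -> np.ndarray | float:
        return loglogistic_eval(x, self.b, self.c, self.d, self.e, self.g)


@dataclass
class DoseResponseFit:
    """One converged (or honestly flagged) fit at a single time point."""

    family: str
    params: dict[str, float]
    se: dict[str, float]
    rse: float
    converged: bool
    n_obs: int
    time: float | None = None
    message: str = ""

    @property
    def ic50(self) -> float:
        return self.params["e"]

    def model(self) -> LogLogisticModel:
        return LogLogisticModel(family=self.family, **self.params)


@dataclass(eq=False)
class IC50Trajectory:
    """The fitted e parameter (IC50/EC50) as a function of time."""

    time: np.ndarray
    e: np.ndarray
    se: np.ndarray
    converged: np.ndarray
    time_unit: str = "s"
    dose_unit: str = ""

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                f"time [{self.time_unit}]": self.time,
                "ic50": self.e,
                "ic50_se": self.se,
                "converged": self.converged.astype(bool),
            }
        )


def _default_init(doses: np.ndarray, responses: np.ndarray, family: str) -> dict[str, float]:
    c0 = float(np.min(responses))
    d0 = float(np.max(responses))
    if family == "LL2":
        c0, d0 = 0.0, 1.0
    elif family == "LL3":
        c0 = 0.0
    mid = (c0 + d0) / 2.0
    pos = doses > 0
    if pos.any():
        cand = doses[pos]
        e0 = float(cand[np.argmin(np.abs(responses[pos] - mid))])
    else:
        e0 = 1.0
    # decreasing response with dose -> b > 0 in this parameterization
    order = np.argsort(doses)
    trend = responses[order][-1] - responses[order][0]
    b0 = 1.0 if trend < 0 else -1.0
    return {"b": b0, "c": c0, "d": d0, "e": e0, "g": 1.0}


def fit_dose_response(
    doses,
    responses,
    family: str = "LL4",
    init_overrides: dict[str, float] | None = None,
    *,
    time: float | None = None,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> DoseResponseFit:
    """Nonlinear least-squares fit of a log-logistic model to one dose set.

    Internally the model is parameterized as (b, c, Δ=d−c, log(e/e0)),
    which enforces d >= c and e > 0 and makes the optimization invariant
    under a joint rescaling of all doses (so the fitted e scales exactly
    with the dose unit).  Standard errors come from the Jacobian at the
    optimum; non-convergence or degeneracy is flagged, never raised, so a
    trajectory of fits can continue past a bad time point.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected {list(FAMILIES)}")
    doses = np.asarray(doses, dtype=float).ravel()
    responses = np.asarray(responses, dtype=float).ravel()
    if doses.size != responses.size:
        raise ValueError("doses and responses differ in length")
    ok = np.isfinite(doses) & np.isfinite(responses)
    doses, responses = doses[ok], responses[ok]
    free = FAMILIES[family]
    n_free = len(free)
    if np.unique(doses).size < n_free + 1:
        raise ValueError(
            f"{family} needs at least {n_free + 1} distinct doses; "
            f"got {np.unique(doses).size}"
        )

    init = _default_init(doses, responses, family)
    if init_overrides:
        init.update(init_overrides)

    span = float(np.max(responses) - np.min(responses))
    scale = max(abs(float(np.max(responses))), abs(float(np.min(responses))), 1e-300)
    if span <= 1e-12 * scale:
        return DoseResponseFit(
            family=family,
            params={
                k: init[k]
                for k in ("b", "c", "d", "e", "g")
                if k != "g" or family == "LL5"
            },
            se={k: float("nan") for k in free},
            rse=0.0,
            converged=False,
            n_obs=int(doses.size),
            time=time,
            message="degenerate: responses show no dose effect",
        )

    e0 = init["e"]
    max_dose = float(np.max(doses[doses > 0], initial=e0))
    # internal vector: free parameters, with d -> delta = d - c, e -> log(e/e0)
    names = list(free)
    x0, lo, hi = [], [], []
    for name in names:
        if name == "b":
            x0.append(init["b"]); lo.append(-50.0); hi.append(50.0)
        elif name == "c":
            x0.append(init["c"]); lo.append(-np.inf); hi.append(np.inf)
        elif name == "d":
            base_c = init["c"] if "c" in free else _FIXED["c"]
            x0.append(max(init["d"] - base_c, 1e-12)); lo.append(0.0); hi.append(np.inf)
        elif name == "e":
            x0.append(0.0)
            lo.append(np.log(1e-6))
            hi.append(np.log(10.0 * max_dose / e0))
        elif name == "g":
            x0.append(np.log(init["g"])); lo.append(np.log(1e-3)); hi.append(np.log(1e3))
    x0 = np.asarray(x0, dtype=float)
    x0 = np.clip(x0, lo, hi)

    def unpack(vec: np.ndarray) -> tuple[float, float, float, float, float]:
        p = dict(zip(names, vec))
        b = p.get("b", 1.0)
        c = p.get("c", _FIXED["c"])
        d = c + p["d"] if "d" in p else _FIXED["d"]
        e = e0 * np.exp(p["e"])
        g = np.exp(p["g"]) if "g" in p else 1.0
        return b, c, d, e, g

    def resid(vec: np.ndarray) -> np.ndarray:
        b, c, d, e, g = unpack(vec)
        return loglogistic_eval(doses, b, c, d, e, g) - responses

    res = least_squares(
        resid, x0, bounds=(lo, hi), method="trf",
        ftol=tol, xtol=tol, gtol=tol, max_nfev=max_iter * (len(names) + 1),
    )
    b, c, d, e, g = unpack(res.x)
    params = {"b": float(b), "c": float(c), "d": float(d), "e": float(e)}
    if family == "LL5":
        params["g"] = float(g)

    m, p = doses.size, len(names)
    dof = max(m - p, 1)
    rse = float(np.sqrt(2.0 * res.cost / dof))

    # covariance of the internal parameters, then delta-method transform
    se = {k: float("nan") for k in params}
    converged = bool(res.success) and np.all(np.isfinite(res.x))
    try:
        JTJ = res.jac.T @ res.jac
        cov_int = rse**2 * np.linalg.pinv(JTJ)
        # external params as functions of internal ones: jacobian T
        T = np.zeros((len(params), p))
        pnames = list(params)
        for j, name in enumerate(names):
            if name == "b":
                T[pnames.index("b"), j] = 1.0
            elif name == "c":
                T[pnames.index("c"), j] = 1.0
                T[pnames.index("d"), j] = 1.0  # d = c + delta
            elif name == "d":
                T[pnames.index("d"), j] = 1.0
            elif name == "e":
                T[pnames.index("e"), j] = params["e"]  # de/dloge = e
            elif name == "g":
                T[pnames.index("g"), j] = params["g"]
        cov_ext = T @ cov_int @ T.T
        for i, k in enumerate(pnames):
            if k in free or k in ("c", "d"):
                v = cov_ext[i, i]
                se[k] = float(np.sqrt(v)) if v >= 0 else float("nan")
        for k in set(params) - set(free):
            se[k] = 0.0 if k in ("c", "d", "g") and k not in free else se[k]
    except np.linalg.LinAlgError:  # pragma: no cover
        converged = False

    return DoseResponseFit(
        family=family,
        params=params,
        se=se,
        rse=rse,
        converged=converged,
        n_obs=int(m),
        time=time,
        message=str(res.message),
    )


def fit_ic50_over_time(
    table: AssayTable,
    layout: PlateLayout,
    family: str = "LL4",
    time_window: tuple[float, float] | None = None,
    stride: int = 1,
    *,
    use_replicates: bool = False,
    init_overrides: dict[str, float] | None = None,
) -> tuple[IC50Trajectory, list[DoseResponseFit]]:
    """Fit the dose-response model at every selected time point.

    By default each dose's replicate columns are averaged first and the fit
    runs on one response per dose (fit to the averaged data); with
    ``use_replicates`` every replicate point enters the fit individually.
    Failed fits are flagged and become gaps in the trajectory, not errors.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected {list(FAMILIES)}")
    stride = int(stride)
    if stride < 1:
        raise ValueError("stride must be >= 1 time steps")
    layout.validate_against(table)
    col_doses = layout.doses()  # raises if a sample column lacks a dose
    if not col_doses:
        raise ValueError("layout defines no sample columns with doses")
    n_free = len(FAMILIES[family])
    n_distinct = np.unique(list(col_doses.values())).size
    if n_distinct < n_free + 1:
        raise ValueError(
            f"{family} needs at least {n_free + 1} distinct doses; layout has {n_distinct}"
        )

    idx = np.arange(table.n_points)
    if time_window is not None:
        t0, t1 = time_window
        idx = idx[(table.time >= t0) & (table.time <= t1)]
        if idx.size == 0:
            raise ValueError(f"no time points inside window [{t0}, {t1}]")
    idx = idx[::stride]

    if use_replicates:
        cols = list(col_doses)
        dose_vec = np.array([col_doses[c] for c in cols])
        resp = table.data[cols].to_numpy()
    else:
        group_doses = layout.group_doses()
        groups = [g for g in group_doses]
        dose_vec = np.array([group_doses[g] for g in groups])
        gcols = layout.groups()
        resp = np.column_stack(
            [
                table.data[[c for c in gcols[g] if layout.wells[c].role == "sample"]]
                .mean(axis=1, skipna=True)
                .to_numpy()
                for g in groups
            ]
        )

    fits: list[DoseResponseFit] = []
    for i in idx:
        t = float(table.time[i])
        r = resp[i]
        ok = np.isfinite(r)
        if np.unique(dose_vec[ok]).size < n_free + 1:
            fits.append(
                DoseResponseFit(
                    family=family,
                    params={k: float("nan") for k in ("b", "c", "d", "e")},
                    se={},
                    rse=float("nan"),
                    converged=False,
                    n_obs=int(ok.sum()),
                    time=t,
                    message="too few valid doses at this time point",
                )
            )
            continue
        fits.append(
            fit_dose_response(
                dose_vec[ok], r[ok], family, init_overrides, time=t
            )
        )

    traj = IC50Trajectory(
        time=np.array([f.time for f in fits], dtype=float),
        e=np.array([f.params.get("e", np.nan) for f in fits], dtype=float),
        se=np.array([f.se.get("e", np.nan) for f in fits], dtype=float),
        converged=np.array([f.converged for f in fits], dtype=bool),
        time_unit=table.time_unit,
    )
    return traj, fits
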