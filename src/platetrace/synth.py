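"""Synthetic plates with the statistical structure the method assumes.

The generator emulates a 24-well dissolved-oxygen sensor plate read out in
an incubator: each well's sensor has a slightly different gain, modelled as
a multiplicative factor in the log domain of the exponential calibration
curve — exactly the error structure the logarithmic recalibration inverts.
On top of that a drug-treatment experiment is emulated phenomenologically:
cells seeded into wells consume oxygen (seeding dip, medium-change
recovery), and from the treatment time onward the viable fraction of each
well follows a log-logistic dose–death law whose inflection e(t) decays
over time, so the true time-resolved IC50 is known by construction.

Everything is a pure function of the configuration (same seed, same bytes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_response import loglogistic_eval
from .plate_io import AssayTable, PlateLayout, WellSpec
from .sensor_correction import CalibrationModel

__all__ = [
    "SimConfig",
    "true_ic50",
    "simulate_empty_plate",
    "simulate_treatment_experiment",
    "simulate_dose_response_surface",
]

#: dose series used throughout (μM), highest to vehicle control
DEFAULT_DOSES = (300.0, 200.0, 100.0, 90.0, 80.0, 70.0, 60.0, 50.0, 40.0, 30.0, 20.0, 10.0, 0.0)


@dataclass
class SimConfig:
    """Study conditions for the synthetic plates.

    Defaults mirror the emulated experiment: 24 sensors, per-sensor
    log-domain gain uniform in 1±0.05, additive reader noise of 0.3% a.s.,
    ambient oxygen 91.3% a.s., 13 doses in triplicate plus 3 medium-only
    wells, a 10-minute measuring interval over 5 days, treatment at day
    2.1, and a true IC50 decaying from 80 μM (day 2.5) to 30 μM (day 4.7).
    """

    n_sensors: int = 24
    gain_delta: float = 0.05          # gains ~ U(1-δ, 1+δ) in the log domain
    plateau: float = 1.0              # calibration P, % a.s.
    span: float = 2.0                 # calibration S, % a.s.
    noise_sd: float = 0.3             # additive reader noise, % a.s.
    seed: int = 0

    doses: tuple[float, ...] = DEFAULT_DOSES
    dose_unit: str = "uM"
    replicates: int = 3
    n_medium: int = 3

    interval_days: float = 1.0 / 144.0  # 10-minute measuring interval
    calib_interval_days: float = 1.0 / 1440.0  # 1-minute interval while calibrating
    duration_days: float = 5.0
    ambient: float = 91.3             # % a.s. of air-equilibrated medium
    medium_drift: float = 0.5         # % a.s. per day, medium-only wells
    seed_time: float = 136.0 / 1440.0  # cells seeded after the calibration segment
    medium_change_time: float = 1.09  # medium change (day)
    treat_time: float = 2.1           # drug addition (day)
    depth_max: float = 40.0           # untreated consumption depth, % a.s.
    hill_b: float = 2.0               # dose–death slope
    e_start: float = 80.0             # true IC50 at e_t_start (μM)
    e_end: float = 30.0               # true IC50 at e_t_end (μM)
    e_t_start: float = 2.5
    e_t_end: float = 4.7
    calib_points: int = 10            # stable pre-seeding points for correction

    def __post_init__(self) -> None:
        if self.gain_delta < 0:
            raise ValueError("gain_delta must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def calibration(self) -> CalibrationModel:
        """Calibration model windowed over the pre-seeding (empty-plate) segment."""
        t_hi = self.seed_time - 0.25 * self.calib_interval_days
        return CalibrationModel(
            plateau=self.plateau, span=self.span, window=(0.0, t_hi)
        )


def true_ic50(config: SimConfig, t: np.ndarray | float) -> np.ndarray | float:
    """Programmed IC50 trajectory: exponential decay through the endpoints."""
    k = np.log(config.e_start / config.e_end) / (config.e_t_end - config.e_t_start)
    t = np.asarray(t, dtype=float)
    return config.e_start * np.exp(-k * np.maximum(t - config.e_t_start, 0.0))


def _read_out(
    o: np.ndarray, gains: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Map true values through per-sensor gains and add reader noise.

    o has shape (T, W); gains (W,).  Gain g acts in the log domain:
    x = P + S·exp(g·ln((o−P)/S)).
    """
    P, S = config.plateau, config.span
    u = (o - P) / S
    if np.any(u <= 0):
        raise ValueError("true level at or below the calibration plateau")
    x = P + S * np.exp(gains[None, :] * np.log(u))
    if config.noise_sd > 0:
        x = x + rng.normal(0.0, config.noise_sd, size=x.shape)
    return x


def simulate_empty_plate(
    config: SimConfig,
    levels: tuple[float, ...] = (91.3, 72.1, 48.1, 24.0, 4.8),
    points_per_level: int = 20,
) -> AssayTable:
    """Empty plate stepped through constant true levels, equal-length segments.

    Emulates moving an empty sensor plate through a series of controlled
    oxygen setpoints: every sensor should read each level exactly, but the
    per-sensor gains spread the raw read-out.
    """
    levels = tuple(float(v) for v in levels)
    if any(v <= config.plateau for v in levels):
        bad = [v for v in levels if v <= config.plateau]
        raise ValueError(f"level(s) {bad} at or below the plateau {config.plateau}")
    rng = np.random.default_rng(config.seed)
    gains = rng.uniform(1.0 - config.gain_delta, 1.0 + config.gain_delta, config.n_sensors)
    n_t = points_per_level * len(levels)
    time = np.arange(n_t) * config.interval_days
    o = np.repeat(np.asarray(levels), points_per_level)[:, None]
    o = np.broadcast_to(o, (n_t, config.n_sensors)).copy()
    x = _read_out(o, gains, config, rng)
    cols = [f"S{i + 1:02d}" for i in range(config.n_sensors)]
    return AssayTable(
        time=time,
        data=pd.DataFrame(x, columns=cols),
        time_unit="day",
        value_unit="% a.s.",
    )


def _consumption_depth(t: np.ndarray, config: SimConfig) -> np.ndarray:
    """Oxygen-consumption depth of untreated cells over time (% a.s.).

    Phenomenological: zero before seeding; a steep attachment dip after
    seeding; partial recovery at the medium change; then a slower return to
    the basal consumption depth ``depth_max``.
    """
    t = np.asarray(t, dtype=float)
    d = np.zeros_like(t)
    seeding = 1.0 / (1.0 + np.exp(-(t - (config.seed_time + 0.35)) / 0.08))
    d = 50.0 * seeding
    after_mc = t >= config.medium_change_time
    regrow = 1.0 / (1.0 + np.exp(-(t - (config.medium_change_time + 0.5)) / 0.12))
    d = np.where(after_mc, 20.0 + (config.depth_max - 20.0) * regrow, d)
    d[t < config.seed_time] = 0.0
    return d


def simulate_treatment_experiment(config: SimConfig | None = None) -> tuple[AssayTable, PlateLayout]:
    """Dose-treatment experiment: doses × replicates plus medium-only wells.

    Per sample well the true oxygen is ambient − depth(t)·v(t, dose) with
    viable fraction v = 1/(1+(dose/e(t))^b): at any fixed time the
    replicate-mean response is exactly log-logistic in dose with inflection
    e(t), so downstream fits have a known truth.  Medium wells track
    ambient oxygen with a slow linear upward drift starting at seeding.
    Wells differ by sensor gain and reader noise only.
    """
    config = config or SimConfig()
    if not config.doses:
        raise ValueError("dose list must be non-empty")
    rng = np.random.default_rng(config.seed)
    n_wells = len(config.doses) * config.replicates + config.n_medium
    gains = rng.uniform(1.0 - config.gain_delta, 1.0 + config.gain_delta, n_wells)

    # fine-grained read-out while the empty plate equilibrates (sensor
    # calibration), then the regular measuring interval for the experiment
    n_cal = int(round(config.seed_time / config.calib_interval_days))
    t_cal = np.arange(n_cal) * config.calib_interval_days
    first = t_cal[-1] + config.interval_days if n_cal else 0.0
    t_rest = np.arange(first, config.duration_days + 1e-12, config.interval_days)
    time = np.concatenate([t_cal, t_rest])
    n_t = time.size
    depth = _consumption_depth(time, config)
    e_t = np.asarray(true_ic50(config, time))

    cols: list[str] = []
    wells: dict[str, WellSpec] = {}
    o = np.empty((n_t, n_wells))
    w = 0
    treated = time >= config.treat_time
    for di, dose in enumerate(config.doses):
        with np.errstate(divide="ignore"):
            ratio = np.where(e_t > 0, (dose / e_t) ** config.hill_b, np.inf)
        v = np.where(treated, 1.0 / (1.0 + ratio), 1.0)
        profile = config.ambient - depth * v
        label = f"{dose:g} {config.dose_unit}"
        for r in range(config.replicates):
            name = f"D{dose:g}_r{r + 1}"
            cols.append(name)
            o[:, w] = profile
            wells[name] = WellSpec(
                label=label,
                group=label,
                role="sample",
                dose=dose,
                dose_unit=config.dose_unit,
                color=f"C{di % 10}",
                legend=label,
            )
            w += 1
    drift = config.medium_drift * np.maximum(time - config.seed_time, 0.0)
    for r in range(config.n_medium):
        name = f"MED_r{r + 1}"
        cols.append(name)
        o[:, w] = config.ambient + drift
        wells[name] = WellSpec(
            label="medium",
            group="medium",
            role="medium_control",
            color="0.4",
            linetype="dashed",
            legend="medium only",
        )
        w += 1

    x = _read_out(o, gains, config, rng)
    table = AssayTable(
        time=time,
        data=pd.DataFrame(x, columns=cols),
        time_unit="day",
        value_unit="% a.s.",
    )
    return table, PlateLayout(wells=wells)


def simulate_dose_response_surface(
    family: str,
    params_of_t,
    doses,
    times,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Direct dose-response surface: rows = times, columns = doses.

    ``params_of_t(t)`` returns the model parameter dict (b, c, d, e[, g])
    at time t; responses are the exact model values plus Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    doses = np.asarray(doses, dtype=float)
    times = np.asarray(times, dtype=float)
    out = np.empty((times.size, doses.size))
    for i, t in enumerate(times):
        p = dict(params_of_t(float(t)))
        out[i] = loglogistic_eval(
            doses, p["b"], p.get("c", 0.0), p.get("d", 1.0), p["e"], p.get("g", 1.0)
        )
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return pd.DataFrame(out, index=times, columns=doses)
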