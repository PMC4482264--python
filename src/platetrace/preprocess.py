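"""Basic formatting: time-unit conversion, trimming, origin shift, scaling."""

from __future__ import annotations

from fractions import Fraction

import numpy as np

from .plate_io import TIME_UNITS_S, AssayTable

__all__ = [
    "convert_time_units",
    "trim_time_range",
    "shift_time_origin",
    "scale_values",
]


def _unit_ratio(from_unit: str, to_unit: str) -> float:
    for u in (from_unit, to_unit):
        if u not in TIME_UNITS_S:
            raise ValueError(
                f"unknown time unit {u!r}; expected one of {sorted(TIME_UNITS_S)}"
            )
    # exact rational ratio so convert∘convert⁻¹ is the identity
    ratio = Fraction(int(TIME_UNITS_S[from_unit])) / Fraction(int(TIME_UNITS_S[to_unit]))
    return float(ratio.numerator) / float(ratio.denominator)


def convert_time_units(table: AssayTable, from_unit: str, to_unit: str) -> AssayTable:
    """Rescale the time vector by the exact unit ratio; values untouched."""
    ratio = _unit_ratio(from_unit, to_unit)
    if from_unit == to_unit:
        return table.replace(time_unit=to_unit)
    frac = Fraction(int(TIME_UNITS_S[from_unit]), int(TIME_UNITS_S[to_unit]))
    if frac.denominator == 1:
        time = table.time * frac.numerator
    elif frac.numerator == 1:
        time = table.time / frac.denominator
    else:
        time = table.time * ratio
    return table.replace(time=time, time_unit=to_unit)


def trim_time_range(table: AssayTable, t_min: float, t_max: float) -> AssayTable:
    """Keep only rows with t_min <= t <= t_max (closed interval)."""
    if not t_min < t_max:
        raise ValueError(f"t_min ({t_min}) must be < t_max ({t_max})")
    keep = (table.time >= t_min) & (table.time <= t_max)
    if not keep.any():
        raise ValueError(
            f"no time points in [{t_min}, {t_max}] "
            f"(data covers [{table.time[0]}, {table.time[-1]}])"
        )
    return table.replace(
        time=table.time[keep], data=table.data.loc[keep].reset_index(drop=True)
    )


def shift_time_origin(table: AssayTable, offset: float) -> AssayTable:
    """Shift the time axis: time' = time - offset (negative times allowed)."""
    return table.replace(time=table.time - float(offset))


def scale_values(table: AssayTable, factor: float, new_unit: str | None = None) -> AssayTable:
    """Multiply every measurement by a fixed factor (unit change)."""
    factor = float(factor)
    if not np.isfinite(factor) or factor == 0.0:
        raise ValueError("scale factor must be finite and nonzero")
    out = table.replace(data=table.data * factor)
    if new_unit is not None:
        out = out.replace(value_unit=new_unit)
    return out
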