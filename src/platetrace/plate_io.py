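"""Reading and writing assay tables, plate layouts and analysis settings.

An assay table is a plain CSV with a header row: the first column holds the
time stamps of the experiment, every further column the time-resolved
read-out of one well/sensor.  The plate layout is a separate YAML file
mapping each data column to a condition label, replicate group, role and
(optionally) a dose — it drives replicate averaging, reference detection
and dose-response fitting downstream.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AssayTable",
    "WellSpec",
    "PlateLayout",
    "AnalysisSettings",
    "CorrectionSettings",
    "FormatSettings",
    "IC50Settings",
    "ROLES",
    "read_assay_csv",
    "write_table_csv",
    "read_layout",
    "write_layout",
    "save_settings",
    "load_settings",
]

ROLES = ("sample", "reference", "medium_control", "excluded")

TIME_UNITS_S = {"s": 1.0, "min": 60.0, "h": 3600.0, "day": 86400.0}

_TIME_HEADER_RE = re.compile(r"^time(?:\s*\[(?P<unit>[^\]]+)\])?$", re.IGNORECASE)


@dataclass(eq=False)
class AssayTable:
    """A shared time vector plus one measurement column per well/sensor.

    Invariants (checked on construction): all columns have the same length
    as the time vector, time is strictly increasing, column names unique.
    """

    time: np.ndarray
    data: pd.DataFrame
    time_unit: str = "s"
    value_unit: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1:
            raise ValueError("time must be a 1-D vector")
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        self.data = self.data.reset_index(drop=True).astype(float)
        if len(self.data) != self.time.size:
            raise ValueError(
                f"column length {len(self.data)} != time length {self.time.size}"
            )
        dup = self.data.columns[self.data.columns.duplicated()].tolist()
        if dup:
            raise ValueError(f"duplicate column names: {dup}")
        bad = np.nonzero(np.diff(self.time) <= 0)[0]
        if bad.size:
            rows = ", ".join(str(i + 1) for i in bad[:10])
            raise ValueError(
                f"time vector not strictly increasing at row(s) {rows}"
            )

    # -- convenience -------------------------------------------------------

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_points(self) -> int:
        return int(self.time.size)

    def replace(self, **kwargs) -> "AssayTable":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)

    def select_columns(self, names: Sequence[str]) -> "AssayTable":
        missing = [c for c in names if c not in self.data.columns]
        if missing:
            raise KeyError(f"unknown columns: {missing}")
        return self.replace(data=self.data[list(names)].copy())

    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def equals(self, other: "AssayTable", rtol: float = 0.0, atol: float = 0.0) -> bool:
        return (
            self.columns == other.columns
            and np.allclose(self.time, other.time, rtol=rtol, atol=atol)
            and np.allclose(
                self.values(), other.values(), rtol=rtol, atol=atol, equal_nan=True
            )
        )


def read_assay_csv(
    paths: str | Path | Sequence[str | Path],
    *,
    sep: str = ",",
    decimal: str = ".",
    skiprows: int = 0,
    time_unit: str | None = None,
    value_unit: str = "",
    merge_atol: float = 1e-9,
) -> AssayTable:
    """Read one or more assay CSVs (first column = time) into an AssayTable.

    Non-numeric measurement cells become missing values.  Several files may
    be given; they must share an identical time vector (within
    ``merge_atol``) and are merged column-wise.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if not paths:
        raise ValueError("no input files given")

    tables: list[tuple[np.ndarray, pd.DataFrame, str | None]] = []
    for p in paths:
        with open(p) as fh:
            for _ in range(skiprows):
                fh.readline()
            header = fh.readline().rstrip("\n").split(sep)
        dups = sorted({h for h in header if header.count(h) > 1})
        if dups:
            raise ValueError(f"{p}: duplicate column names: {dups}")
        df = pd.read_csv(
            p, sep=sep, decimal=decimal, skiprows=skiprows,
            float_precision="round_trip",
        )
        if df.shape[1] < 2:
            raise ValueError(f"{p}: need a time column plus at least one data column")
        tcol = df.columns[0]
        t = pd.to_numeric(df[tcol], errors="coerce").to_numpy()
        if np.isnan(t).any():
            rows = np.nonzero(np.isnan(t))[0] + 2  # 1-based + header
            raise ValueError(f"{p}: non-numeric time values at line(s) {rows[:10].tolist()}")
        body = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
        m = _TIME_HEADER_RE.match(str(tcol).strip())
        unit = m.group("unit") if m else None
        tables.append((t, body, unit))

    t0, body0, unit0 = tables[0]
    merged = body0
    for t, body, _ in tables[1:]:
        if t.size != t0.size or not np.allclose(t, t0, rtol=0.0, atol=merge_atol):
            raise ValueError(
                "input files do not share an identical time vector; cannot merge"
            )
        merged = pd.concat([merged, body], axis=1)

    unit = time_unit or unit0 or "s"
    return AssayTable(time=t0, data=merged, time_unit=unit, value_unit=value_unit)


def write_table_csv(table: AssayTable, path: str | Path) -> Path:
    """Write an AssayTable to CSV; round-trips through read_assay_csv."""
    path = Path(path)
    out = pd.DataFrame({f"time [{table.time_unit}]": table.time})
    out = pd.concat([out, table.data.reset_index(drop=True)], axis=1)
    out.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Plate layout
# ---------------------------------------------------------------------------


@dataclass
class WellSpec:
    """Metadata for one data column of an assay table."""

    label: str = ""
    group: str = ""
    role: str = "sample"
    dose: float | None = None
    dose_unit: str = ""
    color: str = ""
    linetype: str = "solid"
    legend: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.dose is not None:
            self.dose = float(self.dose)
            if self.dose < 0:
                raise ValueError("dose must be nonnegative")
        if not self.group:
            self.group = self.label


@dataclass
class PlateLayout:
    """Per-column condition labels, replicate groups, roles and doses."""

    wells: dict[str, WellSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, spec in self.wells.items():
            if spec.role != "excluded" and not spec.group:
                raise ValueError(f"column {name!r}: empty replicate group")

    # -- queries -----------------------------------------------------------

    def active_columns(self) -> list[str]:
        return [c for c, s in self.wells.items() if s.role != "excluded"]

    def columns_with_role(self, *roles: str) -> list[str]:
        return [c for c, s in self.wells.items() if s.role in roles]

    def reference_columns(self) -> list[str]:
        return self.columns_with_role("reference", "medium_control")

    def sample_columns(self) -> list[str]:
        return self.columns_with_role("sample")

    def groups(self) -> dict[str, list[str]]:
        """Replicate groups over non-excluded columns, in layout order."""
        out: dict[str, list[str]] = {}
        for c, s in self.wells.items():
            if s.role == "excluded":
                continue
            out.setdefault(s.group, []).append(c)
        return out

    def doses(self) -> dict[str, float]:
        """Dose per sample column; raises if any sample column lacks one."""
        missing = [c for c in self.sample_columns() if self.wells[c].dose is None]
        if missing:
            raise ValueError(f"sample column(s) without dose: {missing}")
        return {c: float(self.wells[c].dose) for c in self.sample_columns()}

    def group_doses(self) -> dict[str, float]:
        """Dose per replicate group of sample columns (must be consistent)."""
        doses = self.doses()
        out: dict[str, float] = {}
        for g, cols in self.groups().items():
            scols = [c for c in cols if self.wells[c].role == "sample"]
            if not scols:
                continue
            vals = {doses[c] for c in scols}
            if len(vals) > 1:
                raise ValueError(f"replicate group {g!r} mixes doses {sorted(vals)}")
            out[g] = vals.pop()
        return out

    def validate_against(self, table: AssayTable, *, require_doses: bool = False) -> None:
        """Check that the layout and table describe the same columns."""
        tcols = set(table.columns)
        lcols = set(self.wells)
        extra = sorted(lcols - tcols)
        missing = sorted(tcols - lcols)
        if extra or missing:
            parts = []
            if extra:
                parts.append(f"layout columns absent from table: {extra}")
            if missing:
                parts.append(f"table columns absent from layout: {missing}")
            raise ValueError("; ".join(parts))
        if require_doses:
            self.doses()


def read_layout(path: str | Path) -> PlateLayout:
    """Parse a YAML plate-layout file into a validated PlateLayout."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping) or "columns" not in raw:
        raise ValueError(f"{path}: layout file must contain a 'columns' mapping")
    wells = {}
    for name, entry in raw["columns"].items():
        entry = dict(entry or {})
        unknown = set(entry) - {f.name for f in dataclasses.fields(WellSpec)}
        if unknown:
            raise ValueError(f"{path}: column {name!r} has unknown keys {sorted(unknown)}")
        wells[str(name)] = WellSpec(**entry)
    return PlateLayout(wells=wells)


def write_layout(layout: PlateLayout, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "columns": {
            name: {
                k: v
                for k, v in dataclasses.asdict(spec).items()
                if v not in (None, "")
            }
            for name, spec in layout.wells.items()
        }
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


# ---------------------------------------------------------------------------
# Analysis settings
# ---------------------------------------------------------------------------


@dataclass
class FormatSettings:
    convert_from: str | None = None
    convert_to: str | None = None
    trim_min: float | None = None
    trim_max: float | None = None
    shift: float | None = None
    scale_factor: float | None = None
    scaled_unit: str | None = None


@dataclass
class CorrectionSettings:
    plateau: float = 0.0
    span: float = 1.0
    alpha: float | None = None
    window: list[float] = field(default_factory=lambda: [0.0, 0.0])
    target: float | None = None
    clip_epsilon: float | None = None


@dataclass
class IC50Settings:
    family: str = "LL4"
    window: list[float] | None = None
    stride: int = 1
    use_replicates: bool = False


@dataclass
class AnalysisSettings:
    """Every parameter of every pipeline stage in one serializable record."""

    inputs: list[str] = field(default_factory=list)
    layout: str | None = None
    seed: int | None = None
    value_unit: str = ""
    formatting: FormatSettings | None = None
    correction: CorrectionSettings | None = None
    normalize_target: float | None = None
    aggregate: bool = False
    smooth_n: int | None = None
    slope_n: int | None = None
    ic50: IC50Settings | None = None
    plots: bool = False
    plot_format: str = "png"


_NESTED = {"formatting": FormatSettings, "correction": CorrectionSettings, "ic50": IC50Settings}


def save_settings(settings: AnalysisSettings, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(settings), fh, sort_keys=False)
    return path


def load_settings(path: str | Path) -> AnalysisSettings:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(AnalysisSettings)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown settings keys {sorted(unknown)}")
    for key, cls in _NESTED.items():
        if raw.get(key) is not None:
            raw[key] = cls(**raw[key])
    return AnalysisSettings(**raw)
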