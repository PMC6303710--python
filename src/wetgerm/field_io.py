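"""Field seedbed microclimate time series: reading, validation, gap reports.

One series per site-year: timestamped soil temperature (°C) and soil water
potential (MPa, 0 = saturated, more negative = drier) measured in the seed
zone, typically hourly at 1–3 cm depth. On disk the CSV columns are
``timestamp,soil_temp_c,water_potential_mpa`` with ISO-8601 timestamps; an
XLSX sheet with the same three columns (date-time, temperature, water
potential) is accepted for compatibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COLUMNS = ("timestamp", "soil_temp_c", "water_potential_mpa")


class FieldValidationError(ValueError):
    """A field series violates its contract (too short, unparseable, ...)."""


@dataclass
class FieldSeries:
    """Time-ordered soil temperature / water potential records for one
    site-year.

    ``frame`` holds the columns :data:`COLUMNS`; timestamps are strictly
    increasing; missing sensor values are NaN gaps. ``nominal_step`` is the
    modal inter-record interval (e.g. 1 h for hourly loggers).
    """

    site_year: str
    frame: pd.DataFrame
    nominal_step: pd.Timedelta | None = None

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.frame.columns]
        if missing:
            raise FieldValidationError(f"missing columns {missing}")
        if len(self.frame) < 2:
            raise FieldValidationError("a field series needs at least 2 records")
        ts = self.frame["timestamp"]
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise FieldValidationError("timestamps must be strictly increasing")
        if self.nominal_step is None:
            diffs = ts.diff().dropna()
            self.nominal_step = diffs.mode().iloc[0]

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def start(self) -> pd.Timestamp:
        return self.frame["timestamp"].iloc[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.frame["timestamp"].iloc[-1]

    @classmethod
    def from_arrays(cls, site_year, timestamps, soil_temp_c, water_potential_mpa) -> "FieldSeries":
        frame = pd.DataFrame(
            {
                "timestamp": pd.to_datetime(list(timestamps)),
                "soil_temp_c": np.asarray(soil_temp_c, dtype=float),
                "water_potential_mpa": np.asarray(water_potential_mpa, dtype=float),
            }
        )
        return _clean(frame, site_year, source=site_year)


def _clean(frame: pd.DataFrame, site_year: str, source: str) -> FieldSeries:
    frame = frame.sort_values("timestamp", kind="stable")
    dup = frame["timestamp"].duplicated()
    if dup.any():
        logger.warning(
            "%s: %d duplicated timestamp(s) dropped (first occurrence kept)",
            source, int(dup.sum()),
        )
        frame = frame[~dup]
    positive = frame["water_potential_mpa"] > 0
    if positive.any():
        logger.warning(
            "%s: %d positive water-potential value(s) clamped to 0 MPa",
            source, int(positive.sum()),
        )
        frame.loc[positive, "water_potential_mpa"] = 0.0
    frame = frame.reset_index(drop=True)
    if len(frame) < 2:
        raise FieldValidationError(f"{source}: fewer than 2 records")
    return FieldSeries(site_year=site_year, frame=frame)


def _numeric(col: pd.Series, name: str, source: str) -> pd.Series:
    out = pd.to_numeric(col, errors="coerce")
    bad = out.isna() & col.notna() & (col.astype(str).str.strip() != "")
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based file row after the header
        raise FieldValidationError(
            f"{source}: row {row}: cannot parse {name} value {col[bad.idxmax()]!r}"
        )
    return out.astype(float)


def read_field_series(path, site_year: str | None = None) -> FieldSeries:
    """Read and validate one site-year series (CSV or XLSX).

    Records are sorted by timestamp; duplicated timestamps keep the first
    occurrence with a warning; positive water potentials are clamped to 0
    with a warning; missing sensor values are retained as NaN gaps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if site_year is None:
        site_year = path.stem
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        raw = pd.read_excel(path)
        raw.columns = list(COLUMNS)[: len(raw.columns)]
    else:
        raw = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise FieldValidationError(f"{path}: missing columns {missing}")
    try:
        ts = pd.to_datetime(raw["timestamp"])
    except (ValueError, TypeError) as exc:
        raise FieldValidationError(f"{path}: unparseable timestamp: {exc}") from exc
    frame = pd.DataFrame(
        {
            "timestamp": ts,
            "soil_temp_c": _numeric(raw["soil_temp_c"], "soil_temp_c", str(path)),
            "water_potential_mpa": _numeric(
                raw["water_potential_mpa"], "water_potential_mpa", str(path)
            ),
        }
    )
    return _clean(frame, site_year, source=str(path))


def write_field_series(series: FieldSeries, path) -> Path:
    """Write the CSV dialect (full float precision, ISO timestamps)."""
    path = Path(path)
    out = series.frame.copy()
    out["timestamp"] = out["timestamp"].map(lambda t: t.isoformat())
    out.to_csv(path, index=False)
    return path


def gap_report(
    series: FieldSeries, max_gap: pd.Timedelta | None = None
) -> list[tuple[pd.Timestamp, pd.Timestamp, pd.Timedelta]]:
    """All inter-record gaps longer than ``max_gap``.

    ``max_gap`` defaults to three nominal steps (e.g. 3 h for hourly data).
    Returns ``(gap_start, gap_end, duration)`` triples in time order.
    """
    if max_gap is None:
        max_gap = 3 * series.nominal_step
    ts = series.frame["timestamp"]
    gaps = []
    diffs = ts.diff()
    for i in np.nonzero((diffs > max_gap).to_numpy())[0]:
        gaps.append((ts.iloc[i - 1], ts.iloc[i], diffs.iloc[i]))
    return gaps
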