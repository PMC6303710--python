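"""Read, validate and write constant-temperature germination count tables.

A laboratory trial consists of petri-dish samples incubated at constant
temperature. Each dish is observed on a schedule of dates and the number of
seeds that germinated *since the previous observation* is recorded (interval
counts, never cumulative). The on-disk dialects are:

* **CSV** (primary interchange format): a comment line
  ``# planting_date: <ISO date>`` followed by a header
  ``temperature,rep,plot_id,treatment,seeds_planted`` plus one column per
  ISO-8601 observation date, then one row per dish.
* **XLSX** (compatibility): the original entry-sheet layout — planting date
  in cell B8, a header row whose columns are temperature / rep / plot ID /
  treatment / seeds planted and, from column F rightward, the observation
  dates; data rows follow the header.

Observation dates are converted to elapsed days since planting (fractional
days are kept when timestamps carry a time of day).
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Soft capacity limits inherited from spreadsheet-era tooling; exceeding them
#: logs a warning but is not an error here.
MAX_SAMPLES_SOFT = 1000
MAX_OBSERVATION_DATES_SOFT = 100

LAB_META_COLUMNS = ("temperature", "rep", "plot_id", "treatment", "seeds_planted")


class LabValidationError(ValueError):
    """A count table violates the entry contract (missing required fields,
    non-increasing observation times, cumulative-looking counts, ...)."""


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    if isinstance(value, str) and not value.strip():
        return True
    return False


def _coerce_datetime(value) -> datetime:
    if isinstance(value, datetime):
        return value
    if isinstance(value, date):
        return datetime(value.year, value.month, value.day)
    if isinstance(value, pd.Timestamp):
        return value.to_pydatetime()
    if isinstance(value, str):
        return datetime.fromisoformat(value.strip())
    raise LabValidationError(f"cannot interpret {value!r} as a date")


@dataclass
class GerminationSample:
    """One petri dish: incubation temperature, seed count and interval counts.

    Parameters
    ----------
    temperature:
        Constant incubation temperature, °C.
    treatment:
        Grouping label (species, seedlot, seed treatment, ...).
    seeds_planted:
        Number of seeds placed in the dish (> 0).
    planting_time:
        Calendar timestamp of planting; elapsed observation times are
        measured from it.
    observations:
        Ordered ``(elapsed_days, count)`` pairs. Times must be strictly
        increasing and positive; counts are per-interval and non-negative,
        and their sum may not exceed ``seeds_planted``.
    replicate, plot_id:
        Optional bookkeeping labels.
    """

    temperature: float
    treatment: str
    seeds_planted: int
    planting_time: datetime
    observations: Sequence[tuple[float, int]]
    replicate: str | None = None
    plot_id: str | None = None

    def __post_init__(self) -> None:
        for name in ("temperature", "treatment", "seeds_planted", "planting_time"):
            if _is_missing(getattr(self, name)):
                raise LabValidationError(f"required field {name!r} is missing")
        self.temperature = float(self.temperature)
        self.treatment = str(self.treatment)
        self.seeds_planted = int(self.seeds_planted)
        if self.seeds_planted <= 0:
            raise LabValidationError("seeds_planted must be a positive count")
        self.planting_time = _coerce_datetime(self.planting_time)
        if self.replicate is not None:
            self.replicate = str(self.replicate)
        if self.plot_id is not None:
            self.plot_id = str(self.plot_id)

        obs: list[tuple[float, int]] = []
        prev = 0.0
        total = 0
        for t, n in self.observations:
            t = float(t)
            n = int(n)
            if t <= prev:
                raise LabValidationError(
                    "observation times must be strictly increasing and > 0 "
                    f"(got {t} after {prev})"
                )
            if n < 0:
                raise LabValidationError(f"negative germination count {n}")
            obs.append((t, n))
            prev = t
            total += n
        if not obs:
            raise LabValidationError("sample has no observations")
        if total > self.seeds_planted:
            raise LabValidationError(
                f"total germinated ({total}) exceeds seeds planted "
                f"({self.seeds_planted}); counts must be per-interval, "
                "not cumulative"
            )
        self.observations = tuple(obs)

    @property
    def times(self) -> np.ndarray:
        """Elapsed observation times, days."""
        return np.array([t for t, _ in self.observations], dtype=float)

    @property
    def counts(self) -> np.ndarray:
        """Per-interval germination counts."""
        return np.array([n for _, n in self.observations], dtype=int)

    @property
    def cumulative_counts(self) -> np.ndarray:
        return np.cumsum(self.counts)

    @property
    def germinated_total(self) -> int:
        return int(self.counts.sum())


@dataclass
class LabDataset:
    """A collection of :class:`GerminationSample` read from one source."""

    samples: Sequence[GerminationSample]
    source: str = ""

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        if len(self.samples) > MAX_SAMPLES_SOFT:
            logger.warning(
                "dataset has %d samples (> %d, the historical sheet limit); "
                "processing continues", len(self.samples), MAX_SAMPLES_SOFT,
            )
        n_dates = max((len(s.observations) for s in self.samples), default=0)
        if n_dates > MAX_OBSERVATION_DATES_SOFT:
            logger.warning(
                "dataset has %d observation dates (> %d, the historical sheet "
                "limit); processing continues", n_dates, MAX_OBSERVATION_DATES_SOFT,
            )

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[GerminationSample]:
        return iter(self.samples)

    @property
    def treatments(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.treatment, None)
        return tuple(seen)


# ---------------------------------------------------------------------------
# reading


def read_lab_counts(path, dialect: str | None = None, sheet: str | None = None) -> LabDataset:
    """Read a germination count table.

    ``dialect`` is ``"csv"`` or ``"xlsx"``; when ``None`` it is inferred from
    the file suffix. Blank count cells are read as zero with a logged
    warning; blank required fields are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "xlsx" if path.suffix.lower() in {".xlsx", ".xlsm"} else "csv"
    if dialect == "csv":
        planting, rows, obs_dates = _parse_csv(path)
    elif dialect == "xlsx":
        planting, rows, obs_dates = _parse_xlsx(path, sheet)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _build_dataset(planting, rows, obs_dates, source=str(path))


def _parse_csv(path: Path):
    planting = None
    data_lines: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            m = re.match(r"#\s*planting_date\s*:\s*(\S+)", line)
            if m:
                planting = _coerce_datetime(m.group(1))
        elif line.strip():
            data_lines.append(line)
    if planting is None:
        raise LabValidationError(
            f"{path}: missing '# planting_date: <ISO date>' header line"
        )
    frame = pd.read_csv(io.StringIO("\n".join(data_lines)), dtype=object)
    missing = [c for c in LAB_META_COLUMNS if c not in frame.columns]
    if missing:
        raise LabValidationError(f"{path}: missing columns {missing}")
    obs_cols = [c for c in frame.columns if c not in LAB_META_COLUMNS]
    obs_dates = [_coerce_datetime(c) for c in obs_cols]
    rows = []
    for idx, rec in frame.iterrows():
        rows.append(
            (
                int(idx) + 2,  # 1-based file row, after the header
                {k: rec[k] for k in LAB_META_COLUMNS},
                [rec[c] for c in obs_cols],
            )
        )
    return planting, rows, obs_dates


def _parse_xlsx(path: Path, sheet: str | None):
    from openpyxl import load_workbook

    wb = load_workbook(path, data_only=True, read_only=True)
    ws = wb[sheet] if sheet else wb.active
    grid = [[c for c in row] for row in ws.iter_rows(values_only=True)]
    wb.close()
    planting = None
    if len(grid) >= 8 and len(grid[7]) >= 2 and not _is_missing(grid[7][1]):
        planting = _coerce_datetime(grid[7][1])
    if planting is None:
        raise LabValidationError(f"{path}: planting date missing from cell B8")

    # header row = first row whose column F holds a date
    header_idx = None
    for i, row in enumerate(grid):
        if len(row) >= 6 and isinstance(row[5], (datetime, date)):
            header_idx = i
            break
    if header_idx is None:
        raise LabValidationError(f"{path}: no observation-date header row found")
    header = grid[header_idx]
    obs_dates = []
    for cell in header[5:]:
        if _is_missing(cell):
            break
        obs_dates.append(_coerce_datetime(cell))
    n_obs = len(obs_dates)

    rows = []
    for i in range(header_idx + 1, len(grid)):
        row = list(grid[i]) + [None] * (6 + n_obs - len(grid[i]))
        if all(_is_missing(v) for v in row[:5]):
            break
        meta = dict(
            temperature=row[0], rep=row[1], plot_id=row[2],
            treatment=row[3], seeds_planted=row[4],
        )
        rows.append((i + 1, meta, row[5:5 + n_obs]))
    return planting, rows, obs_dates


def _build_dataset(planting: datetime, rows, obs_dates, source: str) -> LabDataset:
    order = np.argsort([d.timestamp() for d in obs_dates], kind="stable")
    obs_dates = [obs_dates[i] for i in order]
    for d in obs_dates:
        if d <= planting:
            raise LabValidationError(
                f"{source}: observation date {d.date()} is not after the "
                f"planting date {planting.date()}"
            )
    if len({d for d in obs_dates}) != len(obs_dates):
        raise LabValidationError(f"{source}: duplicated observation dates")
    elapsed = [(d - planting).total_seconds() / 86400.0 for d in obs_dates]

    samples: list[GerminationSample] = []
    cumulative_rows: list[int] = []
    for file_row, meta, raw_counts in rows:
        for col in ("temperature", "treatment", "seeds_planted"):
            if _is_missing(meta.get(col)):
                raise LabValidationError(
                    f"{source}: row {file_row}: required column {col!r} is empty"
                )
        counts = []
        for j in order:
            v = raw_counts[j]
            if _is_missing(v):
                logger.warning(
                    "%s: row %d: blank count under %s read as 0",
                    source, file_row, obs_dates[len(counts)].date(),
                )
                counts.append(0)
            else:
                counts.append(int(float(v)))
        seeds = int(float(meta["seeds_planted"]))
        if sum(counts) > seeds:
            cumulative_rows.append(file_row)
            continue
        rep = meta.get("rep")
        plot = meta.get("plot_id")
        samples.append(
            GerminationSample(
                temperature=float(meta["temperature"]),
                treatment=str(meta["treatment"]),
                seeds_planted=seeds,
                planting_time=planting,
                observations=list(zip(elapsed, counts)),
                replicate=None if _is_missing(rep) else str(rep),
                plot_id=None if _is_missing(plot) else str(plot),
            )
        )
    if cumulative_rows:
        raise LabValidationError(
            f"{source}: rows {cumulative_rows} have counts summing to more than "
            "seeds planted — counts look cumulative; enter interval counts"
        )
    return LabDataset(samples=samples, source=source)


# ---------------------------------------------------------------------------
# writing


def _format_obs_date(planting: datetime, elapsed_days: float) -> str:
    ts = planting + timedelta(days=elapsed_days)
    if ts.time() == ts.min.time():
        return ts.date().isoformat()
    return ts.isoformat()


def write_lab_counts(dataset: LabDataset, path) -> Path:
    """Write a :class:`LabDataset` in the CSV dialect.

    All samples must share one planting date (one file per trial). The
    observation columns are the union of elapsed times over the samples;
    samples lacking a column are written blank, which — by the blank-cell
    policy — read back as zero-count observations. For datasets on a common
    observation schedule (the usual case, and everything this module itself
    produces) write-then-read reproduces the samples exactly.
    """
    if not dataset.samples:
        raise ValueError("refusing to write an empty dataset")
    plantings = {s.planting_time for s in dataset.samples}
    if len(plantings) != 1:
        raise ValueError("CSV dialect holds a single planting date per file")
    planting = plantings.pop()
    all_times = sorted({t for s in dataset.samples for t, _ in s.observations})
    header = list(LAB_META_COLUMNS) + [
        _format_obs_date(planting, t) for t in all_times
    ]
    lines = [f"# planting_date: {planting.date().isoformat() if planting.time() == planting.min.time() else planting.isoformat()}"]
    lines.append(",".join(header))
    for s in dataset.samples:
        lookup = {t: n for t, n in s.observations}
        cells = [
            _format_number(s.temperature),
            s.replicate or "",
            s.plot_id or "",
            s.treatment,
            str(s.seeds_planted),
        ] + ["" if t not in lookup else str(lookup[t]) for t in all_times]
        lines.append(",".join(cells))
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def _format_number(x: float) -> str:
    return f"{int(x)}" if float(x).is_integer() else repr(float(x))


def write_metrics_tables(dataset: LabDataset, summary, model=None, out_dir=".") -> dict[str, Path]:
    """Write the four result tables of a processed trial as CSV files.

    ``summary`` is the object returned by :func:`wetgerm.germ_metrics.summarize`;
    ``model`` (optional) a fitted :class:`wetgerm.thermal_model.WetThermalModel`
    whose coefficient table fills the fourth file. Files written:

    - ``germination_metrics.csv`` — per-sample indices, sorted by treatment
      then temperature;
    - ``data_averages.csv`` — treatment × temperature means;
    - ``standard_error.csv`` — standard errors of those means (blank for
      single-sample groups);
    - ``polynomial_equations.csv`` — fitted rate-curve coefficients (header
      only when no model is given).
    """
    if not dataset.samples:
        raise ValueError("empty dataset: nothing to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    per_sample = summary.per_sample.sort_values(
        ["treatment", "temperature"], kind="stable"
    )
    paths["germination_metrics"] = out_dir / "germination_metrics.csv"
    per_sample.to_csv(paths["germination_metrics"], index=False)

    paths["data_averages"] = out_dir / "data_averages.csv"
    summary.means.to_csv(paths["data_averages"], index=False)

    paths["standard_error"] = out_dir / "standard_error.csv"
    summary.standard_errors.to_csv(paths["standard_error"], index=False)

    paths["polynomial_equations"] = out_dir / "polynomial_equations.csv"
    if model is not None:
        model.to_csv(paths["polynomial_equations"])
    else:
        cols = ["treatment", "percentile", "A", "B", "C", "r2", "adj_r2",
                "tmin", "tmax", "n_points", "psi_b"]
        pd.DataFrame(columns=cols).to_csv(paths["polynomial_equations"], index=False)
    return paths
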