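"""Wet-thermal accumulation: predicting field germination dates.

Germination progress for a percentile accrues through a field microclimate
series as

.. math:: P(t) = \\sum_j r(T_j)\\, \\Delta t_j \\; [\\Psi_j \\ge \\Psi_b]

where :math:`r` is the percentile's fitted rate curve (1/day), the sum runs
over record intervals after planting (left-hold: each record's temperature
and wetness apply until the next record), and only wet steps — soil water
potential at or above the base water potential Ψ_b — contribute. The
percentile is predicted to germinate at the first time the accumulated
progress reaches 1 (one full thermal requirement), interpolated linearly
inside the final record interval. Record gaps longer than ``max_gap``
contribute at most ``max_gap`` worth of accrual and are logged.

Three entry points mirror typical use: :func:`predict_dates_for_planting`
(all percentiles for one planting date), :func:`predict_planting_scan`
(one target percentile over a range of daily planting dates), and
:func:`spring_planting_date` (earliest planting date whose predicted
germination falls on/after a spring cutoff, by default 1 March).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date, datetime, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .field_io import FieldSeries
from .thermal_model import (
    DEFAULT_FREEZE_FLOOR,
    RateCurve,
    WetThermalModel,
    predict_rate,
)

logger = logging.getLogger(__name__)

#: Status labels for :func:`spring_planting_date`.
STATUS_GERMINATES_AFTER_CUTOFF = "germinates-after-cutoff"
STATUS_MET_BY_NON_GERMINATION = "met-by-non-germination"
STATUS_INDETERMINATE = "indeterminate"
STATUS_NEVER = "never"


def _as_timestamp(value) -> pd.Timestamp:
    ts = pd.Timestamp(value)
    return ts


@dataclass
class AccumulationTrace:
    """Progress of one percentile through a field series from planting.

    ``progress[i]`` is the accumulated fraction of the thermal requirement
    at ``timestamps[i]`` (0 at the first record on/after planting, capped
    nowhere — it keeps accumulating past 1). ``completion_time`` is the
    first instant progress reaches 1, interpolated inside the final record
    interval, or ``None`` if the series ends first.
    """

    timestamps: pd.DatetimeIndex
    progress: np.ndarray
    wet_time: pd.Timedelta
    completion_time: pd.Timestamp | None
    planting: pd.Timestamp

    @property
    def completed(self) -> bool:
        return self.completion_time is not None


class _CurveAccumulator:
    """Per-interval increments for one curve over a whole series.

    The increments depend on the curve and series only, not on the planting
    date, so one precomputation serves every planting date of a scan; a
    planting date then reduces to a suffix cumulative sum, identical to
    accumulating that date independently.
    """

    def __init__(
        self,
        curve: RateCurve,
        series: FieldSeries,
        psi_b: float,
        max_gap: pd.Timedelta | None,
        freeze_floor: float,
        wet_inclusive: bool,
    ):
        frame = series.frame
        self.times = pd.DatetimeIndex(frame["timestamp"])
        temp = frame["soil_temp_c"].to_numpy(dtype=float)
        psi = frame["water_potential_mpa"].to_numpy(dtype=float)
        if max_gap is None:
            max_gap = 3 * series.nominal_step
        gap_days = np.diff(self.times.asi8) / 1e9 / 86400.0
        cap_days = max_gap.total_seconds() / 86400.0
        n_capped = int((gap_days > cap_days + 1e-12).sum())
        if n_capped:
            logger.warning(
                "%s: %d record gap(s) exceed max_gap=%s; accrual capped",
                series.site_year, n_capped, max_gap,
            )
        self.dt_days = np.minimum(gap_days, cap_days)
        wet = psi >= psi_b if wet_inclusive else psi > psi_b
        valid = ~np.isnan(temp) & ~np.isnan(psi)
        rate = predict_rate(curve, np.where(valid, temp, 0.0), freeze_floor)
        self.rates = np.where(wet & valid, rate, 0.0)[:-1]
        self.increments = self.rates * self.dt_days
        # cum[i] = progress accumulated over intervals 0..i-1
        self.cum = np.concatenate([[0.0], np.cumsum(self.increments)])
        self.wet_days = np.where(wet[:-1] & valid[:-1], self.dt_days, 0.0)

    def start_index(self, planting: pd.Timestamp) -> int:
        return int(self.times.searchsorted(planting, side="left"))

    def completion(self, planting: pd.Timestamp) -> pd.Timestamp | None:
        """First instant progress from ``planting`` reaches 1, or None."""
        i0 = self.start_index(planting)
        if i0 >= len(self.times):
            raise ValueError(
                f"planting {planting} is after the series end {self.times[-1]}"
            )
        base = self.cum[i0]
        if self.cum[-1] - base < 1.0 - 1e-12:
            return None
        k = int(np.searchsorted(self.cum, base + 1.0 - 1e-12, side="left"))
        m = k - 1  # interval index in which progress crosses 1
        needed = 1.0 - (self.cum[m] - base)
        frac_days = 0.0 if needed <= 0 else needed / self.rates[m]
        return self.times[m] + pd.Timedelta(days=frac_days)

    def trace(self, planting: pd.Timestamp) -> AccumulationTrace:
        i0 = self.start_index(planting)
        if i0 >= len(self.times):
            raise ValueError(
                f"planting {planting} is after the series end {self.times[-1]}"
            )
        progress = self.cum[i0:] - self.cum[i0]
        return AccumulationTrace(
            timestamps=self.times[i0:],
            progress=progress,
            wet_time=pd.Timedelta(days=float(self.wet_days[i0:].sum())),
            completion_time=self.completion(planting),
            planting=planting,
        )


def accumulate(
    curve: RateCurve,
    series: FieldSeries,
    planting,
    psi_b: float = -1.5,
    max_gap: pd.Timedelta | None = None,
    freeze_floor: float = DEFAULT_FREEZE_FLOOR,
    wet_inclusive: bool = True,
) -> AccumulationTrace:
    """Accumulate wet-thermal progress for one curve from a planting date.

    Starting at the first record on/after ``planting``, each record interval
    contributes ``rate(T) × Δt`` when the record is wet (Ψ ≥ ``psi_b``;
    strict with ``wet_inclusive=False``) and both sensor values are present,
    where ``Δt`` is the interval length capped at ``max_gap`` (default three
    nominal steps). Raises ``ValueError`` when ``planting`` falls after the
    series end.
    """
    planting = _as_timestamp(planting)
    acc = _CurveAccumulator(curve, series, psi_b, max_gap, freeze_floor, wet_inclusive)
    return acc.trace(planting)


@dataclass
class PredictionTable:
    """Predicted germination dates, one row per treatment × percentile."""

    frame: pd.DataFrame  # site_year, treatment, percentile, planting_date, predicted_date

    def to_csv(self, path):
        out = self.frame.copy()
        out.to_csv(path, index=False)
        return path


def predict_dates_for_planting(
    model: WetThermalModel,
    series: FieldSeries,
    planting,
    *,
    psi_b: float | None = None,
    max_gap: pd.Timedelta | None = None,
    freeze_floor: float = DEFAULT_FREEZE_FLOOR,
    wet_inclusive: bool = True,
) -> PredictionTable:
    """Predicted germination date for every fitted treatment × percentile
    given one planting date (``NaT`` where the requirement is never met)."""
    if not model.curves:
        raise ValueError("model has no curves")
    planting = _as_timestamp(planting)
    psi_b = model.psi_b if psi_b is None else psi_b
    rows = []
    for (treatment, pct), curve in sorted(model.curves.items()):
        acc = _CurveAccumulator(curve, series, psi_b, max_gap, freeze_floor, wet_inclusive)
        done = acc.completion(planting)
        rows.append(
            dict(
                site_year=series.site_year,
                treatment=treatment,
                percentile=pct,
                planting_date=planting,
                predicted_date=done if done is not None else pd.NaT,
            )
        )
    return PredictionTable(frame=pd.DataFrame(rows))


@dataclass
class PlantingScanResult:
    """Predicted germination date of a target percentile for each daily
    planting date, plus the series end needed to interpret non-germination."""

    frame: pd.DataFrame  # site_year, treatment, planting_date, predicted_date
    target_percent: float
    series_end: pd.Timestamp

    def to_csv(self, path):
        self.frame.to_csv(path, index=False)
        return path


def predict_planting_scan(
    model: WetThermalModel,
    series: FieldSeries,
    target_percent: float,
    scan_start,
    scan_end,
    scan_step: timedelta = timedelta(days=1),
    *,
    treatments: Sequence[str] | None = None,
    psi_b: float | None = None,
    max_gap: pd.Timedelta | None = None,
    freeze_floor: float = DEFAULT_FREEZE_FLOOR,
    wet_inclusive: bool = True,
) -> PlantingScanResult:
    """Predict when ``target_percent`` germinates for each planting date in
    ``[scan_start, scan_end]`` (inclusive, default daily).

    The target percentile must lie on the model's fitted grid; otherwise the
    nearest fitted percentile is used with a warning (via
    :meth:`WetThermalModel.get`). The per-interval increments are computed
    once per treatment and reused across planting dates, which is exactly
    equivalent to accumulating each date independently.
    """
    scan_start = _as_timestamp(scan_start)
    scan_end = _as_timestamp(scan_end)
    if scan_end < scan_start:
        raise ValueError("scan_end before scan_start")
    if scan_start < series.start.normalize() or scan_end > series.end:
        raise ValueError(
            f"scan range {scan_start.date()}..{scan_end.date()} falls outside "
            f"the series {series.start}..{series.end}"
        )
    psi_b = model.psi_b if psi_b is None else psi_b
    if treatments is None:
        treatments = model.treatments
    plantings = []
    t = scan_start
    while t <= scan_end:
        plantings.append(t)
        t = t + scan_step
    rows = []
    for treatment in treatments:
        curve = model.get(treatment, target_percent)
        acc = _CurveAccumulator(curve, series, psi_b, max_gap, freeze_floor, wet_inclusive)
        for planting in plantings:
            done = acc.completion(planting)
            rows.append(
                dict(
                    site_year=series.site_year,
                    treatment=treatment,
                    planting_date=planting,
                    predicted_date=done if done is not None else pd.NaT,
                )
            )
    return PlantingScanResult(
        frame=pd.DataFrame(rows),
        target_percent=float(target_percent),
        series_end=series.end,
    )


def _default_cutoff(scan: PlantingScanResult) -> pd.Timestamp:
    """First 1 March strictly after the earliest scanned planting date."""
    first = scan.frame["planting_date"].min()
    year = first.year if (first.month, first.day) < (3, 1) else first.year + 1
    return pd.Timestamp(year=year, month=3, day=1)


def spring_planting_date(
    scan: PlantingScanResult, cutoff=None
) -> pd.DataFrame:
    """Earliest planting date whose predicted germination is on/after
    ``cutoff`` (default: the 1 March following the scan start), per
    site-year × treatment.

    Returns a frame with columns ``site_year, treatment, planting_date,
    status``. A planting date with no germination at all counts as meeting
    the criterion only when the series extends to the cutoff (status
    ``met-by-non-germination``); when the series ends before the cutoff the
    question cannot be decided and status is ``indeterminate`` with a
    missing date. ``never`` means every scanned planting date germinates
    before the cutoff.
    """
    if scan.frame.empty:
        raise ValueError("empty scan")
    cutoff = _default_cutoff(scan) if cutoff is None else _as_timestamp(cutoff)
    results = []
    for (site_year, treatment), grp in scan.frame.groupby(
        ["site_year", "treatment"], sort=True
    ):
        grp = grp.sort_values("planting_date", kind="stable")
        if scan.series_end < cutoff:
            results.append(
                dict(site_year=site_year, treatment=treatment,
                     planting_date=pd.NaT, status=STATUS_INDETERMINATE)
            )
            continue
        found = None
        for rec in grp.itertuples(index=False):
            if pd.isna(rec.predicted_date):
                found = (rec.planting_date, STATUS_MET_BY_NON_GERMINATION)
                break
            if rec.predicted_date >= cutoff:
                found = (rec.planting_date, STATUS_GERMINATES_AFTER_CUTOFF)
                break
        if found is None:
            results.append(
                dict(site_year=site_year, treatment=treatment,
                     planting_date=pd.NaT, status=STATUS_NEVER)
            )
        else:
            results.append(
                dict(site_year=site_year, treatment=treatment,
                     planting_date=found[0], status=found[1])
            )
    return pd.DataFrame(results)
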