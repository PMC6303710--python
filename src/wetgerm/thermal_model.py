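"""Wet-thermal rate curves: germination rate vs. incubation temperature.

For each treatment and each population percentile N on a user grid, the time
:math:`T_N` to N % germination is computed per dish, averaged over
replicates within each incubation temperature, and inverted to a rate
:math:`1/\\overline{T_N}` (1/day). A second-order polynomial

.. math:: r_N(T) = A T^2 + B T + C

is then fitted by ordinary least squares over the temperatures at which the
percentile was reached. The resulting family of curves, together with a base
water potential Ψ_b, forms the wet-thermal model applied to field
microclimate series by :mod:`wetgerm.predictor`.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import germ_metrics
from .lab_io import LabDataset

logger = logging.getLogger(__name__)

#: Base water potential below which no germination progress accrues (MPa).
DEFAULT_PSI_B = -1.5
#: Temperatures below this floor contribute zero rate (°C); set to -inf to disable.
DEFAULT_FREEZE_FLOOR = 0.0


class ModelFitError(RuntimeError):
    """No rate curve could be fitted from the supplied dataset."""


@dataclass(frozen=True)
class PercentileGrid:
    """Evenly spaced germination percentiles, each fitted as its own curve.

    ``lower`` and ``upper`` are percents in [1, 99]; ``interval`` is the step.
    """

    lower: float
    upper: float
    interval: float

    def __post_init__(self) -> None:
        if not (1 <= self.lower <= self.upper <= 99):
            raise ValueError("percentile bounds must satisfy 1 <= lower <= upper <= 99")
        if self.interval <= 0:
            raise ValueError("percentile interval must be positive")

    @property
    def percentiles(self) -> tuple[float, ...]:
        vals = np.arange(self.lower, self.upper + 1e-9, self.interval)
        return tuple(float(v) for v in vals)

    @classmethod
    def parse(cls, text: str) -> "PercentileGrid":
        """Parse ``"lower:upper:step"`` (e.g. ``"10:90:10"``)."""
        parts = text.split(":")
        if len(parts) != 3:
            raise ValueError(f"expected 'lower:upper:step', got {text!r}")
        return cls(*(float(p) for p in parts))


DEFAULT_GRID = PercentileGrid(10, 90, 10)


def r_squared(
    observed: Sequence[float], fitted: Sequence[float], n_regressors: int = 2
) -> tuple[float, float]:
    """Coefficient of determination and its adjusted form.

    ``r2 = 1 - SS_res / SS_tot`` with SS_tot about the mean of ``observed``;
    ``adj_r2 = 1 - (1 - r2)(n - 1)/(n - p - 1)`` with ``p = n_regressors``
    (2 for a quadratic in T: the regressors T and T²). ``r2`` is ``nan``
    when the observations have zero variance; ``adj_r2`` is ``nan`` when
    ``n <= p + 1`` leaves no residual degrees of freedom.
    """
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    ss_res = float(((obs - fit) ** 2).sum())
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    if ss_tot == 0:
        return math.nan, math.nan
    r2 = 1.0 - ss_res / ss_tot
    n = obs.size
    dof = n - n_regressors - 1
    adj = 1.0 - (1.0 - r2) * (n - 1) / dof if dof > 0 else math.nan
    return r2, adj


@dataclass(frozen=True)
class RateCurve:
    """Quadratic germination-rate response to temperature for one
    treatment × percentile: ``rate(T) = a·T² + b·T + c`` (1/day, T in °C)."""

    treatment: str
    percentile: float
    a: float
    b: float
    c: float
    r2: float = math.nan
    adj_r2: float = math.nan
    tmin: float = math.nan
    tmax: float = math.nan
    n_points: int = 0

    def rate_at(
        self, temperature, freeze_floor: float = DEFAULT_FREEZE_FLOOR
    ):
        return predict_rate(self, temperature, freeze_floor=freeze_floor)


def predict_rate(
    curve: RateCurve, temperature, freeze_floor: float = DEFAULT_FREEZE_FLOOR
):
    """Evaluate a rate curve, clamped to physical rates.

    Negative polynomial values clamp to zero (no negative progress), and any
    temperature below ``freeze_floor`` (default 0 °C) contributes zero rate.
    Scalar in, scalar out; array in, array out. Extrapolation beyond the
    fitted temperature range is permitted (the caller may consult
    ``curve.tmin``/``tmax`` to flag it).
    """
    t = np.asarray(temperature, dtype=float)
    raw = curve.a * t * t + curve.b * t + curve.c
    rate = np.where(t < freeze_floor, 0.0, np.maximum(raw, 0.0))
    if np.isscalar(temperature) or t.ndim == 0:
        return float(rate)
    return rate


@dataclass
class WetThermalModel:
    """A family of fitted rate curves plus the base water potential Ψ_b."""

    curves: dict[tuple[str, float], RateCurve]
    psi_b: float = DEFAULT_PSI_B

    def __post_init__(self) -> None:
        if self.psi_b >= 0:
            raise ValueError("psi_b must be negative (MPa; drier = more negative)")

    @property
    def treatments(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t, _ in self.curves:
            seen.setdefault(t, None)
        return tuple(seen)

    def percentiles(self, treatment: str) -> tuple[float, ...]:
        return tuple(sorted(p for t, p in self.curves if t == treatment))

    def get(self, treatment: str, percentile: float) -> RateCurve:
        """Look up a curve; falls back to the nearest fitted percentile with
        a warning when the exact one is absent."""
        key = (treatment, float(percentile))
        if key in self.curves:
            return self.curves[key]
        avail = self.percentiles(treatment)
        if not avail:
            raise KeyError(f"no curves for treatment {treatment!r}")
        nearest = min(avail, key=lambda p: (abs(p - percentile), p))
        logger.warning(
            "percentile %g not on the fitted grid for %r; using nearest (%g)",
            percentile, treatment, nearest,
        )
        return self.curves[(treatment, nearest)]

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                treatment=c.treatment, percentile=c.percentile,
                A=c.a, B=c.b, C=c.c, r2=c.r2, adj_r2=c.adj_r2,
                tmin=c.tmin, tmax=c.tmax, n_points=c.n_points,
                psi_b=self.psi_b,
            )
            for c in sorted(
                self.curves.values(), key=lambda c: (c.treatment, c.percentile)
            )
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "psi_b": self.psi_b,
            "curves": self.to_frame().drop(columns="psi_b").to_dict("records"),
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, psi_b: float | None = None) -> "WetThermalModel":
        if psi_b is None:
            psi_b = float(frame["psi_b"].iloc[0]) if "psi_b" in frame else DEFAULT_PSI_B
        curves = {}
        for rec in frame.to_dict("records"):
            curve = RateCurve(
                treatment=str(rec["treatment"]), percentile=float(rec["percentile"]),
                a=float(rec["A"]), b=float(rec["B"]), c=float(rec["C"]),
                r2=float(rec.get("r2", math.nan)), adj_r2=float(rec.get("adj_r2", math.nan)),
                tmin=float(rec.get("tmin", math.nan)), tmax=float(rec.get("tmax", math.nan)),
                n_points=int(rec.get("n_points", 0)),
            )
            curves[(curve.treatment, curve.percentile)] = curve
        return cls(curves=curves, psi_b=psi_b)

    @classmethod
    def from_csv(cls, path) -> "WetThermalModel":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def from_json(cls, path) -> "WetThermalModel":
        payload = json.loads(Path(path).read_text())
        return cls.from_frame(pd.DataFrame(payload["curves"]), psi_b=payload["psi_b"])


RateAveraging = Literal["inverse-mean-time", "mean-rate"]


def build_rate_curves(
    dataset: LabDataset,
    grid: PercentileGrid = DEFAULT_GRID,
    *,
    psi_b: float = DEFAULT_PSI_B,
    basis: germ_metrics.PercentBasis = "planted",
    rate_averaging: RateAveraging = "inverse-mean-time",
    min_temperatures: int = 3,
) -> WetThermalModel:
    """Fit the quadratic rate curve for every treatment × grid percentile.

    Per percentile: T_N is computed per dish; within each temperature the
    replicate T_N values are averaged, dishes that never reached N being
    excluded; temperatures where no dish reached N are dropped; the rate is
    ``1/mean(T_N)`` (or ``mean(1/T_N)`` under ``rate_averaging="mean-rate"``);
    and the quadratic is fitted by OLS over the surviving temperatures.
    Percentiles left with fewer than ``min_temperatures`` temperatures are
    skipped with a warning. Raises :class:`ModelFitError` if nothing fits.
    """
    if not dataset.samples:
        raise ModelFitError("empty dataset")
    curves: dict[tuple[str, float], RateCurve] = {}
    by_treatment: dict[str, list] = {}
    for s in dataset.samples:
        by_treatment.setdefault(s.treatment, []).append(s)

    for treatment, samples in by_treatment.items():
        by_temp: dict[float, list] = {}
        for s in samples:
            by_temp.setdefault(s.temperature, []).append(s)
        for pct in grid.percentiles:
            temps, rates = [], []
            for temperature in sorted(by_temp):
                tns = [
                    germ_metrics.time_to_percent(s, pct, basis=basis)
                    for s in by_temp[temperature]
                ]
                tns = [t for t in tns if not math.isnan(t)]
                if not tns:
                    continue
                if rate_averaging == "inverse-mean-time":
                    rate = 1.0 / float(np.mean(tns))
                elif rate_averaging == "mean-rate":
                    rate = float(np.mean([1.0 / t for t in tns]))
                else:
                    raise ValueError(f"unknown rate_averaging {rate_averaging!r}")
                temps.append(temperature)
                rates.append(rate)
            if len(temps) < min_temperatures:
                logger.warning(
                    "treatment %r, percentile %g%%: reached at only %d "
                    "temperature(s) (< %d); curve skipped",
                    treatment, pct, len(temps), min_temperatures,
                )
                continue
            t_arr = np.asarray(temps, dtype=float)
            r_arr = np.asarray(rates, dtype=float)
            a, b, c = np.polyfit(t_arr, r_arr, 2)
            fitted = np.polyval([a, b, c], t_arr)
            r2, adj = r_squared(r_arr, fitted, n_regressors=2)
            curves[(treatment, float(pct))] = RateCurve(
                treatment=treatment, percentile=float(pct),
                a=float(a), b=float(b), c=float(c),
                r2=r2, adj_r2=adj,
                tmin=float(t_arr.min()), tmax=float(t_arr.max()),
                n_points=len(temps),
            )
    if not curves:
        raise ModelFitError(
            "no treatment × percentile combination had enough temperatures to fit"
        )
    return WetThermalModel(curves=curves, psi_b=psi_b)
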