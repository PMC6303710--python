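"""Synthetic laboratory trials and field microclimate series with known truth.

The laboratory generator emulates a constant-temperature germination trial:
each seed in a dish is germinable with a temperature-dependent probability
(the final germinable fraction), and germinable seeds draw a germination
time from a parametric law whose *median rate* (1/median time) follows a
known quadratic in temperature — the same family the rate-curve fitting
assumes, so estimation error can be separated from model misspecification.
A deliberately misspecified option (log-logistic time law) is included for
robustness checks. Times are then binned onto the observation schedule
exactly as a technician would count dishes, so the only noise is the
binomial/multinomial sampling of seeds into intervals.

The field generator emulates seed-zone sensor series: a seasonal mean trend
(constant, or piecewise linear through anchor points), a diurnal sinusoid,
Gaussian sensor noise, and soil moisture alternating between a wet and a dry
water potential either on an explicit schedule or as a two-state process
with exponential dwell times.

Defaults mirror a typical wet-thermal trial: incubation at 5–25 °C in 5 °C
steps, 7 replicate dishes of 25 seeds, counts every 2 days out to day 60,
hourly field records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .field_io import FieldSeries
from .lab_io import GerminationSample, LabDataset

LawFamily = Literal["weibull", "loglogistic", "fixed"]


@dataclass(frozen=True)
class GerminationLaw:
    """Germination-time distribution for one treatment.

    The median germination *rate* at temperature T is the quadratic
    ``rate_coeffs[0]·T² + rate_coeffs[1]·T + rate_coeffs[2]`` (1/day); a
    non-positive value means no germination at that temperature. ``family``
    sets the shape of the time distribution around that median:

    - ``weibull``: time = scale · (−ln(1−u))^(1/shape), scale chosen so the
      median is 1/rate;
    - ``loglogistic``: time = median · (u/(1−u))^(1/shape);
    - ``fixed``: every germinable seed germinates exactly at the median
      (degenerate law, useful for exact tests).

    Larger ``shape`` = tighter spread around the median.
    """

    rate_coeffs: tuple[float, float, float]
    family: LawFamily = "weibull"
    shape: float = 3.0

    def median_rate(self, temperature: float) -> float:
        a, b, c = self.rate_coeffs
        return a * temperature**2 + b * temperature + c

    def median_time(self, temperature: float) -> float:
        r = self.median_rate(temperature)
        return math.inf if r <= 0 else 1.0 / r

    def quantile(self, temperature: float, q: float) -> float:
        """Closed-form germination-time quantile (days); ``inf`` if q ≥ 1 or
        no germination occurs at this temperature."""
        m = self.median_time(temperature)
        if not 0 < q < 1:
            return math.inf if q >= 1 else 0.0
        if math.isinf(m):
            return math.inf
        if self.family == "weibull":
            factor = (math.log(1 - q) / math.log(0.5)) ** (1.0 / self.shape)
        elif self.family == "loglogistic":
            factor = (q / (1 - q)) ** (1.0 / self.shape)
        elif self.family == "fixed":
            factor = 1.0
        else:
            raise ValueError(f"unknown family {self.family!r}")
        return m * factor

    def sample_times(self, temperature: float, n: int, rng: np.random.Generator) -> np.ndarray:
        m = self.median_time(temperature)
        if math.isinf(m):
            return np.full(n, np.inf)
        if self.family == "fixed":
            return np.full(n, m)
        u = rng.random(n)
        if self.family == "weibull":
            scale = m / math.log(2) ** (1.0 / self.shape)
            return scale * (-np.log1p(-u)) ** (1.0 / self.shape)
        if self.family == "loglogistic":
            return m * (u / (1 - u)) ** (1.0 / self.shape)
        raise ValueError(f"unknown family {self.family!r}")


#: A realistic cool-season response: rates positive over 5–25 °C, peaking
#: near 19 °C (T50 ≈ 20 d at 5 °C down to ≈ 5 d at 15–25 °C).
DEFAULT_LAW = GerminationLaw(rate_coeffs=(-0.0008, 0.0306, -0.083))


@dataclass
class LabSimConfig:
    """Configuration of a synthetic constant-temperature trial."""

    treatments: Mapping[str, GerminationLaw] = field(
        default_factory=lambda: {"SYNTH": DEFAULT_LAW}
    )
    temperatures: Sequence[float] = (5.0, 10.0, 15.0, 20.0, 25.0)
    reps: int = 7
    seeds_per_dish: int = 25
    #: Germinable fraction of seeds; a constant or a callable of temperature.
    final_fraction: float | Callable[[float], float] = 0.9
    #: Observation schedule, elapsed days.
    schedule: Sequence[float] = tuple(range(2, 61, 2))
    planting_date: date = date(2016, 1, 1)
    rng_seed: int = 0

    def fraction_at(self, temperature: float) -> float:
        f = (
            self.final_fraction(temperature)
            if callable(self.final_fraction)
            else float(self.final_fraction)
        )
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"final fraction {f} outside [0, 1]")
        return f

    def true_time_to_percent(
        self, treatment: str, temperature: float, percent: float,
        basis: str = "planted",
    ) -> float:
        """Ground-truth T_N (days) implied by the generating law.

        With ``basis="planted"`` the target fraction of *planted* seeds is
        converted to a quantile of the germinable subpopulation using the
        final germinable fraction; ``inf`` when the percentile is never
        reached.
        """
        law = self.treatments[treatment]
        q = percent / 100.0
        if basis == "planted":
            f = self.fraction_at(temperature)
            if f <= 0:
                return math.inf
            q = q / f
        if q >= 1:
            return math.inf
        return law.quantile(temperature, q)


def simulate_lab_counts(config: LabSimConfig) -> LabDataset:
    """Draw a synthetic :class:`LabDataset` (reproducible for a given seed).

    Per dish: each seed is independently germinable with the final-fraction
    probability at its temperature; germinable seeds draw germination times
    from the treatment's law; times are binned into the observation schedule
    (a time t is counted at the first schedule day ≥ t); times beyond the
    last observation day go uncounted, exactly as a trial that ends would
    leave them.
    """
    schedule = [float(t) for t in config.schedule]
    if not schedule or any(b <= a for a, b in zip(schedule, schedule[1:])):
        raise ValueError("schedule must be strictly increasing and non-empty")
    if schedule[0] <= 0:
        raise ValueError("schedule times must be positive")
    if config.reps <= 0 or config.seeds_per_dish <= 0:
        raise ValueError("reps and seeds_per_dish must be positive")
    for name, law in config.treatments.items():
        if law.shape <= 0:
            raise ValueError(f"treatment {name!r}: shape must be positive")
    rng = np.random.default_rng(config.rng_seed)
    edges = np.asarray(schedule)
    samples = []
    for treatment, law in config.treatments.items():
        for temperature in config.temperatures:
            frac = config.fraction_at(temperature)
            for rep in range(1, config.reps + 1):
                n_germinable = rng.binomial(config.seeds_per_dish, frac)
                times = law.sample_times(temperature, n_germinable, rng)
                idx = np.searchsorted(edges, times, side="left")
                counts = np.bincount(
                    idx[idx < len(edges)], minlength=len(edges)
                )
                samples.append(
                    GerminationSample(
                        temperature=temperature,
                        treatment=treatment,
                        seeds_planted=config.seeds_per_dish,
                        planting_time=datetime.combine(
                            config.planting_date, datetime.min.time()
                        ),
                        observations=list(zip(schedule, (int(c) for c in counts))),
                        replicate=str(rep),
                    )
                )
    return LabDataset(samples=samples, source="simulate_lab_counts")


@dataclass
class FieldSimConfig:
    """Configuration of a synthetic seed-zone microclimate series."""

    start: datetime
    end: datetime
    step: timedelta = timedelta(hours=1)
    #: Seasonal mean soil temperature: a constant, or piecewise-linear
    #: anchor points [(datetime, °C), ...] interpolated over the range.
    temp_trend: float | Sequence[tuple[datetime, float]] = 10.0
    #: Amplitude of the diurnal sinusoid, °C.
    diurnal_amplitude: float = 8.0
    noise_sd: float = 0.5
    wet_psi: float = -0.3
    dry_psi: float = -3.0
    #: Moisture regime: ``None`` = always wet; a list of (start, end) wet
    #: windows (dry elsewhere); or ``("markov", mean_wet_days, mean_dry_days)``
    #: for random episodes with exponential dwell times.
    wet_windows: Sequence[tuple[datetime, datetime]] | tuple | None = None
    site_year: str = "synthetic-site"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.step <= timedelta(0):
            raise ValueError("step must be positive")
        if self.wet_psi <= self.dry_psi:
            raise ValueError("wet_psi must exceed dry_psi")


def _trend_values(config: FieldSimConfig, times: pd.DatetimeIndex) -> np.ndarray:
    if isinstance(config.temp_trend, (int, float)):
        return np.full(len(times), float(config.temp_trend))
    anchors = sorted(config.temp_trend, key=lambda p: p[0])
    xs = np.array([pd.Timestamp(t).value for t, _ in anchors], dtype=float)
    ys = np.array([v for _, v in anchors], dtype=float)
    return np.interp(times.asi8.astype(float), xs, ys)


def simulate_field_series(config: FieldSimConfig) -> FieldSeries:
    """Generate an evenly stepped field series (reproducible for a seed)."""
    times = pd.date_range(config.start, config.end, freq=config.step)
    if len(times) < 2:
        raise ValueError("date range must span at least two records")
    rng = np.random.default_rng(config.rng_seed)
    hour = (times - times.normalize()).total_seconds() / 3600.0
    temp = (
        _trend_values(config, times)
        + config.diurnal_amplitude * np.sin(2 * np.pi * np.asarray(hour) / 24.0)
        + (rng.normal(0.0, config.noise_sd, len(times)) if config.noise_sd > 0 else 0.0)
    )

    if config.wet_windows is None:
        wet = np.ones(len(times), dtype=bool)
    elif len(config.wet_windows) == 3 and config.wet_windows[0] == "markov":
        _, mean_wet, mean_dry = config.wet_windows
        wet = np.empty(len(times), dtype=bool)
        state = True
        t_switch = 0.0
        step_days = config.step.total_seconds() / 86400.0
        elapsed = 0.0
        dwell = rng.exponential(mean_wet)
        for i in range(len(times)):
            if elapsed >= dwell:
                state = not state
                elapsed = 0.0
                dwell = rng.exponential(mean_wet if state else mean_dry)
            wet[i] = state
            elapsed += step_days
    else:
        wet = np.zeros(len(times), dtype=bool)
        for w_start, w_end in config.wet_windows:
            wet |= (times >= pd.Timestamp(w_start)) & (times < pd.Timestamp(w_end))
    psi = np.where(wet, config.wet_psi, config.dry_psi)

    frame = pd.DataFrame(
        {
            "timestamp": times,
            "soil_temp_c": temp,
            "water_potential_mpa": psi,
        }
    )
    return FieldSeries(site_year=config.site_year, frame=frame)
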