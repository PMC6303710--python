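"""Per-sample germination indices and grouped summaries.

Given interval germination counts :math:`n_i` recorded at elapsed times
:math:`t_i` (days), the classical indices are

* mean germination time  :math:`\\bar t = \\sum n_i t_i / \\sum n_i`,
* coefficient of variation of germination time
  :math:`CV_t = s_t/\\bar t \\times 100` with :math:`s_t` the count-weighted
  sample standard deviation (denominator :math:`\\sum n_i - 1`),
* mean germination rate :math:`1/\\bar t` (1/day),
* uncertainty :math:`U = -\\sum f_i \\log_2 f_i` (bits), the Shannon entropy
  of the distribution of germination events over counting intervals,
* synchrony :math:`Z = \\sum \\binom{n_i}{2} / \\binom{\\sum n_i}{2}`, the
  probability that two randomly chosen germinants share an interval,
* :math:`T_N`, the time for N % of the population to germinate, linearly
  interpolated between the bracketing cumulative counts.

Every index is returned as ``nan`` ("missing") when its preconditions fail
(e.g. no germinants); it is never raised as an exception, so zero-germination
dishes flow through grouped summaries under pairwise deletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .lab_io import GerminationSample, LabDataset

PercentBasis = Literal["planted", "germinated"]

#: Default percentile grid for the per-sample time-to-percent columns.
DEFAULT_PERCENTILES: tuple[float, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90)

_EPS = 1e-9


def mean_germination_time(sample: GerminationSample) -> float:
    """Count-weighted mean germination time, days; ``nan`` with no germinants."""
    n = sample.counts
    total = n.sum()
    if total == 0:
        return math.nan
    return float((n * sample.times).sum() / total)


def sd_germination_time(sample: GerminationSample, ddof: int = 1) -> float:
    """Count-weighted standard deviation of germination time, days.

    ``ddof=1`` (default) divides by ``Σn_i − 1``, the sample-SD convention;
    ``ddof=0`` gives the population SD.
    """
    n = sample.counts
    total = n.sum()
    if total < ddof + 1:
        return math.nan
    tbar = (n * sample.times).sum() / total
    ss = (n * (sample.times - tbar) ** 2).sum()
    return float(math.sqrt(ss / (total - ddof)))


def cv_germination_time(sample: GerminationSample, ddof: int = 1) -> float:
    """Coefficient of variation of germination time, percent."""
    st = sd_germination_time(sample, ddof=ddof)
    if math.isnan(st):
        return math.nan
    tbar = mean_germination_time(sample)
    return float(st / tbar * 100.0)


def mean_germination_rate(sample: GerminationSample) -> float:
    """Reciprocal of the mean germination time, 1/day."""
    tbar = mean_germination_time(sample)
    if math.isnan(tbar) or tbar <= 0:
        return math.nan
    return 1.0 / tbar


def uncertainty(sample: GerminationSample) -> float:
    """Shannon entropy (bits) of germination events over counting intervals.

    Intervals with zero counts contribute nothing (0·log2 0 := 0). Zero for
    perfectly synchronized germination; at most log2 of the number of
    occupied intervals.
    """
    n = sample.counts
    total = n.sum()
    if total == 0:
        return math.nan
    f = n[n > 0] / total
    return float(-(f * np.log2(f)).sum())


def synchrony(sample: GerminationSample) -> float:
    """Probability that two random germinants germinated in the same interval.

    ``Z = Σ C(n_i, 2) / C(Σ n_i, 2)``; 1 when all germinants share one
    interval, 0 when no interval holds more than one.
    """
    n = sample.counts
    total = int(n.sum())
    if total < 2:
        return math.nan
    pairs_within = (n * (n - 1) / 2.0).sum()
    pairs_total = total * (total - 1) / 2.0
    return float(pairs_within / pairs_total)


def final_germination_percent(sample: GerminationSample) -> float:
    """Total germinated as a percentage of seeds planted."""
    return float(sample.germinated_total / sample.seeds_planted * 100.0)


def time_to_percent(
    sample: GerminationSample,
    percent: float,
    basis: PercentBasis = "planted",
) -> float:
    """Days until ``percent`` % of the population germinated (T_N).

    The target count is ``percent/100`` of the seeds planted (default) or of
    the seeds that germinated (``basis="germinated"``). Let observation *a*
    be the first at which the cumulative count reaches the target and *b*
    its predecessor (the origin ``t=0, n=0`` when *a* is the first
    observation); the time is interpolated linearly between them::

        T_N = (t_a - t_b) / (n_a - n_b) * (N* - n_b) + t_b

    Returns ``nan`` when the cumulative total never reaches the target.
    """
    if not 0 < percent <= 100:
        raise ValueError("percent must lie in (0, 100]")
    denom = sample.seeds_planted if basis == "planted" else sample.germinated_total
    if denom == 0:
        return math.nan
    target = percent / 100.0 * denom
    cum = sample.cumulative_counts
    times = sample.times
    reached = np.nonzero(cum >= target - _EPS)[0]
    if reached.size == 0:
        return math.nan
    a = int(reached[0])
    t_a, n_a = times[a], cum[a]
    t_b, n_b = (0.0, 0.0) if a == 0 else (times[a - 1], cum[a - 1])
    return float((t_a - t_b) / (n_a - n_b) * (target - n_b) + t_b)


def compute_sample_metrics(
    sample: GerminationSample,
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
    basis: PercentBasis = "planted",
) -> dict[str, float]:
    """All indices for one sample as a flat mapping (``nan`` = missing)."""
    out: dict[str, float] = {
        "germinated": float(sample.germinated_total),
        "final_percent": final_germination_percent(sample),
        "mean_time_days": mean_germination_time(sample),
        "cv_percent": cv_germination_time(sample),
        "mean_rate_per_day": mean_germination_rate(sample),
        "uncertainty_bits": uncertainty(sample),
        "synchrony": synchrony(sample),
    }
    for p in percentiles:
        out[f"t{p:g}_days"] = time_to_percent(sample, p, basis=basis)
    return out


@dataclass
class SummaryResult:
    """Per-sample indices plus treatment × temperature summaries.

    ``means``/``standard_errors``/``counts`` share the grouping columns
    ``treatment, temperature``; metric means use pairwise deletion (each
    metric averages the samples where it is defined, with ``counts`` giving
    the per-metric n) and standard errors are ``sd/sqrt(n)``, missing when
    n < 2.
    """

    per_sample: pd.DataFrame
    means: pd.DataFrame
    standard_errors: pd.DataFrame
    counts: pd.DataFrame


def summarize(
    dataset: LabDataset,
    percentiles: Sequence[float] | "object" = DEFAULT_PERCENTILES,
    basis: PercentBasis = "planted",
) -> SummaryResult:
    """Compute indices for every sample and group them.

    ``percentiles`` may be any sequence of percent values or an object with
    a ``.percentiles`` attribute (e.g. a percentile grid).
    """
    if not dataset.samples:
        raise ValueError("empty dataset")
    if hasattr(percentiles, "percentiles"):
        percentiles = percentiles.percentiles
    rows = []
    for s in dataset.samples:
        row: dict[str, object] = {
            "treatment": s.treatment,
            "temperature": s.temperature,
            "rep": s.replicate,
            "plot_id": s.plot_id,
            "seeds_planted": s.seeds_planted,
        }
        row.update(compute_sample_metrics(s, percentiles, basis=basis))
        rows.append(row)
    per_sample = pd.DataFrame(rows)

    metric_cols = [
        c for c in per_sample.columns
        if c not in ("treatment", "temperature", "rep", "plot_id")
    ]
    grouped = per_sample.groupby(["treatment", "temperature"], sort=True)[metric_cols]
    means = grouped.mean().reset_index()
    ses = grouped.sem(ddof=1).reset_index()
    counts = grouped.count().reset_index()
    return SummaryResult(
        per_sample=per_sample, means=means, standard_errors=ses, counts=counts
    )
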