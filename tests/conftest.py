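"""Shared fixtures and the independent brute-force oracle.

The oracle computes every germination index from the *per-seed expansion*
of a sample: each germinated seed is listed individually with its counting
interval's end time, and the indices are recomputed from first principles
on that list (plain means/SDs, entropy over a grouped tally, pairwise
co-germination counting, a linear scan for time-to-percent). It shares no
code with the package implementation.
"""

from __future__ import annotations

import math
from datetime import datetime

import numpy as np
import pytest

from wetgerm.lab_io import GerminationSample

PLANTING = datetime(2016, 1, 1)


def make_sample(times, counts, seeds=None, temperature=15.0, treatment="A",
                rep=None):
    if seeds is None:
        seeds = int(sum(counts))
    return GerminationSample(
        temperature=temperature,
        treatment=treatment,
        seeds_planted=seeds,
        planting_time=PLANTING,
        observations=list(zip(times, counts)),
        replicate=rep,
    )


def random_sample(rng: np.random.Generator) -> GerminationSample:
    """A random valid sample: random schedule, random interval counts."""
    k = int(rng.integers(1, 12))
    times = np.sort(rng.uniform(0.5, 60.0, size=k))
    while np.any(np.diff(times) <= 1e-6):
        times = np.sort(rng.uniform(0.5, 60.0, size=k))
    seeds = int(rng.integers(1, 60))
    # split a random number of germinants over the k intervals
    germinated = int(rng.integers(0, seeds + 1))
    counts = rng.multinomial(germinated, np.ones(k) / k)
    return make_sample(times.tolist(), counts.tolist(), seeds=seeds,
                       temperature=float(rng.choice([5, 10, 15, 20, 25])))


# --------------------------------------------------------------------------
# brute-force oracle on the per-seed expansion


def expand(sample: GerminationSample) -> list[float]:
    """One entry per germinated seed: its interval's end time."""
    out: list[float] = []
    for t, n in sample.observations:
        out.extend([t] * n)
    return out


def oracle_metrics(sample: GerminationSample, percentiles=(), basis="planted"):
    seed_times = expand(sample)
    n = len(seed_times)
    out: dict[str, float] = {}
    out["final_percent"] = 100.0 * n / sample.seeds_planted
    out["mean_time_days"] = sum(seed_times) / n if n else math.nan
    if n >= 2:
        mean = out["mean_time_days"]
        sd = math.sqrt(sum((t - mean) ** 2 for t in seed_times) / (n - 1))
        out["cv_percent"] = sd / mean * 100.0
    else:
        out["cv_percent"] = math.nan
    out["mean_rate_per_day"] = 1.0 / out["mean_time_days"] if n else math.nan

    if n:
        tally: dict[float, int] = {}
        for t in seed_times:
            tally[t] = tally.get(t, 0) + 1
        out["uncertainty_bits"] = -sum(
            (c / n) * math.log2(c / n) for c in tally.values()
        )
        if n >= 2:
            same = sum(c * (c - 1) / 2 for c in tally.values())
            out["synchrony"] = same / (n * (n - 1) / 2)
        else:
            out["synchrony"] = math.nan
    else:
        out["uncertainty_bits"] = math.nan
        out["synchrony"] = math.nan

    denom = sample.seeds_planted if basis == "planted" else n
    for p in percentiles:
        target = p / 100.0 * denom if denom else math.inf
        reached = math.nan
        cum = 0.0
        prev_t, prev_c = 0.0, 0.0
        for t, c in sample.observations:
            cum += c
            if cum >= target - 1e-9:
                reached = prev_t + (t - prev_t) * (target - prev_c) / (cum - prev_c)
                break
            prev_t, prev_c = t, cum
        out[f"t{p:g}_days"] = reached
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)
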