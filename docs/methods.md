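# Methods

## Scope and data model

`wetgerm` models germination timing of non-dormant seeds in two stages.
First, constant-temperature laboratory trials (petri-dish samples counted
on a schedule) yield per-sample germination indices and, per treatment and
population percentile, a fitted temperature response of germination rate.
Second, that response is integrated over field seedbed records of soil
temperature and soil water potential to predict when each percentile of a
planted population germinates, under the wet-thermal assumption that
progress accrues only while the seedbed is wet enough.

A laboratory sample is the tuple (incubation temperature, treatment label,
seeds planted, planting timestamp, ordered interval counts). Counts are
*per interval*: the number of seeds that germinated since the previous
observation, attributed to the interval's end time — the recorded
observation day. Cumulative-looking rows (total > seeds planted) are
rejected on input. Replicate and plot labels are optional; temperature,
treatment, seed count and planting date are mandatory. Blank count cells
are read as zero with a logged warning rather than rejected, because
field-collected sheets commonly contain them; blank *required* cells are
errors. Historical sheet limits (1,000 samples, 100 observation dates) are
soft warnings only — they were capacity limits of spreadsheet tooling, not
of the model.

## Germination indices

For interval counts `n_i` at elapsed times `t_i` (days since planting,
fractional when timestamps carry a time of day):

- mean time `t̄ = Σ n_i t_i / Σ n_i`; mean rate `1/t̄`;
- `CV_t = s_t/t̄ × 100` with `s_t` the count-weighted standard deviation
  using denominator `Σ n_i − 1` (the sample-SD convention; the
  population-SD variant is available via `ddof=0`);
- uncertainty `U = −Σ f_i log₂ f_i` bits with `f_i = n_i/Σn_i` and
  `0·log₂0 := 0`;
- synchrony `Z = Σ C(n_i,2) / C(Σn_i,2)`;
- `T_N`: with target count `N* = N/100 ×` seeds planted, find the first
  observation `a` whose cumulative count reaches `N*` and interpolate
  linearly from its predecessor `b` (the origin when `a` is first):
  `T_N = (t_a−t_b)/(n_a−n_b)·(N*−n_b) + t_b`.

Every index is *missing* (NaN), never an exception, when its preconditions
fail (no germinants for `t̄`/`U`; fewer than two for `CV_t`/`Z`; target
never reached for `T_N`). Grouped treatment × temperature summaries use
pairwise deletion — each metric averages the samples where it is defined,
with the per-metric n and the standard error `sd/√n` reported (missing for
n < 2).

The percentile denominator is seeds **planted** by default, with
`basis="germinated"` as the alternative. The planted basis is what the
field predictor means by "50 % of the population", and it is the default
throughout; both bases are implemented and tested.

## Rate curves

Per treatment × percentile: `T_N` per dish → replicate mean within each
temperature (dishes that never reached N are excluded; temperatures where
no dish reached N are dropped) → rate `1/mean(T_N)` → ordinary least
squares fit of `A·T² + B·T + C` over the surviving temperatures (via
`numpy.polyfit`, unweighted — three free parameters, so at least three
temperatures are required; fewer → the percentile is skipped with a
warning). `R²` is computed about the mean and the adjusted form uses p = 2
regressors (T, T²); with exactly three points the fit interpolates
(`R² = 1`) and the adjusted value is undefined. Averaging times before
inverting (rather than averaging `1/T_N`) follows the convention of
summary-average worksheets feeding a single fitted curve; the mean-rate
alternative is available as `rate_averaging="mean-rate"` and covered by a
test — with homogeneous replicates the two agree, and with heterogeneous
replicates the inverse-mean is the smaller (harmonic-vs-arithmetic
ordering).

Evaluation clamps negative polynomial values to zero (negative progress is
physically meaningless) and zeroes the rate below a freeze floor, 0 °C by
default (configurable; `-inf` disables it). Extrapolation beyond the fitted
temperature range is permitted; the fitted range is stored on each curve so
callers can flag it.

## Field accumulation

Records are interpreted left-hold (piecewise constant over each interval —
the simplest defensible quadrature for hourly sensors). For each interval
the increment is `rate(T) × Δt` when the record is wet and both sensor
values are present, else zero. Wetness is `Ψ ≥ Ψ_b` — the boundary counts
as wet by default, configurable to strict inequality. `Ψ_b` defaults to
−1.5 MPa, the conventional base water potential for cool-season cold-desert
species; it is a per-model parameter and a per-call override. `Δt` is the
record gap capped at `max_gap` (default three nominal steps, i.e. 3 h for
hourly data): a long sensor hole contributes at most one cap's worth of
accrual and is logged. Completion is the first instant accumulated progress
reaches 1, interpolated linearly inside the final interval (the
alternative — snapping to the record timestamp — differs by at most one
step). Planting time-of-day is midnight of the planting date.

Planting-date scans precompute the per-interval increments once per curve;
a planting date is then a suffix sum, which is arithmetically identical to
accumulating each date independently (asserted by test). Because increments
are non-negative, the predicted germination date is non-decreasing in
planting date, which makes the spring threshold a single crossing: the
spring-planting-date query returns the earliest scanned planting date whose
prediction falls on/after the cutoff (default: the 1 March following the
scan start). A planting date with *no* germination counts as meeting the
criterion only when the series itself extends to the cutoff (reported as
`met-by-non-germination`); if the series ends before the cutoff the
question is undecidable and the result is `indeterminate`.

## Synthetic data

The laboratory generator draws, per dish, a binomial number of germinable
seeds (default germinable fraction 0.9 — final germination in such trials
is rarely 100 %) and, for each, a germination time from a law whose
*median rate* follows a known quadratic in temperature. With the default
Weibull time law the q-quantile is the median times a temperature-free
factor, so every percentile's true rate curve is itself a quadratic — the
fitted family is exactly right and any recovery error is estimation error,
not misspecification. A log-logistic option provides deliberate
misspecification for robustness checks, and a degenerate `fixed` law gives
exact point-mass tests. Times are binned onto the observation schedule
(attributed to the first observation day ≥ the true time), so the only
noise is multinomial counting noise. Defaults mirror a typical wet-thermal
trial: 5/10/15/20/25 °C, 7 replicate dishes of 25 seeds, counts every
2 days to day 60. The default rate quadratic (−0.0008, 0.0306, −0.083)
gives a cool-season response: positive between ~3 and ~35 °C, T50 ≈ 20 days
at 5 °C and ≈ 5 days at 15–25 °C.

The field generator produces evenly stepped records (default hourly):
temperature = seasonal trend (constant or piecewise-linear anchors) +
diurnal sinusoid (default amplitude 8 °C, typical of 1–3 cm seedbed depth)
+ Gaussian sensor noise; moisture alternates between a wet (−0.3 MPa) and a
dry (−3 MPa) water potential on an explicit window schedule or via a
two-state process with exponential dwell times. Both generators are
byte-reproducible for a given seed.

What the generators do **not** emulate — and therefore what passing tests
do not demonstrate about real data: dormancy cycling and after-ripening
(real responses drift between seasons; adjusting Ψ_b can absorb some of
this but is left to the user), non-quadratic rate responses near the
thermal limits, correlated sensor error and drift, freeze–thaw artefacts
in gypsum-block readings, and irregular observation schedules with
recording mistakes.

## Numerical choices and problem sizes

- Target-reached comparisons in `T_N` use a 1e-9 absolute tolerance on
  counts so exact cumulative hits interpolate to the observation time
  itself.
- Progress-complete comparisons use a 1e-12 tolerance so a closed-form
  completion landing exactly on a record boundary is deterministic.
- Curve lookup at an off-grid percentile falls back to the nearest fitted
  percentile with a warning (ties break toward the lower percentile).
- Missing metrics are NaN end to end; CSV round-trips preserve elapsed
  times to better than 1e-9 days via ISO timestamps with microseconds.
- Test and acceptance runs use desk-scale problems — 200-sample oracle
  sweeps, 35-dish simulated trials (5 temperatures × 7 reps × 25 seeds),
  single-site-year hourly series of up to nine months, and ~180-date scans
  — chosen so the full suite completes in seconds while every code path is
  exercised at realistic sizes.

## Known limitations

- The model predicts germination, not emergence or establishment.
- A single Ψ_b per model: no percentile-specific base water potential.
- OLS quadratic only; no non-linear response families.
- Dishes that never reach a percentile are excluded from that percentile's
  average rather than treated as censored observations; with heavy
  non-germination this biases fitted rates toward the faster dishes.
- Gap capping bounds the damage of sensor holes but cannot recover what the
  seedbed actually did during them.
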