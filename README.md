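# wetgerm

Wet-thermal seed germination modelling for restoration ecology and seed
science: compute classical germination indices from constant-temperature
laboratory trials, fit per-percentile rate-vs-temperature curves, and apply
them to field seedbed microclimate data to predict when a planted seed
population will germinate — including daily planting-date scans against a
spring-germination cutoff.

Direct seeding in cold-desert systems (e.g. the sagebrush steppe) often
fails when seeds sown in autumn germinate before winter and the seedlings
die of frost or drought. A wet-thermal accumulation model predicts
germination timing from soil temperature and soil water potential in the
seed zone: progress toward germination accrues at a temperature-dependent
rate, but only while the seedbed is wet enough (water potential at or above
a base threshold Ψ_b, by default −1.5 MPa). The toolkit answers the
practical question: *how late must I plant so that 50 % of the population
germinates on or after 1 March?*

## The model

From interval germination counts n_i recorded at elapsed times t_i:

- mean germination time t̄ = Σ n_i t_i / Σ n_i, and mean rate 1/t̄ (1/day);
- coefficient of variation CV_t = s_t / t̄ × 100, with s_t the
  count-weighted sample standard deviation;
- uncertainty U = −Σ f_i log₂ f_i (bits), f_i = n_i / Σ n_i — the Shannon
  entropy of germination events over counting intervals;
- synchrony Z = Σ C(n_i, 2) / C(Σ n_i, 2) — the probability that two random
  germinants share an interval;
- T_N, the time to N % germination, linearly interpolated between the
  bracketing cumulative counts.

For each treatment and each percentile N on a user grid, the germination
rate 1/T̄_N is regressed on incubation temperature T with a second-order
polynomial, rate_N(T) = A·T² + B·T + C. Field prediction then integrates
rate_N(T(t)) over a soil-sensor time series, counting only wet records
(Ψ ≥ Ψ_b) and temperatures above a freeze floor (0 °C by default); the
percentile germinates when accumulated progress reaches 1.

## Worked example

Everything below uses synthetic data generated by the package itself, so it
runs anywhere:

```sh
wetgerm simulate --kind lab --seed 7 --out lab.csv
wetgerm simulate --kind field --seed 7 --out field.csv \
    --start 2015-09-01 --end 2016-05-01
wetgerm metrics lab.csv --out-dir metrics
wetgerm fit-model lab.csv --grid 10:90:10 --out model.csv
wetgerm plant-window model.csv field.csv --target-percent 50 \
    --scan-start 2015-09-01 --scan-end 2016-02-28 --cutoff 2016-03-01 \
    --out window.csv
```

`metrics/data_averages.csv` starts (columns truncated):

```
treatment,temperature,seeds_planted,germinated,final_percent,mean_time_days,...
SYNTH,5.0,25.0,22.71,90.86,21.49,...
SYNTH,10.0,25.0,22.57,90.29,8.09,...
SYNTH,15.0,25.0,23.0,92.0,6.32,...
```

— at 5 °C the simulated seedlot needs ~21.5 days on average to germinate,
at 15 °C only ~6.3. `model.csv` holds one fitted quadratic per percentile:

```
treatment,percentile,A,B,C,r2,adj_r2,tmin,tmax,n_points,psi_b
SYNTH,10.0,-0.0013466,0.0535029,-0.1434555,0.97995,0.95989,5.0,25.0,5,-1.5
SYNTH,20.0,-0.0010711,0.0422579,-0.1135618,0.98880,0.97760,5.0,25.0,5,-1.5
...
```

and the planting-window scan prints

```
SYNTH: 2016-02-18 (germinates-after-cutoff)
```

meaning that on this site-year, sowing on or after 18 February is the
earliest planting for which half the population is predicted to germinate
on or after 1 March; anything sown earlier germinates during winter.

The same pipeline is available as library calls (`read_lab_counts`,
`summarize`, `build_rate_curves`, `predict_planting_scan`,
`spring_planting_date`, ...) — see the module docstrings.

## Input formats

- **Lab counts (CSV)**: a `# planting_date: YYYY-MM-DD` header line, then
  columns `temperature,rep,plot_id,treatment,seeds_planted` followed by one
  column per ISO observation date holding *interval* (not cumulative)
  counts. An XLSX reader for the classic entry-sheet layout (planting date
  in cell B8, dates from column F) is also provided.
- **Field series (CSV)**: `timestamp,soil_temp_c,water_potential_mpa`,
  one file per site-year, typically hourly sensors at 1–3 cm depth.

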