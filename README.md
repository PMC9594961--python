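# ethobudget

Analyses for **continuous on-board behaviour records** from GPS-accelerometer
tags. Modern trackers can classify accelerometer data on the tag itself,
producing one behaviour code (out of a fixed 8-class ethogram: dabbling,
feeding, floating, flying, preening, resting, running, walking) every 2 s,
alongside hourly GPS fixes and 10-min mean ODBA (overall dynamic body
acceleration, an energy-expenditure proxy). `ethobudget` is for movement
ecologists who want to know what that continuous stream buys them over
burst-sampled accelerometry or GPS alone:

1. **Time-activity-budget sampling error** (`budget_sampling`). If behaviour
   were sampled every *i* seconds instead of continuously, daily budgets
   acquire an error quantified by the *error ratio*

   ```
   error_ratio_ij = sd_sampling_ij / p_j
   ```

   the across-day SD of (continuous − sampled) daily proportion differences
   for behaviour *j* at interval *i*, scaled by the behaviour's mean daily
   proportion *p_j*. Under independent records its expectation is binomial,

   ```
   E[error_ratio_ij] = sqrt(p_j (1 − p_j) / n_i) / p_j,
   ```

   with *n_i* records per day — a planning tool for choosing sampling
   schedules. Serial dependence at lag *i* is measured by

   ```
   dependence = Σ_k |q_k − p_k| / (2 (1 − p_min))  ∈ [0, 1],
   ```

   where *q* is the next-behaviour distribution at that lag conditional on a
   focal behaviour. A log-log OLS regression of the error ratio on sampling
   interval (minutes) and *p* (percent) summarizes the scaling (slopes →
   ±1/2 in the independent limit).

2. **Daily travel distance** (`travel_distance`). GPS-based distance (chained
   haversine between hourly fixes) versus behaviour-based distance (daily
   flight time from ≥ 6 s flight bouts × 15 m/s cruise speed), compared with
   a paired t-test. Tortuous routes and multiple flights between fixes make
   the GPS estimate a lower bound.

3. **Behaviour/energy home ranges** (`home_range`). Every behaviour and ODBA
   record is geolocated by its nearest-in-time fix and binned into 30 × 30 m
   cells carrying occupancy time, behaviour proportions, energy percentage
   and diel/daily usage profiles; core cells (≥ 24 h) are grouped into
   geographic sites and clustered hierarchically by behaviour and by
   hour-of-day.

A **synthetic tag-data generator** (`synthetic_data`) — a sticky Markov
ethogram plus a scheduled multi-site roost/feed routine with analytic
ground-truth distances — makes every stage testable without field data.

## Worked example

```python
import ethobudget as eb
from ethobudget import budget_sampling as bs, travel_distance as td

# 100 days whose 2-s epochs are i.i.d. draws (flying 1%, resting 25%, ...)
days = eb.simulate_iid_days(eb.synthetic_data.IID_VALIDATION_BUDGET, 100, seed=42)
table = bs.sampling_error_table(days)
fit = bs.fit_loglog_regression(table)
```

Selected rows of `table` (rare flying vs common resting):

```
 interval_s behaviour        p  error_ratio
         60    flying 0.009930     0.250647
         60   resting 0.249638     0.039192
        600    flying 0.009930     0.766568
        600   resting 0.249638     0.147519
       3600    flying 0.009930     1.555674
       3600   resting 0.249638     0.336240
```

At hourly sampling the flying budget's error ratio is 1.56 — the sampling
noise exceeds the quantity being estimated — while resting stays at 0.34.
The fitted scaling law,

```
ln(error ratio) = -1.447 + 0.510 ln(interval) -0.513 ln(p),  R^2 = 0.996
```

recovers the ±1/2 binomial slopes, and
`bs.expected_error_ratio(0.01, 24) = 2.03` says hourly sampling of a 1%
behaviour is hopeless before any data are collected.

Distance, on a simulated commuting duck whose flight paths are 1.5× longer
than the straight lines between sites:

```python
cfg = eb.SimulationConfig.commute(tortuosity=1.5, n_days=3, seed=0)
seqs, track, odba, truth = eb.simulate_tag_data(cfg)
td.build_daily_distance_records(seqs, track, timezone="UTC")
```

```
       day  gps_distance_m  behaviour_distance_m  n_fixes  total_flight_s
2021-01-01         27000.0               40500.0       24            2700
2021-01-02         36000.0               54000.0       24            3600
2021-01-03         36000.0               54000.0       24            3600
```

The behaviour-based estimate exceeds the GPS chain by exactly the simulated
tortuosity (50%), the mechanism by which hourly fixes understate true travel.

## Command line

```sh
ethobudget simulate     --config sim.yaml --out out/           # synthetic CSVs + truth
ethobudget budget-error --behaviour b.csv --out out/
ethobudget distance     --behaviour b.csv --gps g.csv --out out/
ethobudget homerange    --behaviour b.csv --gps g.csv --odba o.csv --out out/
ethobudget run-all      --config cfg.yaml --out out/ --seed 1
```

Input CSVs: `animal_id,timestamp,behaviour` / `animal_id,timestamp,lat,lon` /
`animal_id,timestamp,odba`, ISO-8601 timestamps, header row required; other
schemas attach via a column-mapping entry in the YAML config. Cell polygons
export as RFC 7946 GeoJSON. Every run writes a `manifest.json` with config
hash, seed, file digests and all filter tallies.

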