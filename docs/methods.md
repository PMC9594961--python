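# Methods

## Data model

The unit of analysis is the *animal-day*: an ordered sequence of 2-s
behaviour epochs (≤ 43,200 per day) drawn from the closed 8-class ethogram
(dabbling, feeding, floating, flying, preening, resting, running, walking —
alphabetical, and that order is the canonical index map exported by
`ethogram_index_map`). Days are cut at local civil midnight in a
configurable study timezone (default `Australia/Melbourne`; the motivating
deployments were in south-eastern Australia). GPS fixes are hourly WGS84
positions; ODBA values are non-negative 10-min window means in arbitrary tag
units. Readers validate invariants on ingest (closed ethogram, strictly
increasing timestamps, coordinate ranges, non-overlapping ODBA windows) and
a column-mapping config adapts foreign table schemas.

## Sampling error of time-activity budgets

For each sampling interval *i* (default grid 10 s – 60 min) a day is
downsampled deterministically: the first epoch, then every (*i*/2)-th
record. The daily difference (continuous − sampled) proportion is computed
per behaviour; its across-day sample SD (divisor n−1) scaled by the
behaviour's mean daily proportion *p_j* is the error ratio. Analysis days
must cover ≥ 99.5% of a day (≥ 42,984 epochs), and each animal's first and
last tracking days are discarded.

Choices where the procedure was under-determined:

* **p_j** defaults to the mean of daily proportions; a pooled-epochs variant
  is available (`p_mode="pooled"`). The two coincide on complete days.
* The deterministic first-record start is the default; an `all_offsets`
  variant averages the sampled budget over every start offset as a
  robustness check.
* Rows with p_j = 0 are flagged undefined; rows with error ratio 0 are
  excluded from the log regression with a warning (their log is undefined).

**Independence expectation.** Treating records as independent Bernoulli
draws gives E[error ratio] = √(p(1−p)/n)/p with n records per day. This is
the right planning quantity for prospective schedules (n ≪ N). When the
error ratio is *measured* as continuous-minus-sampled on the same day,
however, the sampled records are a subset of the continuous reference, so
the difference has variance p(1−p)(1/n − 1/N) with N = 43,200: a
finite-overlap factor √(1 − n/N) ≈ 0.894 at the 10 s interval (n/N = 0.2)
and ≥ 0.98 beyond 30 s. `expected_error_ratio` exposes the correction via
its `day_epochs` argument; simulation tests show the pipeline matches the
corrected form at every interval, and the uncorrected form everywhere except
the shortest interval, where the ~11% systematic overlap offset exceeds
Monte-Carlo noise at 500 days (≈ 3 SE). The uncorrected comparison at 10 s
is therefore expected to fail a 3-SE equivalence check — a property of the
approximation, not of the pipeline.

**Dependence.** At lag *i*, q is the next-behaviour distribution over all
same-day epoch pairs (t, t+i) with the focal behaviour at t, pooled across
days; dependence = Σ|q−p| / (2(1−p_min)) with p_min the minimum of the 8
mean proportions — the unique normalization for which the upper bound 1 is
attained exactly (point mass on the rarest class). Pairs never span
midnight. On a single i.i.d. day the estimator has a counting-noise floor
E[dep] ≈ √(2/(π·p_focal·43,200)) · Σ_k √(p_k(1−p_k)) / (2(1−p_min)) —
about 0.009 for a 25% focal but 0.03–0.04 for a 1% focal; near-zero
dependence on one day is therefore only resolvable for common focals, and
multi-day pooling is needed for rare ones.

**Regression.** ln(error ratio) is regressed (OLS, statsmodels) on
ln(interval in minutes) and ln(p in percent). With the full 9 × 8 grid the
design has df = (2, 69). In the independent limit ln E = −½ln n − ½ln p +
½ln(1−p) and n ∝ 1/interval, so slopes approach +½/−½; the ½ln(1−p) term
biases the p-slope away from −½ by the OLS projection of ln(1−p) on ln p,
which is why the i.i.d. validation budget (below) keeps max p ≤ 0.25.

## Travel distance

GPS daily distance chains haversine legs (R = 6,371 km) over consecutive
same-day fixes; days need a configurable minimum fix count (default 24,
hourly schedule). Behaviour-based distance is daily flight time × cruise
speed (default 15 m/s, a mallard-like non-migratory cruise), counting only
maximal flying runs ≥ 6 s (3 epochs, boundary inclusive) to suppress
isolated wing-flap epochs; bouts never span midnight (day-partitioned
sequences re-test each part). Walking/running displacement is ignored by
design. The paired t-test is oriented behaviour − GPS (positive = behaviour
larger) and |t| is reported alongside; both readings of a "% larger"
headline (max ratio, max excess) are emitted because the two are easily
conflated.

## Home range

Records are geolocated by the nearest-in-time fix (ties to the earlier fix;
outside the track span, to the nearest end). Positions are projected into a
local tangent-plane equirectangular projection (x = R cosφ₀ Δλ, y = R Δφ)
centred on the data; over the few-km extents of a 30 m grid its distortion
is negligible (< 0.05 m at 5 km), and the inverse is exact, which the
GeoJSON round-trip test exploits. The grid origin snaps *down* to cell-size
multiples of the minimum easting/northing, so cell membership is a pure
function of the data and translation by exact cell multiples only relabels
cells.

Occupancy is 2 s per behaviour record (behaviour records are the continuous
time base); ODBA contributes only to the energy percentage (cell ODBA sum /
total, summing to 1 over occupied cells). Core cells require ≥ 24 h total
occupancy (inclusive). Geographic sites are connected components of core
cells under queen (8-neighbour) adjacency with a 1-cell gap tolerance
(configurable) — a component-based reading of "nearby cells form one site".
Hierarchical clustering (scipy `linkage`) uses complete linkage + euclidean
by default on behaviour proportions or 24-bin local-hour profiles; the
k-cut is user-supplied (default 4) and the full merge tree is always
returned so any cut can be audited.

## Synthetic data

The generator emulates the statistical structure the analyses assume, not
ducks in full realism:

* **Behaviour**: first-order sticky Markov chain P = sI + (1−s)1πᵀ at the
  2-s scale. The mixture form pins the stationary budget to π exactly while
  the diagonal weight s (default 0.97, mean bout ≈ 67 s) tunes short-lag
  dependence. The default π is resting-dominated (0.35) with flying rarest
  (0.01). A separate i.i.d.-epoch generator provides the independence regime
  for oracle tests; its budget (0.05, 0.15, 0.20, 0.01, 0.14, 0.25, 0.04,
  0.16 in ethogram order) spans rare→common with flying at 1% while keeping
  max p ≤ 0.25 so the ±½ slope limit applies (see above).
* **Movement**: a diurnal schedule maps hour-of-day to a site role (roost at
  night, feed 06–18 by default); same-role sites rotate by day, giving
  multi-day alternation among 2 roosts + 2 feed sites 450–1,800 m apart.
  Commutes are *scheduled* flights at the top of the changed hour, flown at
  the cruise speed along a two-segment dog-leg whose path length is exactly
  tortuosity × displacement, so ground-truth distances are analytic; chain
  flying outside a scheduled commute is flown out-and-back (path, no net
  displacement). Walking/running is a bounded random walk inside the site
  radius (default 12 m — compact sites whose occupancy concentrates in
  one-to-few grid cells, as for a roost pond corner or a feed patch);
  default leg lengths are exact multiples of the 2-s flight step so bout
  durations are exact. The local plane converts to WGS84 via the tangent
  projection at (−38.0, 144.5).
* **ODBA**: per-epoch Gaussian draws with behaviour-specific mean/sd
  (flying ≈ 20× resting), clipped at 0, averaged per 10-min window.
* The `commute` scenario (two sites 9 km apart, 3–4 single hourly flight
  legs per day, walking/running speeds 0) is the degenerate case where
  behaviour- and GPS-based distances coincide analytically at tortuosity 1.

What the generator does **not** emulate: classifier error, GPS position
noise, missing data/transmission gaps, weather-dependent routines, wind
drift, or migratory movement. Passing tests therefore validate the
estimators' arithmetic and their behaviour under the stated statistical
structure, not robustness to those field realities.

## Problem sizes and numerical choices

Validation runs use 500 i.i.d. days for the sampling-error oracle (bootstrap
SEs from 500 day-resamples), 10–20 days of sticky-chain records for
dependence curves, 3–4 days of commuting for distance identities, and a
20-day four-site routine for home-range recovery — sized so every core cell
clears the 24 h threshold even in the worst-case 2×2 cell straddle of a
site (roost: 11 h/day × 10 days ÷ 4 > 24 h). Stationary distributions come
from the eigen decomposition with a power-iteration fallback (tol 1e-12)
and a warning for reducible/periodic chains. All simulation randomness
flows through seeded `numpy` Generators; identical seeds give byte-identical
outputs, which the pipeline manifest digests verify.

## Known limitations

* The error-ratio statistic inherits the finite-overlap subtlety above;
  quote the uncorrected expectation only for prospective n ≪ N schedules.
* A 3-SE-everywhere equivalence band over a 72-cell grid has an ≈ 18%
  per-seed chance of one benign Monte-Carlo excursion; fixed seeds make test
  outcomes deterministic, but single-cell excursions near 3 SE should be
  read accordingly.
* Geographic "sites" depend on the gap tolerance; the default (1 cell)
  merges cells separated by one empty cell.
* Nearest-fix geolocation smears records near transit hours onto the
  departure fix (≈ ½ fix interval); with hourly fixes this is a ~30 min
  blur, visible as minority behaviours in site cells.
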