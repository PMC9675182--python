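# Methods

## The exposure metric and the event definition

The pipeline works on daily district temperature series (tmax, tmin in
degC).  Its exposure metric is the diurnal temperature range,

    DTR(d) = tmax(d) - tmin(d),

a variability measure with an established association with short-term
mortality.  The mean daily temperature is the midrange,

    tmean(d) = (tmax(d) + tmin(d)) / 2,

which is the only daily mean computable from max/min records; it is what
district minimum-mortality temperatures (MMTs) are compared against.

A day **qualifies** when

1. DTR(d) exceeds the national health-based alert threshold
   (default 12.8 degC), and
2. tmean(d) >= MMT of the district, and
3. neither temperature is missing.

A **heatwave event** is a maximal run of consecutive qualifying days of
length >= `min_duration` (default 2 days).  Both defaults are inputs to
this pipeline, not outputs: the 12.8 degC value is a previously estimated
national mortality threshold and the 2-day duration follows the
heat-mortality literature.  Each event is characterised by start/end/peak
dates, duration (inclusive day count), peak and mean DTR over its
qualifying days, and cumulative exceedance sum(DTR - threshold) in
degC-days.

### Conventions and tie-breaks

- **Exceedance is strict** (`DTR > threshold`).  "Exceedance" reads most
  naturally as strict and printed counts cannot adjudicate it; the `>=`
  convention is available via `ThresholdConfig(strict_exceedance=False)`.
- **MMT masking is per-day, before run detection.**  A below-MMT day
  terminates a run exactly like a sub-threshold day; this is the only
  reading consistent with excluding *days* from the analysis.
- **No gap-joining by default.**  Marine-heatwave conventions merge events
  separated by short gaps; here a single non-qualifying day always ends an
  event (`max_gap=0`; a configurable bridge exists but is off by default
  because gap-joining can fabricate long headline durations).
- **A missing day terminates a run.**  Missing observations are excluded
  from analysis, never interpolated or bridged — an interpolated day would
  manufacture exposure.
- **Peak** is the event day of maximum DTR (the detection metric), earliest
  day on ties, for determinism; the day of maximum tmax is reported as an
  auxiliary field.
- **Attribution**: an event belongs to the austral season (DJF summer, MAM
  autumn, JJA winter, SON spring) and calendar year of its *start* date, so
  a multi-month event is counted once.

### Descriptive statistics

Per-district mean, sample SD (n-1 denominator) and 95th percentile of
tmax, tmin and DTR are computed over non-missing days.  The percentile
interpolates linearly between closest order statistics (numpy's default);
other conventions (nearest-rank, Stata's default) differ in the last
decimal on small samples, so the choice is documented here and fixed.
Statistics are computed over all non-missing days of the period; a date
range filter is available for seasonal subsets.

## Climate-scenario projection (delta-change)

Future series are built additively: `future_t(d) = observed_t(analogue(d))
+ delta_var(d)`, with tmax and tmin perturbed by their own deltas.
Additive delta-change is the standard first-order downscaling of scenario
anomalies onto an observed baseline; multiplicative scaling is not offered
for temperature.

- **Calendar mapping.**  The 6-year observed calendar (whole calendar
  years required) is cycled across the projection period (default
  2020-2039), aligning by month and day; Feb 29 in a future leap year maps
  from Feb 28 when its source year lacks one.  Days missing in the
  observed base stay missing in the future series.
- **Anomaly fields** are per-variable deltas, either per-district series
  or a regular lat/lon grid interpolated bilinearly (via
  `scipy.interpolate.RegularGridInterpolator`) to district centroids, with
  no extrapolation outside the grid.  Time resolution is monthly
  (month-of-year climatology broadcast to all days of the month) or daily.
- **Fixed thresholds.**  The DTR threshold and district MMTs are held at
  their present-day values in all scenarios — no acclimatisation
  adjustment — which likely overestimates future event counts.  This is a
  deliberate, documented limitation of stationary health thresholds.
- **Degenerate days.**  If a projected day ends with tmax < tmin (possible
  when the tmin delta exceeds a small observed DTR), the day is set fully
  missing with a warning rather than silently clipped.
- **Comparison tables** report observed and future event counts *and*
  event-days separately, with percent change `100*(future - observed) /
  observed` given both raw and rounded to whole percent; the change is
  reported as undefined (empty), not infinite, where the observed count is
  zero.  Note the periods deliberately differ in length (6 observed years
  vs ~20 projected), as in the underlying study design; the tables carry
  raw counts so any normalisation can be applied downstream.

## Synthetic data generator

Because the source observations are not redistributable, every stage is
exercised on generated data with known ground truth.

The generator draws, per district regime,

    tmax(d) = mu_max + A_max * cos(2*pi*(doy - 15)/365.25) + e_max(d)
    DTR(d)  = max(dtr_base + (A_max - A_min) * cos(...) + e_dtr(d), 0.05)
    tmin(d) = tmax(d) - DTR(d)

with `e_max`, `e_dtr` independent stationary AR(1) processes (default
lag-1 coefficient 0.7, marginal SD 2 degC).  Construction via DTR
guarantees tmax >= tmin on every day.  Design notes:

- **Seasonal phase** peaks at day-of-year 15 (austral mid-summer).
- **AR(1), not i.i.d., noise**: heat spells persist for days; with i.i.d.
  noise, >= 2-day exceedance runs would be unrealistically rare.  The 0.7
  coefficient gives day-to-day temperature autocorrelation in the range
  typical of daily station series.
- **Coastal vs inland regimes**: coastal districts default to DTR bases of
  ~8-11.5 degC, inland ~14-19 degC, matching the published descriptive
  ranges for the region; with 2 degC noise the regimes' deterministic
  separation dominates, so coastal mean DTR < inland mean DTR in every
  replicate.  Unequal seasonal amplitudes (A_min > A_max) place the DTR
  maximum in winter/spring, as continental interiors show.
- **Missingness** is i.i.d. per day at rate 0.16 by default (the emulated
  aggregate); a block-outage mode exists for stress tests.  Masking a day
  blanks both temperatures.
- **Planted events** set DTR to threshold + boost on each day of a window
  (shifting the level so tmean clears the MMT), give the designated peak
  day an extra 1 degC (otherwise all planted days tie and the recovered
  peak would be decided by floating-point noise), and depress the single
  day on each side of the window below threshold, so detection must
  recover the boundaries exactly.  Windows whose one-day guard bands touch
  are rejected — a shared guard/planted day would make exact recovery
  ill-posed.
- **Scales.**  The default fixture is 6 districts (3 coastal, 3 inland) x
  2191 days, which keeps the test suite fast while exercising every code
  path at full temporal scale; `full_scale_regimes()` reproduces the
  50-district shape used by the `analysis/` drivers.

What passing on synthetic data does *not* show: the generator matches only
first/second moments and persistence, not ENSO-scale interannual anomalies,
spatial correlation between districts, or non-random (instrument-outage)
missingness, so the headline *counts* from the analysis scripts
characterise the generator, not the real region.  The arithmetic identities
(calendar counts, worked event duration, percent changes) and the
structural guarantees (oracle equivalence, planted recovery, projection
identities) are data-independent.

## Numerical and interface choices

- Thresholds are compared in double precision with no tolerance; a day at
  exactly the threshold does not qualify under the strict convention.
- `pct_change` rounds with Python's banker's rounding for presentation and
  always retains the raw value.
- Descriptive statistics require >= 2 non-missing days; fewer is an error,
  not a NaN.
- Metadata validation is hard-fail: MMT outside [10, 45] degC, coordinates
  out of range, duplicate district ids, and tmax < tmin rows (the last are
  flagged to missing with a warning rather than rejected, since a sensor
  error on one day should not discard a district).
- CSV is the interchange format throughout (long daily format; anomaly
  long format with month or date time keys); the column mapping is
  configurable so differently headed exports load without editing.

## Known limitations

- One series per district is assumed; station-to-district aggregation is
  out of scope and left upstream.
- No climatology-percentile threshold mode (the point of this pipeline is
  the fixed health-based threshold); a hook exists in `ThresholdConfig`.
- No bias correction beyond delta-change, no GCM ensemble handling.
- Mortality modelling — the derivation of the 12.8 degC threshold and of
  district MMTs — is prior work; both enter here as validated inputs.
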