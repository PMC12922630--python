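# Methods

## The exposure model

The quantity of interest is the annual count of *potentially hazardous
heat days*: calendar days on which the daily maximum indoor (shaded)
wet-bulb globe temperature at a location exceeds a fixed threshold. The
default threshold is 28 °C, the NIOSH recommended exposure limit for
acclimatised workers at moderate workloads (234–349 W); 26 °C and 30 °C
are supported as sensitivity settings. "Exceeds" is read strictly
(`>`); a `strict_exceedance=False` switch gives `>=` for sensitivity.

WBGT is not observed on climate grids, so it is estimated from the two
variables PRISM-style products provide, daily maximum temperature and
daily maximum vapour pressure deficit, in three steps.

**Humidity from VPD.** VPD is saturation vapour pressure minus actual
vapour pressure, so `RH = 100·(1 − VPD/e_s(T))`. Saturation vapour
pressure uses the Magnus form over water,
`e_s(T) = 6.112·exp(17.67·T/(T + 243.5))` hPa. Pairing the day's
maximum temperature with the day's maximum VPD is the conservative
(driest-hour) pairing; the recovered RH is clamped to [0, 100] % to
absorb formulation mismatches between the VPD producer's saturation
curve and ours. The Magnus coefficients are configurable because the
producer's exact formulation is generally not documented; any
discrepancy shifts recovered RH by well under a percentage point over
the relevant range.

**Heat index.** The US National Weather Service procedure, taken
verbatim: compute the simple Steadman-derived branch
`0.5·(T + 61.0 + (T − 68.0)·1.2 + RH·0.094)` in °F; where that value
reaches 80 °F, replace it with the nine-coefficient Rothfusz regression
plus the documented low-humidity subtraction (RH < 13 %, T 80–112 °F)
and high-humidity addition (RH > 85 %, T 80–87 °F). All coefficients
are loaded from one machine-readable table
(`src/hazardheat/data/heat_index_constants.json`) so the implementation
can be audited against independent transcriptions, and the test suite
does exactly that over a 21 × 21 temperature–humidity grid at 0.1 °F
tolerance.

One property of the published procedure is worth knowing: the two
branches do not join continuously. At air temperatures between roughly
27 and 28 °C the switch to the regression can *lower* the heat index by
up to ~0.9 °F-equivalent as humidity rises. We reproduce the procedure
faithfully rather than smoothing it; the monotonicity property "drier
air never increases WBGT" therefore holds exactly for Tmax ≥ 28 °C
(where every humidity falls on the regression branch) and is tested
there.

**Indoor WBGT.** A quadratic in the heat index (°F):
`WBGT(°C) = a·HI² + b·HI + c`, defaults `(−0.0034, 0.96, −34)`, the
occupational-heat (Bernard-lineage) transform for indoor/shaded
conditions with a fixed 0.5 m s⁻¹ wind and no radiant load. The
transform is trusted on HI ∈ [70, 115] °F; outside it the code warns
and extrapolates rather than failing, because a grid will always
contain harmless cold days. Construction verifies the quadratic is
strictly increasing over the trusted range (the parabola's vertex sits
near 141 °F, safely above it). Coefficients are config-overridable;
with `(0, 5/9, −160/9)` the transform degenerates to a unit conversion,
which the tests exploit.

Missing daily values are NaN and propagate through the whole chain;
they are never imputed or dropped. A facility-year containing any
missing day is flagged incomplete, excluded from window means, and
reported in a completeness sidecar.

## Exposure, disparity, trends

**Person-days.** Facility population (a single snapshot year, applied
unchanged to every year of the window — no interpolation) times the
facility's mean annual exceedance days over the exposure window
(default: the last five years of the run). Aggregates by any
stratification conserve the grand total exactly, and shares are
invariant to rescaling all populations.

**Disparity.** For each year and stratum, the
incarcerated-population-weighted mean of exceedance days over facility
locations minus the general-population-weighted mean over all grid
cells not containing a facility. Cell-level exclusion (the whole cell a
facility sits in leaves the background) is our reading of "the rest of
the state"; zero-population cells stay in the background with zero
weight. The "continental" stratum applies the same formula to the union
of states, not the mean of state disparities. Disparities are invariant
to adding a constant to every location's counts and to rescaling either
side's weights — both are property-tested.

**Trends.** Ordinary least squares of the annual count on calendar
year, untransformed, per facility: slope (days/yr per year), intercept
referenced to the first year, slope standard error, two-sided t-test
p-value, and total change = slope × (last − first year). "Increasing"
defaults to slope > 0 with no significance filter; a `p < α and
slope > 0` rule is available via config. Facility-vs-region trends fit
the per-year difference between the facility count and the region's
population-weighted background mean; by OLS linearity the resulting
slope equals the difference of the separate slopes, which the tests
assert numerically.

## The synthetic generator

The generator emulates the three real inputs at desk scale.

*Climate*: `Tmax(cell, day) = mean + gradient·(lat − lat̄) +
A·sin(2π(doy − 105)/365.25) + trend·(years since start)/10 + ε`, with
`ε` a stationary AR(1) process over days. Defaults describe a
warm-temperate-to-subtropical study region, where threshold exceedances
actually occur: domain-mean Tmax 24 °C, seasonal half-amplitude 12 °C
peaking mid-July, 0.8 °C per degree latitude poleward cooling,
0.3 °C/decade warming, noise sd 3 °C with lag-1 autocorrelation 0.7,
mean RH 55 % (sd 10 %). VPD is generated *from* temperature and an
explicit RH draw through the same Magnus curve the analysis inverts, so
the VPD→RH inversion is exact by construction (round-trip error is at
float precision, ~1e−15 relative). Calendars are real: leap days are
generated and counted, and annual counts are raw day counts, never
normalised to 365.

*Facilities*: distinct grid cells, optionally biased into the hottest
decile of cells by climatological mean (facilities sited on cheap, hot
land) and jittered off cell centres by up to a configurable fraction of
a cell to exercise nearest-centre assignment. Populations are lognormal
(median 150, σ = 1.1 — a heavy right tail like real facility
inventories); facility types are drawn from a fixed five-level
taxonomy.

*Background population*: lognormal per cell (median 1,000), optionally
damped by `exp(−a·z(hotness))` to mimic populous cool coasts and empty
hot interiors.

Planted truths make recovery tests exact rather than approximate:
a cell-year can be forced to exactly *k* exceedance days, and facility
cells can receive exactly δ *extra* exceedance days per year on top of
their own stochastic realisation (δ otherwise-sub-threshold days are
raised just above threshold), so the expected population-weighted
disparity equals δ with no calibration step. All randomness flows
through a fixed-algorithm generator (PCG64); a fixed seed is
bit-identical across platforms.

What the generator does **not** emulate: orographic structure and
spatial interpolation artefacts of real gridded products, spatially
correlated weather across cells (noise is independent per cell),
humidity–temperature dependence beyond the mean RH level, real US
geography, or population change over time. Passing recovery tests
therefore establishes the correctness of the *computational chain* —
not the fidelity of the transform stack to any particular real region.
Running on real grids only requires pointing the NetCDF reader at them.

## Study sizes and numerical choices

The shipped studies are sized for a single CPU: the disparity-recovery
study uses a 5 × 5 grid, 6 facility cells, 39 years and 200 seeds
(expected disparity exactly 7 days; the seed-mean recovers it to within
a few hundredths); the trend study fits 1,000 replicate 39-year series
with planted slope 0.3 days/yr and noise σ = 5, plus 1,000 null series
for type-I calibration; the end-to-end scenario is 3 states ×
60 facilities × 39 years on a 12 × 12 grid. The documented
"mini-continental" scenario doubles as the default `run_pipeline`
input.

Numerical conventions: ties in nearest-cell assignment break toward the
lower cell id (distances within 1e−9 km are treated as tied); ranking
ties break by facility id; stratum ordering is by time-mean disparity
descending with the continental row first; output CSVs are written with
`%.10g` floats so reruns are byte-identical; temperature inputs outside
[−60, 60] °C, negative VPD, RH outside [0, 100] % and infinite heat
indices raise immediately rather than propagating.

## Limitations

* The quadratic WBGT transform is an empirical fit; outside its trusted
  heat-index range the code extrapolates (with a warning) and the
  parabola eventually turns over, so extreme heat indices (> ~141 °F)
  would be misranked — far outside the range the transform is used in.
* Disparities are descriptive population-weighted differences; no
  uncertainty is attached to them.
* Trend fits are unweighted OLS on counts; counts are bounded and
  integer-valued, so for facilities near 0 or 365 days/yr the Gaussian
  error model is approximate and p-values should be read accordingly.
* Point facilities only: a facility inherits its single nearest cell's
  climate; areal facilities spanning cells are not modelled.
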