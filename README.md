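# hazardheat

Humid-heat exposure assessment for point facilities on gridded daily
climate, built for environmental-epidemiology questions of the form:
*how many potentially hazardous heat days per year do the people held at
these locations experience, how does that compare with the surrounding
population, and how fast is it changing?* The motivating application is
carceral facilities — prisons, jails and detention centres whose
residents cannot avoid heat — but any point-located, population-bearing
facility table works.

## What it computes

Starting from daily maximum 2 m air temperature `Tmax` (°C) and daily
maximum vapour pressure deficit `VPDmax` (hPa) on a regular lat/lon grid
(PRISM-style), the pipeline derives, per grid cell and day:

1. **Relative humidity**, by inverting the vapour pressure deficit
   against a Magnus saturation curve:
   `e_s(T) = 6.112·exp(17.67·T/(T+243.5))` hPa,
   `RH = 100·(1 − VPDmax/e_s(Tmax))`, clamped to [0, 100] %.
2. **Heat index** `HImax`, via the US National Weather Service
   procedure: the simple Steadman-derived formula
   `0.5·(T + 61.0 + (T−68.0)·1.2 + RH·0.094)` (°F), replaced by the full
   nine-coefficient Rothfusz regression — with the documented low-RH
   (RH < 13 %, 80–112 °F) subtraction and high-RH (RH > 85 %, 80–87 °F)
   addition — whenever the simple value reaches 80 °F. All coefficients
   live in `src/hazardheat/data/heat_index_constants.json` for audit.
3. **Indoor (shaded) wet-bulb globe temperature**
   `WBGTmax = a·HI_F² + b·HI_F + c` with defaults
   `(a, b, c) = (−0.0034, 0.96, −34)` (HI in °F, WBGT in °C), an
   occupational-heat quadratic that assumes a fixed 0.5 m s⁻¹ wind and
   no radiant load, trusted over HI ∈ [70, 115] °F.

On top of the daily WBGT series it computes:

* **Exceedance days** — days per year with `WBGTmax > 28 °C`, the NIOSH
  recommended limit for acclimatised workers at moderate workloads
  (26 °C and 30 °C available as sensitivity thresholds);
* **Person-days exposure** — facility population × mean annual
  exceedance days over an exposure window, aggregated by state and
  facility type with shares of the grand total;
* **Population-weighted disparity** — per year and stratum, the
  facility-population-weighted mean of exceedance days at facility
  locations minus the general-population-weighted mean over all grid
  cells without a facility ("the rest of the state");
* **Linear trends** — per-facility OLS of annual counts on calendar
  year (slope, standard error, two-sided p, and total change =
  slope × span), plus facility-minus-region disparity trends and counts
  of facilities (and people housed in them) with increasing trends.

A synthetic generator emulates all three real data sources — daily
climate grids with seasonal cycle, latitudinal gradient, warming trend
and AR(1) noise; facility tables with lognormal populations and
optional hot-cell placement bias; background population surfaces — and
records planted truths (per-cell warming slopes, exact exceedance-day
counts, a constant facility-vs-background offset) so every stage is
testable without downloading anything.

## Worked example

```python
from hazardheat import heat_index, relative_humidity_from_vpd, wbgt_from_heat_index

t_max, vpd_max = 34.0, 25.0        # a humid summer day: degC, hPa
rh = relative_humidity_from_vpd(t_max, vpd_max)
hi = heat_index(t_max, rh)
wbgt = wbgt_from_heat_index(hi)
print(f"RH    = {rh:.1f} %")
print(f"HImax = {hi:.1f} degC")
print(f"WBGT  = {wbgt:.1f} degC")
```

```
RH    = 53.1 %
HImax = 39.5 degC
WBGT  = 28.8 degC
```

A 34 °C day with a 25 hPa vapour pressure deficit is at 53 % relative
humidity; it feels like 39.5 °C, and the indoor WBGT of 28.8 °C is above
the 28 °C NIOSH limit — a potentially hazardous heat day.

The full pipeline on the documented synthetic scenario (three states,
60 facilities, 39 years of daily climate on a 12×12 grid):

```python
from hazardheat.config import RunConfig
from hazardheat.pipeline import run_pipeline

tables = run_pipeline(RunConfig(seed=1), "out/")
print(tables["exposure_by_stratum"].head(3).to_string(index=False))
cont = tables["disparity_summary"].iloc[0]
print(f"continental disparity: mean {cont['mean']:.1f} days/yr "
      f"(max {cont['max_value']:.1f} in {cont['max_year']})")
```

```
state facility_type  person_days  population  mean_days    share
   AC  state_prison     535141.4        5404  99.026906 0.263589
   AC   county_jail     405339.8        4133  98.073990 0.199654
   AB  state_prison     195553.4        1963  99.619664 0.096322
continental disparity: mean 15.7 days/yr (max 25.4 in 2002)
```

State prisons in the hottest synthetic state (`AC`) carry 26 % of all
person-days of exposure, and facility locations see on average 15.7
more hazardous-heat days per year than the rest of the region — the
planted hot-cell placement bias, recovered by the analysis. The same
run writes tidy CSVs (`exposure_by_stratum.csv`, `disparity_series.csv`,
`facility_trends.csv`, …) plus a `provenance.json` recording the config
hash and seed; a rerun with the same config is byte-identical.

The same stages are available from a shell:

```sh
hazardheat simulate --out sim/ --seed 3
hazardheat run-all --out results/ --climate sim/climate.nc \
    --facilities sim/facilities.csv --background sim/background.csv
```

Grid convention: WGS84 decimal degrees, latitude descending and
longitude ascending; a cell's identity is `row * n_lon + col` in that
ordering. Facilities are assigned to the nearest cell centre by
great-circle distance, ties toward the lower cell id.

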