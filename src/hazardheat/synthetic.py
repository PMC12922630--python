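"""Synthetic PRISM-like climate grids, facility tables and population surfaces.

Everything the pipeline consumes can be generated here with known planted
structure, so every stage is testable without downloading real data:

* daily Tmax fields with a seasonal cycle, a north-south gradient, a
  linear warming trend and AR(1) day-to-day noise;
* VPDmax derived *from* Tmax and an explicit relative-humidity draw via
  the same saturation-vapour-pressure curve the analysis inverts — the
  VPD -> RH inversion is therefore exactly recoverable by construction;
* facility tables with lognormal populations and optional placement bias
  toward hot cells (mimicking siting on cheap, hot land);
* background general-population surfaces, optionally anti-correlated
  with heat (populous cool coast, empty hot interior);
* planted truths: per-cell warming slopes, exact per-year exceedance-day
  counts, and a constant facility-vs-background offset of extra
  exceedance days, recorded in a :class:`SyntheticTruth` for recovery
  tests.

All randomness flows through ``numpy.random.default_rng`` (PCG64, a fixed
algorithm), so a fixed seed gives bit-identical output across platforms.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .constants import NIOSH_THRESHOLD_C
from .grid import ClimateGrid
from .wbgt import (
    WbgtTransformParams,
    heat_index,
    saturation_vapor_pressure,
    wbgt_from_heat_index,
)

__all__ = [
    "ClimateGenParams",
    "SyntheticTruth",
    "tmax_for_wbgt",
    "generate_climate",
    "make_states",
    "generate_facilities",
    "generate_background_population",
    "simulate_annual_counts",
    "mini_continental",
]

_AR_BURN_IN = 100  # days discarded so the AR(1) noise starts stationary


@dataclass
class ClimateGenParams:
    """Parameters of the synthetic daily climate generator.

    Defaults emulate a warm-temperate-to-subtropical study region on a
    PRISM-like grid: domain-mean daily Tmax of 24 degC with a 12 degC
    seasonal half-amplitude peaking in mid-July, a 0.8 degC-per-degree
    poleward cooling gradient, 0.3 degC/decade warming, AR(1) weather
    noise (sd 3 degC, lag-1 autocorrelation 0.7) and a mean relative
    humidity of 55 % (sd 10 %).
    """

    n_lat: int = 10
    n_lon: int = 10
    cell_size_deg: float = 0.25
    lat0: float = 36.0   # center of the northernmost row, degrees
    lon0: float = -100.0  # center of the westernmost column, degrees
    first_year: int = 1982
    n_years: int = 39
    mean_tmax: float = 24.0
    seasonal_amplitude: float = 12.0
    latitudinal_gradient: float = -0.8  # degC per degree latitude (cooler north)
    warming_trend: float | np.ndarray = 0.3  # degC per decade, scalar or per-cell
    noise_sd: float = 3.0
    noise_autocorrelation: float = 0.7
    base_rh: float = 55.0
    rh_noise_sd: float = 10.0
    seed: int = 0
    threshold_c: float = NIOSH_THRESHOLD_C
    wbgt_params: WbgtTransformParams = field(default_factory=WbgtTransformParams)
    #: cell_id -> {year -> k}: plant exactly k exceedance days (deterministic)
    plant_exceedance: dict | None = None
    #: (cell_ids, delta): plant delta extra exceedance days per cell-year
    facility_extra_days: tuple | None = None

    def __post_init__(self):
        if not 0 <= self.noise_autocorrelation < 1:
            raise ValueError("noise_autocorrelation must lie in [0, 1)")
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal_amplitude must be non-negative")
        if self.n_lat < 1 or self.n_lon < 1 or self.n_years < 1:
            raise ValueError("grid shape and year count must be positive")
        if self.noise_sd < 0 or self.rh_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")

    @property
    def years(self) -> range:
        return range(self.first_year, self.first_year + self.n_years)

    def lats(self) -> np.ndarray:
        return self.lat0 - np.arange(self.n_lat) * self.cell_size_deg

    def lons(self) -> np.ndarray:
        return self.lon0 + np.arange(self.n_lon) * self.cell_size_deg


@dataclass
class SyntheticTruth:
    """Planted structure recorded by the generator for recovery tests."""

    warming_slope_per_cell: np.ndarray  # degC/decade, (n_lat, n_lon)
    rh: np.ndarray                      # the RH draws, (time, lat, lon), percent
    threshold_c: float
    planted_exceedance: dict            # cell_id -> {year -> [day-of-series idx]}
    facility_extra_days: float | None   # planted facility-vs-background offset
    facility_cells: list                # cells that received the offset
    facility_assignment: dict | None = None  # facility_id -> cell_id (set later)


def tmax_for_wbgt(
    wbgt_target: float,
    rh: float,
    params: WbgtTransformParams | None = None,
) -> float:
    """Air temperature (degC) at which indoor WBGT reaches ``wbgt_target``.

    Two steps: the quadratic's closed-form root gives the target heat
    index (increasing branch), then the heat index — monotone in
    temperature at fixed RH — is inverted by bisection.
    """
    if params is None:
        params = WbgtTransformParams()
    hi_target_c = (params.hi_f_at_wbgt(wbgt_target) - 32.0) * 5.0 / 9.0

    def f(t):
        return heat_index(t, rh) - hi_target_c

    return float(optimize.brentq(f, -20.0, 59.0, xtol=1e-8))


def _ar1_noise(rng, shape, sd, rho):
    """Stationary AR(1) noise over axis 0 with marginal sd ``sd``."""
    n_t = shape[0]
    if sd == 0:
        return np.zeros(shape)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    z = rng.standard_normal((n_t + _AR_BURN_IN, *shape[1:])) * innov_sd
    x = signal.lfilter([1.0], [1.0, -rho], z, axis=0)
    return x[_AR_BURN_IN:]


def _wbgt_chain(tmax, rh, params):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return wbgt_from_heat_index(heat_index(tmax, rh), params)


def generate_climate(
    params: ClimateGenParams,
) -> tuple[ClimateGrid, SyntheticTruth]:
    """Generate a daily Tmax/VPDmax grid with planted, recorded structure.

    Tmax(cell, day) = mean + gradient * (lat - domain-mean lat)
    + amplitude * sin(2*pi*(doy - 105)/365.25) (peak mid-July)
    + trend * (years since first)/10 + AR(1) noise.

    VPDmax = e_s(Tmax) * (1 - RH/100) with RH drawn per cell-day, so
    pushing (Tmax, VPDmax) back through the analysis chain recovers the
    RH draws exactly.
    """
    rng = np.random.default_rng(params.seed)
    lats, lons = params.lats(), params.lons()
    times = pd.date_range(
        start=f"{params.first_year}-01-01",
        end=f"{params.first_year + params.n_years - 1}-12-31",
        freq="D",
    )
    n_t = len(times)
    doy = times.dayofyear.values.astype(float)
    years_since = (times.year.values - params.first_year).astype(float)

    trend = np.broadcast_to(
        np.asarray(params.warming_trend, dtype=float),
        (params.n_lat, params.n_lon),
    ).copy()

    seasonal = params.seasonal_amplitude * np.sin(
        2 * np.pi * (doy - 105.0) / 365.25
    )
    lat_term = params.latitudinal_gradient * (lats - lats.mean())
    tmax = (
        params.mean_tmax
        + seasonal[:, None, None]
        + lat_term[None, :, None]
        + np.zeros((1, 1, params.n_lon))
        + trend[None, :, :] * (years_since[:, None, None] / 10.0)
        + _ar1_noise(
            rng,
            (n_t, params.n_lat, params.n_lon),
            params.noise_sd,
            params.noise_autocorrelation,
        )
    )
    np.clip(tmax, -59.0, 59.0, out=tmax)

    rh = params.base_rh + params.rh_noise_sd * rng.standard_normal(tmax.shape)
    np.clip(rh, 1.0, 100.0, out=rh)

    planted: dict = {}
    facility_cells: list = []
    n_lon = params.n_lon

    if params.plant_exceedance:
        # deterministic override: exactly k hot days per planted cell-year
        rh_plant = 50.0
        t_hot = tmax_for_wbgt(params.threshold_c + 2.0, rh_plant, params.wbgt_params)
        t_cold = tmax_for_wbgt(params.threshold_c - 5.0, rh_plant, params.wbgt_params)
        year_arr = times.year.values
        for cell_id, per_year in params.plant_exceedance.items():
            r, c = divmod(int(cell_id), n_lon)
            planted[int(cell_id)] = {}
            for year, k in per_year.items():
                idx = np.flatnonzero(year_arr == year)
                if len(idx) == 0:
                    raise ValueError(f"planted year {year} outside generated range")
                if k > len(idx):
                    raise ValueError(
                        f"cannot plant {k} exceedance days in a {len(idx)}-day year"
                    )
                tmax[idx, r, c] = t_cold
                rh[idx, r, c] = rh_plant
                hot = idx[:k]
                tmax[hot, r, c] = t_hot
                planted[int(cell_id)][int(year)] = hot.tolist()

    if params.facility_extra_days:
        cells, delta = params.facility_extra_days
        delta = int(delta)
        facility_cells = [int(c) for c in cells]
        year_arr = times.year.values
        wparams = params.wbgt_params
        rh_plant = 50.0
        t_hot = tmax_for_wbgt(params.threshold_c + 1.0, rh_plant, wparams)
        for cell_id in facility_cells:
            r, c = divmod(cell_id, n_lon)
            wbgt_cell = _wbgt_chain(tmax[:, r, c], rh[:, r, c], wparams)
            for year in params.years:
                idx = np.flatnonzero(year_arr == year)
                below = idx[wbgt_cell[idx] <= params.threshold_c]
                if len(below) < delta:
                    raise ValueError(
                        f"cell {cell_id} year {year}: only {len(below)} "
                        f"sub-threshold days available to plant {delta} extras"
                    )
                chosen = rng.choice(below, size=delta, replace=False)
                tmax[chosen, r, c] = t_hot
                rh[chosen, r, c] = rh_plant

    vpd = saturation_vapor_pressure(tmax) * (1.0 - rh / 100.0)
    grid = ClimateGrid.from_arrays(times, lats, lons, tmax, vpd)
    truth = SyntheticTruth(
        warming_slope_per_cell=trend,
        rh=rh,
        threshold_c=params.threshold_c,
        planted_exceedance=planted,
        facility_extra_days=(
            float(params.facility_extra_days[1])
            if params.facility_extra_days
            else None
        ),
        facility_cells=facility_cells,
    )
    return grid, truth


def make_states(grid: ClimateGrid, n_states: int) -> pd.Series:
    """Partition the grid into vertical (longitude-band) synthetic states.

    Returns a cell_id -> two-letter state code Series; codes run "AA",
    "AB", ... west to east.
    """
    if n_states < 1 or n_states > grid.n_lon:
        raise ValueError("n_states must lie in [1, n_lon]")
    codes = [
        "".join(p)
        for p in itertools.islice(
            itertools.product("ABCDEFGHIJKLMNOPQRSTUVWXYZ", repeat=2), n_states
        )
    ]
    centers = grid.cell_centers()
    band = (centers["col"] * n_states) // grid.n_lon
    return pd.Series(
        [codes[b] for b in band], index=centers["cell_id"].values, name="state"
    )


def _cell_hotness(grid: ClimateGrid) -> np.ndarray:
    """Climatological mean Tmax per cell (cell_id order)."""
    return grid.values(ClimateGrid.TMAX).mean(axis=0)


def generate_facilities(
    n: int,
    grid: ClimateGrid,
    states: pd.Series,
    seed: int = 0,
    population_median: float = 150.0,
    population_sigma: float = 1.1,
    bias_hot_fraction: float = 0.0,
    jitter: float = 0.0,
    cells: list | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Synthetic HIFLD-like facility table.

    Facilities occupy distinct cells (``n`` may not exceed the cell
    count). ``bias_hot_fraction`` of them are forced into the hottest
    decile of cells by climatological mean Tmax, mimicking siting on
    cheap hot land; the rest are uniform. ``jitter`` (fraction of a cell
    size, < 0.5) offsets facilities from cell centers to exercise
    nearest-center assignment without changing the true cell.

    Returns ``(table, assignment)`` where assignment maps facility_id to
    the cell the facility truly belongs to.
    """
    rng = np.random.default_rng(seed)
    n_cells = grid.n_cells
    if cells is not None:
        chosen = np.asarray(cells, dtype=int)
        if len(chosen) != n:
            raise ValueError("len(cells) must equal n")
    else:
        if n > n_cells:
            raise ValueError(f"cannot place {n} facilities in {n_cells} cells")
        hotness = _cell_hotness(grid)
        order = np.argsort(hotness)
        n_hot = max(1, n_cells // 10)
        hot_cells = order[-n_hot:]
        n_biased = min(int(round(bias_hot_fraction * n)), len(hot_cells))
        biased = rng.choice(hot_cells, size=n_biased, replace=False)
        rest_pool = np.setdiff1d(np.arange(n_cells), biased)
        rest = rng.choice(rest_pool, size=n - n_biased, replace=False)
        chosen = np.concatenate([biased, rest])
    chosen = np.sort(chosen)

    centers = grid.cell_centers().set_index("cell_id")
    lat = centers.loc[chosen, "lat"].values.copy()
    lon = centers.loc[chosen, "lon"].values.copy()
    if jitter:
        if not 0 <= jitter < 0.5:
            raise ValueError("jitter must lie in [0, 0.5) cell sizes")
        dlat = abs(np.diff(grid.lats).mean()) if grid.n_lat > 1 else 0.0
        dlon = abs(np.diff(grid.lons).mean()) if grid.n_lon > 1 else 0.0
        lat = lat + rng.uniform(-jitter, jitter, size=n) * dlat
        lon = lon + rng.uniform(-jitter, jitter, size=n) * dlon

    populations = np.maximum(
        1,
        np.round(
            rng.lognormal(mean=np.log(population_median), sigma=population_sigma,
                          size=n)
        ).astype(int),
    )
    type_probs = {
        "state_prison": 0.30,
        "county_jail": 0.40,
        "federal": 0.05,
        "local": 0.15,
        "other": 0.10,
    }
    ftypes = rng.choice(
        list(type_probs), size=n, p=list(type_probs.values())
    )
    ids = [f"F{i:04d}" for i in range(n)]
    table = pd.DataFrame(
        {
            "facility_id": ids,
            "name": [f"Synthetic Facility {i}" for i in range(n)],
            "lat": lat,
            "lon": lon,
            "state": states.loc[chosen].values,
            "facility_type": ftypes,
            "population": populations,
            "population_year": 2018,
        }
    )
    assignment = pd.Series(chosen, index=ids, name="cell_id")
    return table, assignment


def generate_background_population(
    grid: ClimateGrid,
    states: pd.Series,
    seed: int = 0,
    facility_cells=None,
    population_median: float = 1000.0,
    population_sigma: float = 1.0,
    heat_anticorrelation: float = 0.0,
) -> pd.DataFrame:
    """Synthetic general-population surface, one row per grid cell.

    ``heat_anticorrelation`` > 0 multiplies populations by
    exp(-a * standardized hotness): populous cool areas, empty hot ones
    (the coastal-Florida pattern). Cells hosting a facility are flagged
    ``contains_facility`` so the disparity background excludes them.
    """
    rng = np.random.default_rng(seed)
    centers = grid.cell_centers()
    n = len(centers)
    pop = rng.lognormal(
        mean=np.log(population_median), sigma=population_sigma, size=n
    )
    if heat_anticorrelation:
        hotness = _cell_hotness(grid)
        z = (hotness - hotness.mean()) / (hotness.std() or 1.0)
        pop = pop * np.exp(-heat_anticorrelation * z)
    fac_cells = set(int(c) for c in (facility_cells if facility_cells is not None
                                     else []))
    return pd.DataFrame(
        {
            "cell_id": centers["cell_id"],
            "lat": centers["lat"],
            "lon": centers["lon"],
            "state": states.loc[centers["cell_id"]].values,
            "population": np.round(pop).astype(int),
            "contains_facility": [
                cid in fac_cells for cid in centers["cell_id"]
            ],
        }
    )


def simulate_annual_counts(
    n_units: int,
    years,
    slope: float,
    intercept: float,
    noise_sd: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate annual count series with a planted linear trend.

    counts = intercept + slope * (year - first year) + N(0, noise_sd^2),
    independently per unit and year. Used for trend-recovery and
    type-I-error studies at the annual-count level (no daily climate).
    """
    rng = np.random.default_rng(seed)
    years = np.asarray(list(years))
    t = years - years.min()
    mean = intercept + slope * t
    draws = mean[None, :] + noise_sd * rng.standard_normal((n_units, len(years)))
    return pd.DataFrame(
        {
            "unit_id": np.repeat([f"U{i:05d}" for i in range(n_units)], len(years)),
            "year": np.tile(years, n_units),
            "exceedance_days": draws.ravel(),
        }
    )


def mini_continental(seed: int = 0, n_years: int = 39):
    """The documented default end-to-end scenario.

    Three synthetic states across a 12 x 12 grid, 60 facilities (30 % of
    them biased into the hottest decile of cells), 39 years of daily
    climate with 0.3 degC/decade warming, and a heat-anticorrelated
    background population. Returns a dict with the generator params, the
    climate grid, the facility and background tables, the cell -> state
    map and the planted truth.
    """
    params = ClimateGenParams(
        n_lat=12,
        n_lon=12,
        first_year=1982,
        n_years=n_years,
        seed=seed,
    )
    grid, truth = generate_climate(params)
    states = make_states(grid, 3)
    facilities, assignment = generate_facilities(
        60, grid, states, seed=seed + 1, bias_hot_fraction=0.3, jitter=0.2
    )
    background = generate_background_population(
        grid,
        states,
        seed=seed + 2,
        facility_cells=assignment.values,
        heat_anticorrelation=0.5,
    )
    truth.facility_assignment = assignment.to_dict()
    return {
        "params": params,
        "grid": grid,
        "truth": truth,
        "states": states,
        "facilities": facilities,
        "background": background,
        "assignment": assignment,
    }
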