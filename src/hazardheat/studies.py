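"""Self-contained recovery studies on the synthetic generator.

Each study plants a known truth, runs the full analysis pipeline on top
of it, and reports how well the truth is recovered. They back both the
test suite and the reproducibility script.

Problem sizes are chosen so each study runs in well under five minutes on
one CPU: the disparity study uses a 5 x 5 grid with 6 facility cells over
39 years, and the trend study works at the annual-count level with 1,000
replicate facilities.
"""

from __future__ import annotations

import numpy as np

from . import disparity as disp
from . import trends as trnd
from .pipeline import (
    cell_annual_exceedance,
    compute_wbgt_matrix,
    facility_annual_from_cells,
)
from .synthetic import (
    ClimateGenParams,
    generate_background_population,
    generate_climate,
    generate_facilities,
    make_states,
    simulate_annual_counts,
)
from .wbgt import relative_humidity_from_vpd

__all__ = [
    "rh_round_trip_error",
    "disparity_recovery_study",
    "trend_recovery_study",
]


def rh_round_trip_error(seed: int = 0, n_lat: int = 10, n_lon: int = 10) -> float:
    """Max relative error recovering the generator's RH draws via VPD inversion.

    One year of daily fields on an ``n_lat x n_lon`` grid.
    """
    params = ClimateGenParams(n_lat=n_lat, n_lon=n_lon, n_years=1, seed=seed)
    grid, truth = generate_climate(params)
    recovered = relative_humidity_from_vpd(
        grid.ds.tmax.values, grid.ds.vpdmax.values
    )
    return float(np.max(np.abs(recovered - truth.rh) / truth.rh))


def _one_disparity_run(seed: int, delta: int, n_years: int) -> float:
    """Time-mean continental disparity for one seeded realisation."""
    cells = [0, 4, 7, 12, 18, 23]  # fixed facility cells on the 5x5 grid
    params = ClimateGenParams(
        n_lat=5,
        n_lon=5,
        n_years=n_years,
        latitudinal_gradient=0.0,  # exchangeable cells: truth is exactly delta
        warming_trend=0.0,
        seed=seed,
        facility_extra_days=(cells, delta),
    )
    grid, _ = generate_climate(params)
    states = make_states(grid, 1)
    facilities, assignment = generate_facilities(
        len(cells), grid, states, seed=seed + 1, cells=cells
    )
    background = generate_background_population(
        grid, states, seed=seed + 2, facility_cells=cells
    )
    wbgt = compute_wbgt_matrix(grid, params.wbgt_params)
    cell_annual = cell_annual_exceedance(wbgt, grid.times, params.threshold_c)
    fac_annual = facility_annual_from_cells(cell_annual, assignment)
    _, summary = disp.disparity_series(
        fac_annual, facilities, cell_annual, background, params.years, strata=[]
    )
    return float(
        summary.loc[summary["stratum"] == disp.CONTINENTAL, "mean"].iloc[0]
    )


def disparity_recovery_study(
    n_seeds: int = 200,
    delta: int = 7,
    n_years: int = 39,
    base_seed: int = 0,
) -> dict:
    """Planted facility-vs-background offset recovery.

    Each facility cell receives exactly ``delta`` extra exceedance days
    per year on top of its own stochastic realisation, so the expected
    population-weighted disparity equals ``delta`` exactly; the study
    averages the time-mean disparity over ``n_seeds`` independent
    realisations.
    """
    per_seed = np.array(
        [
            _one_disparity_run(base_seed + 10 * i, delta, n_years)
            for i in range(n_seeds)
        ]
    )
    return {
        "delta": float(delta),
        "mean_disparity": float(per_seed.mean()),
        "sd_across_seeds": float(per_seed.std(ddof=1)),
        "per_seed": per_seed,
    }


def trend_recovery_study(
    n_units: int = 1000,
    slope: float = 0.3,
    noise_sd: float = 5.0,
    first_year: int = 1982,
    n_years: int = 39,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Planted-slope recovery, CI coverage, and null type-I error.

    Fits OLS trends to ``n_units`` replicate annual-count series with a
    planted slope, then to an equal number of null (slope-zero) series,
    and reports the mean estimated slope, empirical 95 % CI coverage of
    the truth, and the fraction of null fits with p < alpha.
    """
    years = range(first_year, first_year + n_years)
    sim = simulate_annual_counts(
        n_units, years, slope=slope, intercept=20.0, noise_sd=noise_sd, seed=seed
    )
    table = trnd.fit_trend_table(sim)
    tcrit_half_width = table["stderr"] * _tcrit(n_years, 0.95)
    covered = (
        (table["slope"] - tcrit_half_width <= slope)
        & (slope <= table["slope"] + tcrit_half_width)
    ).mean()

    null = simulate_annual_counts(
        n_units, years, slope=0.0, intercept=20.0, noise_sd=noise_sd,
        seed=seed + 1,
    )
    null_table = trnd.fit_trend_table(null)
    type1 = (
        (null_table["p_value"] < alpha) & (null_table["slope"] != 0)
    ).mean()
    return {
        "true_slope": float(slope),
        "mean_slope": float(table["slope"].mean()),
        "coverage_95": float(covered),
        "type_i_error": float(type1),
        "n_units": int(n_units),
    }


def _tcrit(n_years: int, level: float) -> float:
    from scipy import stats

    return float(stats.t.ppf(0.5 + level / 2, df=n_years - 2))
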