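"""Grid-level computation and the end-to-end pipeline.

Stages: daily WBGT over the whole grid -> per-cell annual exceedance
counts -> facility series via nearest-cell assignment -> person-days
exposure aggregates, facility-vs-background disparity series, and
per-facility trends. :func:`run_pipeline` composes the stages and writes
tidy CSV outputs with a provenance JSON sidecar; identical config and
inputs give byte-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd

from . import disparity as disp
from . import exposure as expo
from . import trends as trnd
from .config import RunConfig
from .grid import ClimateGrid
from .synthetic import (
    generate_background_population,
    generate_climate,
    generate_facilities,
    make_states,
    ClimateGenParams,
)
from .wbgt import WbgtTransformParams, heat_index, relative_humidity_from_vpd, wbgt_from_heat_index

__all__ = [
    "compute_wbgt_matrix",
    "cell_annual_exceedance",
    "facility_annual_from_cells",
    "background_weighted_series",
    "run_pipeline",
]

_FLOAT_FORMAT = "%.10g"


def compute_wbgt_matrix(
    grid: ClimateGrid, params: WbgtTransformParams | None = None
) -> np.ndarray:
    """Daily indoor WBGT (degC) as a (time, cell) matrix in cell_id order."""
    tmax = grid.values(ClimateGrid.TMAX)
    vpd = grid.values(ClimateGrid.VPDMAX)
    rh = relative_humidity_from_vpd(tmax, vpd)
    hi = heat_index(tmax, rh)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return wbgt_from_heat_index(hi, params)


def cell_annual_exceedance(
    wbgt_matrix: np.ndarray,
    times: pd.DatetimeIndex,
    threshold: float,
    strict: bool = True,
) -> pd.DataFrame:
    """Tidy (unit_id, year, exceedance_days, complete) table for every cell.

    Vectorised equivalent of counting each cell's series separately; a
    cell-year is complete when every calendar day is present with finite
    WBGT.
    """
    with np.errstate(invalid="ignore"):
        above = (
            wbgt_matrix > threshold if strict else wbgt_matrix >= threshold
        )
    years = times.year.values
    df = pd.DataFrame(above.astype(int))
    counts = df.groupby(years).sum()
    present = pd.Series(1, index=times).groupby(years).count()
    expected = pd.Series(
        {y: 366 if pd.Timestamp(year=y, month=12, day=31).dayofyear == 366 else 365
         for y in counts.index}
    )
    # completeness: all days of the year present and all values finite
    finite = pd.DataFrame(np.isfinite(wbgt_matrix)).groupby(years).all()
    year_complete = present == expected
    complete = finite & year_complete.values[:, None]

    out = counts.stack().rename("exceedance_days").reset_index()
    out.columns = ["year", "unit_id", "exceedance_days"]
    comp = complete.stack().rename("complete").reset_index()
    comp.columns = ["year", "unit_id", "complete"]
    out = out.merge(comp, on=["year", "unit_id"])
    out = out[["unit_id", "year", "exceedance_days", "complete"]]
    return out.sort_values(["unit_id", "year"], kind="mergesort").reset_index(
        drop=True
    )


def facility_annual_from_cells(
    cell_annual: pd.DataFrame, assignment: pd.Series
) -> pd.DataFrame:
    """Per-facility annual table by mapping each facility onto its cell."""
    rows = []
    for fac_id, cell_id in assignment.items():
        sub = cell_annual[cell_annual["unit_id"] == cell_id]
        if sub.empty:
            raise ValueError(f"facility {fac_id!r}: cell {cell_id} has no series")
        block = sub.copy()
        block["unit_id"] = fac_id
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


def background_weighted_series(
    cell_annual: pd.DataFrame, background: pd.DataFrame
) -> pd.DataFrame:
    """Per-state, per-year general-population-weighted mean exceedance days.

    Cells flagged ``contains_facility`` are excluded ("the rest of the
    state"). Returns a tidy (state, year, weighted_mean_days) table.
    """
    bg = background[~background["contains_facility"]]
    merged = cell_annual.merge(
        bg[["cell_id", "state", "population"]].rename(
            columns={"cell_id": "unit_id"}
        ),
        on="unit_id",
        how="inner",
    )
    rows = []
    for (state, year), sub in merged.groupby(["state", "year"], sort=True):
        rows.append(
            (
                state,
                int(year),
                disp.population_weighted_mean(
                    sub["exceedance_days"], sub["population"]
                ),
            )
        )
    return pd.DataFrame(rows, columns=["state", "year", "weighted_mean_days"])


def _simulate_inputs(config: RunConfig):
    """Build the synthetic scenario a config describes (no external files)."""
    first, last = config.trend_window
    params = ClimateGenParams(
        n_lat=config.n_lat,
        n_lon=config.n_lon,
        first_year=first,
        n_years=last - first + 1,
        seed=config.seed,
        threshold_c=config.threshold_c,
        wbgt_params=config.wbgt_params(),
    )
    grid, truth = generate_climate(params)
    states = make_states(grid, config.n_states)
    facilities, assignment = generate_facilities(
        config.n_facilities, grid, states, seed=config.seed + 1,
        bias_hot_fraction=0.3, jitter=0.2,
    )
    background = generate_background_population(
        grid, states, seed=config.seed + 2,
        facility_cells=assignment.values, heat_anticorrelation=0.5,
    )
    truth.facility_assignment = assignment.to_dict()
    return grid, facilities, background, states, truth


def run_pipeline(
    config: RunConfig,
    outdir,
    grid: ClimateGrid | None = None,
    facilities: pd.DataFrame | None = None,
    background: pd.DataFrame | None = None,
) -> dict:
    """Run simulate -> wbgt -> exposure -> disparity -> trends, write CSVs.

    With no inputs supplied, the synthetic scenario described by the
    config is generated in-memory. Returns a dict of the in-memory result
    tables; files are written under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if grid is None:
        grid, facilities, background, _states, _truth = _simulate_inputs(config)
    if facilities is None or background is None:
        raise ValueError("facility and background tables are required")

    wparams = config.wbgt_params()
    wbgt = compute_wbgt_matrix(grid, wparams)
    cell_annual = cell_annual_exceedance(
        wbgt, grid.times, config.threshold_c, strict=config.strict_exceedance
    )
    assignment = disp.assign_units_to_cells(facilities, grid)
    fac_annual = facility_annual_from_cells(cell_annual, assignment)

    exp_years = range(config.exposure_window[0], config.exposure_window[1] + 1)
    trend_years = range(config.trend_window[0], config.trend_window[1] + 1)

    exposure_table, excluded = expo.aggregate_exposure(
        facilities, fac_annual, exp_years, group_by=list(config.group_by)
    )
    top, n_headline = expo.top_exposed_facilities(
        facilities, fac_annual, exp_years, min_days=config.min_days_headline
    )

    series, summary = disp.disparity_series(
        fac_annual, facilities, cell_annual, background, trend_years
    )

    fac_trends = trnd.fit_trend_table(fac_annual, window=trend_years)
    n_incr, people_incr = trnd.count_increasing(
        fac_trends, facilities, rule=config.increasing_rule, alpha=config.alpha
    )
    bg_series = background_weighted_series(cell_annual, background)
    dis_trend_rows = []
    fac_state = facilities.set_index("facility_id")["state"]
    for fac_id, sub in fac_annual.groupby("unit_id", sort=True):
        state = fac_state[fac_id]
        reg = bg_series[bg_series["state"] == state][["year", "weighted_mean_days"]]
        sub = sub[sub["year"].isin(list(trend_years))]
        reg = reg[reg["year"].isin(list(trend_years))]
        r = trnd.facility_vs_region_trend(sub, reg, unit_id=fac_id)
        dis_trend_rows.append(
            {
                "unit_id": fac_id,
                "slope": r.slope,
                "stderr": r.stderr,
                "p_value": r.p_value,
                "total_change": r.total_change,
                "increasing": r.increasing,
            }
        )
    dis_trends = pd.DataFrame(dis_trend_rows)
    state_summary = trnd.state_summary_changes(fac_trends, dis_trends, facilities)

    tables = {
        "facility_annual": fac_annual,
        "exposure_by_stratum": exposure_table,
        "exposure_excluded": excluded,
        "top_facilities": top,
        "disparity_series": series,
        "disparity_summary": summary,
        "facility_trends": fac_trends,
        "disparity_trends": dis_trends,
        "state_summary": state_summary,
    }
    for name, table in tables.items():
        table.to_csv(outdir / f"{name}.csv", index=False,
                     float_format=_FLOAT_FORMAT)

    try:
        version = metadata.version("hazardheat")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    provenance = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "package_version": version,
        "seed": config.seed,
        "headline": {
            "n_facilities": int(len(facilities)),
            "n_facilities_min_days": int(n_headline),
            "n_facilities_increasing": int(n_incr),
            "people_in_increasing": float(people_incr),
            "total_person_days": float(exposure_table["person_days"].sum()),
        },
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    tables["provenance"] = provenance
    return tables
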