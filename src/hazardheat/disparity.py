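"""Population-weighted facility-vs-background exposure disparities.

For every year and stratum (a state, or the whole "continental" run), the
disparity is the incarcerated-population-weighted mean of annual
exceedance-day counts over facility locations minus the general-population-
weighted mean over all grid cells that do not contain a facility. A
positive value means people held at facility locations saw more hazardous
heat days than the surrounding population did.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import ClimateGrid, assign_points_to_cells

__all__ = [
    "CONTINENTAL",
    "population_weighted_mean",
    "annual_disparity",
    "disparity_series",
    "assign_units_to_cells",
]

#: Name of the all-states stratum.
CONTINENTAL = "continental"

#: Columns a background-cell table must carry.
BACKGROUND_COLUMNS = ("cell_id", "lat", "lon", "state", "population",
                      "contains_facility")


def population_weighted_mean(values, weights) -> float:
    """Sum(w*v)/Sum(w) with non-negative weights, at least one positive."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("all weights are zero; weighted mean undefined")
    return float((w * v).sum() / total)


def assign_units_to_cells(facilities: pd.DataFrame, grid: ClimateGrid) -> pd.Series:
    """facility_id -> cell_id map by nearest great-circle cell center.

    Ties break toward the lower cell_id; facilities outside the grid
    bounding box raise, naming the facility.
    """
    try:
        cells = assign_points_to_cells(
            facilities["lat"].values, facilities["lon"].values, grid
        )
    except ValueError as exc:
        # re-raise with the facility id instead of the row index
        msg = str(exc)
        if msg.startswith("point "):
            i = int(msg.split()[1])
            fac = facilities.iloc[i]
            raise ValueError(
                f"facility {fac['facility_id']!r} at "
                f"(lat={fac['lat']:.4f}, lon={fac['lon']:.4f}) "
                "falls outside the climate grid"
            ) from exc
        raise
    return pd.Series(cells, index=facilities["facility_id"].values, name="cell_id")


def _side_table(annual: pd.DataFrame, units: pd.DataFrame,
                id_col: str, pop_col: str = "population") -> pd.DataFrame:
    """Join annual counts to unit populations -> (unit, year, days, weight)."""
    merged = annual.merge(
        units[[id_col, "state", pop_col]].rename(
            columns={id_col: "unit_id", pop_col: "weight"}
        ),
        on="unit_id",
        how="inner",
    )
    return merged


def annual_disparity(
    facility_annual: pd.DataFrame,
    facilities: pd.DataFrame,
    background_annual: pd.DataFrame,
    background: pd.DataFrame,
    year: int,
    stratum: str = CONTINENTAL,
) -> float:
    """Population-weighted facility-minus-background disparity for one year.

    ``facility_annual`` / ``background_annual`` are tidy (unit_id, year,
    exceedance_days) tables; ``facilities`` carries incarcerated
    populations, ``background`` general populations with a
    ``contains_facility`` flag (flagged cells are excluded from the
    background side).
    """
    fac = _side_table(facility_annual, facilities, "facility_id")
    bg = _side_table(
        background_annual,
        background[~background["contains_facility"]],
        "cell_id",
    )
    if stratum != CONTINENTAL:
        fac = fac[fac["state"] == stratum]
        bg = bg[bg["state"] == stratum]
    fac = fac[fac["year"] == year]
    bg = bg[bg["year"] == year]
    if fac.empty or bg.empty:
        raise ValueError(
            f"stratum {stratum!r} has no "
            f"{'facility' if fac.empty else 'background'} units in year {year}"
        )
    return population_weighted_mean(
        fac["exceedance_days"], fac["weight"]
    ) - population_weighted_mean(bg["exceedance_days"], bg["weight"])


def disparity_series(
    facility_annual: pd.DataFrame,
    facilities: pd.DataFrame,
    background_annual: pd.DataFrame,
    background: pd.DataFrame,
    years,
    strata: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annual disparity series per stratum plus the continental series.

    Returns ``(series, summary)``:

    * ``series`` — tidy (stratum, year, disparity_days), strata ordered by
      time-mean disparity descending (continental listed first);
    * ``summary`` — per stratum: mean, and the (year, value) of the series
      max and min.
    """
    years = list(years)
    if not years:
        raise ValueError("empty year range")
    if strata is None:
        strata = sorted(set(facilities["state"]))
    rows = []
    for stratum in [CONTINENTAL, *strata]:
        for year in years:
            rows.append(
                (
                    stratum,
                    int(year),
                    annual_disparity(
                        facility_annual, facilities,
                        background_annual, background,
                        year, stratum,
                    ),
                )
            )
    series = pd.DataFrame(rows, columns=["stratum", "year", "disparity_days"])

    summary_rows = []
    for stratum, sub in series.groupby("stratum"):
        imax = sub["disparity_days"].idxmax()
        imin = sub["disparity_days"].idxmin()
        summary_rows.append(
            {
                "stratum": stratum,
                "mean": sub["disparity_days"].mean(),
                "max_year": int(sub.loc[imax, "year"]),
                "max_value": sub.loc[imax, "disparity_days"],
                "min_year": int(sub.loc[imin, "year"]),
                "min_value": sub.loc[imin, "disparity_days"],
            }
        )
    summary = pd.DataFrame(summary_rows)
    # continental first, then states by time-mean disparity descending
    summary["_cont"] = (summary["stratum"] != CONTINENTAL).astype(int)
    summary = summary.sort_values(
        ["_cont", "mean", "stratum"], ascending=[True, False, True],
        kind="mergesort",
    ).drop(columns="_cont").reset_index(drop=True)
    order = {s: i for i, s in enumerate(summary["stratum"])}
    series = series.sort_values(
        ["stratum", "year"],
        key=lambda col: col.map(order) if col.name == "stratum" else col,
        kind="mergesort",
    ).reset_index(drop=True)
    return series, summary
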