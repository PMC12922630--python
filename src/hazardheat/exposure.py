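"""Threshold-exceedance day counts and person-days exposure aggregates.

A "potentially hazardous heat" day is a calendar day whose daily maximum
indoor WBGT exceeds a fixed threshold (default 28 degC, the NIOSH
recommended limit for acclimatised workers at moderate workloads).
Annual counts per facility feed person-days exposure: the facility's
population (a single snapshot year) times its mean annual exceedance-day
count over an exposure window.

Tables are tidy pandas DataFrames throughout:

* annual exceedance: one row per (unit_id, year) with ``exceedance_days``
  and a ``complete`` flag (False if any day of that year was missing);
* exposure aggregates: one row per stratum with person_days, population,
  mean_days and share of the grand total.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .constants import NIOSH_THRESHOLD_C

logger = logging.getLogger(__name__)

__all__ = [
    "FACILITY_TYPES",
    "normalize_facility_type",
    "count_exceedance_days",
    "annual_exceedance_series",
    "mean_annual_exceedance",
    "person_days_exposure",
    "aggregate_exposure",
    "top_exposed_facilities",
]

#: Five-level facility taxonomy.
FACILITY_TYPES = ("state_prison", "county_jail", "federal", "local", "other")

#: Columns a facility table must carry.
FACILITY_COLUMNS = (
    "facility_id", "name", "lat", "lon", "state",
    "facility_type", "population", "population_year",
)


def normalize_facility_type(raw: str, mapping: dict[str, str] | None = None) -> str:
    """Map a raw source type string onto the five-level taxonomy.

    Unknown strings map to ``"other"`` with a logged warning.
    """
    if raw in FACILITY_TYPES:
        return raw
    if mapping and raw in mapping:
        mapped = mapping[raw]
        if mapped not in FACILITY_TYPES:
            raise ValueError(
                f"facility-type mapping sends {raw!r} to unknown type {mapped!r}"
            )
        return mapped
    logger.warning("unknown facility type %r mapped to 'other'", raw)
    return "other"


def _days_in_year(year: int) -> int:
    return 366 if pd.Timestamp(year=year, month=12, day=31).dayofyear == 366 else 365


def count_exceedance_days(
    wbgt_series: pd.DataFrame,
    year: int,
    threshold: float = NIOSH_THRESHOLD_C,
    strict: bool = True,
) -> tuple[int, bool]:
    """Count days in ``year`` with WBGTmax above ``threshold``.

    Parameters
    ----------
    wbgt_series
        DataFrame with ``date`` and ``wbgt_max`` columns (the output of
        :func:`hazardheat.wbgt.daily_wbgt_series`).
    year
        Calendar year to count; must be present in the series.
    threshold
        Exceedance threshold in degC.
    strict
        "Exceeds" means strictly greater than the threshold (default);
        ``False`` uses >= for sensitivity analysis.

    Returns
    -------
    (count, complete) — complete is False if any calendar day of the year
    is absent from the series or has missing (NaN) WBGT.
    """
    dates = pd.DatetimeIndex(wbgt_series["date"])
    in_year = dates.year == year
    if not in_year.any():
        raise ValueError(f"year {year} absent from WBGT series")
    vals = np.asarray(wbgt_series["wbgt_max"], dtype=float)[in_year]
    n_expected = _days_in_year(year)
    complete = (
        len(np.unique(dates[in_year].normalize())) == n_expected
        and not np.isnan(vals).any()
    )
    with np.errstate(invalid="ignore"):
        above = vals > threshold if strict else vals >= threshold
    return int(above.sum()), bool(complete)


def annual_exceedance_series(
    unit_id,
    wbgt_series: pd.DataFrame,
    threshold: float = NIOSH_THRESHOLD_C,
    strict: bool = True,
) -> pd.DataFrame:
    """Per-year exceedance counts for one unit, as a tidy table."""
    years = sorted(pd.DatetimeIndex(wbgt_series["date"]).year.unique())
    rows = []
    for year in years:
        count, complete = count_exceedance_days(
            wbgt_series, year, threshold=threshold, strict=strict
        )
        rows.append((unit_id, int(year), count, complete))
    return pd.DataFrame(
        rows, columns=["unit_id", "year", "exceedance_days", "complete"]
    )


def _window_years(window) -> list[int]:
    years = list(window)
    if not years:
        raise ValueError("empty year window")
    return years


def mean_annual_exceedance(
    annual: pd.DataFrame, window, require_complete: bool = True
) -> float:
    """Arithmetic mean of annual exceedance counts over a year window.

    ``annual`` holds one unit's rows (columns ``year``, ``exceedance_days``,
    optionally ``complete``). Missing years raise; incomplete years raise
    unless ``require_complete=False``.
    """
    years = _window_years(window)
    sub = annual[annual["year"].isin(years)]
    missing = sorted(set(years) - set(sub["year"]))
    if missing:
        raise ValueError(f"window years missing from series: {missing}")
    if require_complete and "complete" in sub and not sub["complete"].all():
        bad = sorted(sub.loc[~sub["complete"], "year"])
        raise ValueError(f"incomplete daily coverage in years {bad}")
    return float(sub["exceedance_days"].mean())


def person_days_exposure(population: float, mean_days: float) -> float:
    """Annual person-days: people housed times mean hazardous days per year."""
    if population < 1:
        raise ValueError("facility population must be >= 1")
    if mean_days < 0:
        raise ValueError("mean_days must be non-negative")
    return float(population) * float(mean_days)


def _check_facilities(facilities: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FACILITY_COLUMNS if c not in facilities.columns]
    if missing:
        raise ValueError(f"facility table missing columns: {missing}")
    if (facilities["population"] < 1).any():
        bad = facilities.loc[facilities["population"] < 1, "facility_id"].tolist()
        raise ValueError(f"facilities with population < 1: {bad[:5]}")
    return facilities


def _facility_means(
    facilities: pd.DataFrame, annual: pd.DataFrame, window
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-facility mean days over the window; incomplete facilities split off."""
    years = _window_years(window)
    rows, excluded = [], []
    grouped = dict(tuple(annual.groupby("unit_id")))
    for fac in facilities.itertuples(index=False):
        sub = grouped.get(fac.facility_id)
        if sub is None:
            raise ValueError(
                f"facility {fac.facility_id!r} has no annual exceedance series"
            )
        try:
            mean_days = mean_annual_exceedance(sub, years)
        except ValueError as exc:
            excluded.append((fac.facility_id, str(exc)))
            continue
        rows.append(
            {
                "facility_id": fac.facility_id,
                "state": fac.state,
                "facility_type": fac.facility_type,
                "population": fac.population,
                "mean_days": mean_days,
                "person_days": person_days_exposure(fac.population, mean_days),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "facility_id", "state", "facility_type",
            "population", "mean_days", "person_days",
        ],
    )
    excluded_df = pd.DataFrame(excluded, columns=["facility_id", "reason"])
    return table, excluded_df


def aggregate_exposure(
    facilities: pd.DataFrame,
    annual: pd.DataFrame,
    window,
    group_by: list[str] | tuple[str, ...] = ("state", "facility_type"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Person-days exposure summed by stratum.

    Returns ``(table, excluded)``: one row per stratum with ``person_days``
    (sum of population x mean_days over member facilities), ``population``,
    ``mean_days`` (person-days per person, i.e. population-weighted mean
    days) and ``share`` of the grand total; plus a completeness sidecar of
    facilities excluded for incomplete coverage.
    """
    _check_facilities(facilities)
    per_fac, excluded = _facility_means(facilities, annual, window)
    group_by = list(group_by)
    if per_fac.empty:
        return (
            pd.DataFrame(
                columns=group_by + ["person_days", "population", "mean_days", "share"]
            ),
            excluded,
        )
    g = per_fac.groupby(group_by, as_index=False).agg(
        person_days=("person_days", "sum"), population=("population", "sum")
    )
    g["mean_days"] = g["person_days"] / g["population"]
    total = g["person_days"].sum()
    g["share"] = g["person_days"] / total if total > 0 else 0.0
    g = g.sort_values("person_days", ascending=False, kind="mergesort").reset_index(
        drop=True
    )
    return g, excluded


def top_exposed_facilities(
    facilities: pd.DataFrame,
    annual: pd.DataFrame,
    window,
    k: int | None = None,
    min_days: float = 75.0,
) -> tuple[pd.DataFrame, int]:
    """Facilities ranked by mean annual exceedance days, descending.

    Ties break by facility_id lexicographic order (deterministic). Also
    returns the number of facilities whose mean is at least ``min_days``.
    """
    _check_facilities(facilities)
    per_fac, _ = _facility_means(facilities, annual, window)
    ranked = per_fac.sort_values(
        ["mean_days", "facility_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    n_at_least = int((ranked["mean_days"] >= min_days).sum())
    if k is not None:
        ranked = ranked.head(k)
    return ranked, n_at_least
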