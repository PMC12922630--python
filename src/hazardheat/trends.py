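"""Per-facility linear trends in annual hazardous-heat day counts.

Ordinary least squares of the annual exceedance-day count on calendar
year, per facility; the fitted slope (days/yr per year) times the span in
years gives the "total change" — how many more hazardous days the final
year saw than the first, as estimated by the trend line. Counts are
regressed untransformed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrendResult",
    "fit_annual_trend",
    "trend_ci",
    "fit_trend_table",
    "count_increasing",
    "facility_vs_region_trend",
    "state_summary_changes",
]


@dataclass(frozen=True)
class TrendResult:
    """OLS trend of an annual count series.

    slope is days/yr per year; intercept is the fitted value at the first
    year of the series; total_change = slope * (last_year - first_year);
    ``increasing`` means slope > 0 (no significance filter by default).
    """

    unit_id: object
    slope: float
    intercept: float
    stderr: float
    p_value: float
    total_change: float
    increasing: bool
    first_year: int
    last_year: int


def fit_annual_trend(years, counts, unit_id=None) -> TrendResult:
    """OLS of annual counts on calendar year.

    Requires at least three distinct years. The two-sided p-value comes
    from the t distribution with n-2 degrees of freedom.
    """
    y = np.asarray(counts, dtype=float)
    x = np.asarray(years, dtype=float)
    if len(x) != len(y):
        raise ValueError("years and counts must have equal length")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct years to fit a trend")
    res = stats.linregress(x, y)
    first, last = int(x.min()), int(x.max())
    slope = float(res.slope)
    return TrendResult(
        unit_id=unit_id,
        slope=slope,
        intercept=float(res.intercept + res.slope * first),
        stderr=float(res.stderr),
        p_value=float(res.pvalue),
        total_change=slope * (last - first),
        increasing=slope > 0,
        first_year=first,
        last_year=last,
    )


def trend_ci(result: TrendResult, n_years: int, level: float = 0.95):
    """Confidence interval for the slope at the given level."""
    tcrit = stats.t.ppf(0.5 + level / 2, df=n_years - 2)
    return (result.slope - tcrit * result.stderr,
            result.slope + tcrit * result.stderr)


def fit_trend_table(annual: pd.DataFrame, window=None) -> pd.DataFrame:
    """Fit one trend per unit from a tidy (unit_id, year, exceedance_days) table."""
    rows = []
    for unit_id, sub in annual.groupby("unit_id", sort=True):
        if window is not None:
            sub = sub[sub["year"].isin(list(window))]
        r = fit_annual_trend(sub["year"], sub["exceedance_days"], unit_id=unit_id)
        rows.append(
            {
                "unit_id": unit_id,
                "slope": r.slope,
                "intercept": r.intercept,
                "stderr": r.stderr,
                "p_value": r.p_value,
                "total_change": r.total_change,
                "increasing": r.increasing,
            }
        )
    return pd.DataFrame(rows)


def count_increasing(
    trends: pd.DataFrame,
    facilities: pd.DataFrame,
    rule: str = "slope",
    alpha: float = 0.05,
) -> tuple[int, float]:
    """Facilities with an increasing trend, and the people they house.

    rule="slope": slope > 0 (default — no significance filter);
    rule="significant": slope > 0 and p < alpha.
    """
    merged = trends.merge(
        facilities[["facility_id", "population"]],
        left_on="unit_id",
        right_on="facility_id",
        how="left",
    )
    unmatched = merged["population"].isna()
    if unmatched.any():
        bad = merged.loc[unmatched, "unit_id"].tolist()
        raise ValueError(f"trend unit_ids with no facility record: {bad[:5]}")
    if rule == "slope":
        sel = merged["slope"] > 0
    elif rule == "significant":
        sel = (merged["slope"] > 0) & (merged["p_value"] < alpha)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return int(sel.sum()), float(merged.loc[sel, "population"].sum())


def facility_vs_region_trend(
    facility_annual: pd.DataFrame,
    region_weighted_annual: pd.DataFrame,
    unit_id=None,
) -> TrendResult:
    """Trend of the per-year (facility count - region weighted mean) difference.

    ``facility_annual``: (year, exceedance_days) for one facility;
    ``region_weighted_annual``: (year, weighted_mean_days) for its region.
    Both must cover the same years. By OLS linearity the fitted slope
    equals the facility slope minus the region slope.
    """
    fac = facility_annual.set_index("year")["exceedance_days"]
    reg = region_weighted_annual.set_index("year")["weighted_mean_days"]
    if set(fac.index) != set(reg.index):
        raise ValueError("facility and region series cover different years")
    diff = (fac - reg).sort_index()
    return fit_annual_trend(diff.index, diff.values, unit_id=unit_id)


def state_summary_changes(
    trends: pd.DataFrame,
    disparity_trends: pd.DataFrame,
    facilities: pd.DataFrame,
) -> pd.DataFrame:
    """Per-state mean total change, absolute and relative to the state.

    One row per state: mean facility total_change, mean disparity
    total_change, and the facility with the largest |total_change|.
    """
    fac_states = facilities[["facility_id", "state"]]
    t = trends.merge(fac_states, left_on="unit_id", right_on="facility_id")
    d = disparity_trends.merge(fac_states, left_on="unit_id", right_on="facility_id")
    rows = []
    for state, sub in t.groupby("state", sort=True):
        dsub = d[d["state"] == state]
        imax = sub["total_change"].abs().idxmax()
        rows.append(
            {
                "state": state,
                "mean_total_change": sub["total_change"].mean(),
                "mean_disparity_total_change": (
                    dsub["total_change"].mean() if len(dsub) else np.nan
                ),
                "max_change_facility": sub.loc[imax, "unit_id"],
                "max_change_value": sub.loc[imax, "total_change"],
            }
        )
    return pd.DataFrame(rows)
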