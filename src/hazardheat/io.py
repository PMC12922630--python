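"""Readers and writers for the pipeline's file formats.

Climate grids travel as NetCDF (classic format via the scipy engine);
facility and background-population tables as CSV with strict schema
validation and row-numbered error messages (row numbers count data rows,
header excluded).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .disparity import BACKGROUND_COLUMNS
from .exposure import FACILITY_COLUMNS, FACILITY_TYPES, normalize_facility_type
from .grid import ClimateGrid

logger = logging.getLogger(__name__)

__all__ = [
    "read_climate",
    "write_climate",
    "read_facilities",
    "write_facilities",
    "read_background",
    "write_background",
]


def read_climate(path, tmax_var: str = "tmax", vpdmax_var: str = "vpdmax") -> ClimateGrid:
    """Load a (time, lat, lon) NetCDF climate grid; report calendar gaps."""
    grid = ClimateGrid.from_netcdf(path, tmax_var=tmax_var, vpdmax_var=vpdmax_var)
    times = grid.times
    if len(times) > 1:
        full = pd.date_range(times[0], times[-1], freq="D")
        missing = full.difference(times)
        if len(missing):
            logger.warning(
                "%s: %d calendar days missing between %s and %s",
                path, len(missing), times[0].date(), times[-1].date(),
            )
    return grid


def write_climate(grid: ClimateGrid, path) -> None:
    grid.to_netcdf(path)


def _row_error(path, i: int, message: str) -> ValueError:
    return ValueError(f"{path}, data row {i + 1}: {message}")


def read_facilities(
    path, type_mapping: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read and validate a facility CSV.

    Required columns: facility_id, name, lat, lon, state, facility_type,
    population, population_year. Populations must be >= 1 (the analysis
    covers operational, populated facilities only); facility types are
    normalised onto the five-level taxonomy.
    """
    df = pd.read_csv(path)
    missing = [c for c in FACILITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df["facility_id"].duplicated().any():
        dupes = df.loc[df["facility_id"].duplicated(), "facility_id"].tolist()
        raise ValueError(f"{path}: duplicate facility_id values {dupes[:5]}")
    for i, row in df.iterrows():
        if pd.isna(row["lat"]) or not -90 <= row["lat"] <= 90:
            raise _row_error(path, i, f"latitude {row['lat']!r} out of range")
        if pd.isna(row["lon"]) or not -180 <= row["lon"] <= 180:
            raise _row_error(path, i, f"longitude {row['lon']!r} out of range")
        if pd.isna(row["population"]) or row["population"] < 1:
            raise _row_error(
                path, i,
                f"population {row['population']!r} invalid: facilities must be "
                "operational and populated (population >= 1)",
            )
    df["facility_type"] = [
        normalize_facility_type(t, type_mapping) for t in df["facility_type"]
    ]
    df["population"] = df["population"].astype(int)
    return df


def write_facilities(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_background(path) -> pd.DataFrame:
    """Read and validate a background-population cell CSV."""
    df = pd.read_csv(path)
    missing = [c for c in BACKGROUND_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for i, row in df.iterrows():
        if pd.isna(row["population"]) or row["population"] < 0:
            raise _row_error(path, i, f"population {row['population']!r} negative")
    df["contains_facility"] = df["contains_facility"].astype(bool)
    return df


def write_background(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_truth(truth, path) -> None:
    """Serialise a SyntheticTruth (minus the bulky RH field) to JSON."""
    payload = {
        "warming_slope_per_cell": np.asarray(
            truth.warming_slope_per_cell
        ).tolist(),
        "threshold_c": truth.threshold_c,
        "planted_exceedance": {
            str(cell): {str(y): idx for y, idx in per_year.items()}
            for cell, per_year in truth.planted_exceedance.items()
        },
        "facility_extra_days": truth.facility_extra_days,
        "facility_cells": list(truth.facility_cells),
        "facility_assignment": (
            {k: int(v) for k, v in truth.facility_assignment.items()}
            if truth.facility_assignment
            else None
        ),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
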