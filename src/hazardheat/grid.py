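"""Regular lat/lon daily climate grids and point-to-cell assignment.

A :class:`ClimateGrid` wraps an :class:`xarray.Dataset` with dimensions
``(time, lat, lon)`` and variables for daily maximum temperature (degC) and
daily maximum vapour pressure deficit (hPa). Grids are WGS84 decimal
degrees, indexed latitude-descending / longitude-ascending; a cell's
identity is ``row * n_lon + col`` in that ordering, so cell ids are stable
across round-trips through NetCDF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

__all__ = ["ClimateGrid", "haversine_km", "assign_points_to_cells"]

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points in decimal degrees."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


@dataclass
class ClimateGrid:
    """Daily Tmax/VPDmax fields on a regular lat/lon grid."""

    ds: xr.Dataset

    TMAX = "tmax"
    VPDMAX = "vpdmax"

    def __post_init__(self):
        ds = self.ds
        for dim in ("time", "lat", "lon"):
            if dim not in ds.dims:
                raise ValueError(f"climate dataset is missing dimension {dim!r}")
        for var in (self.TMAX, self.VPDMAX):
            if var not in ds.data_vars:
                raise ValueError(f"climate dataset is missing variable {var!r}")
            if ds[var].dims != ("time", "lat", "lon"):
                raise ValueError(
                    f"{var!r} must have dims (time, lat, lon), got {ds[var].dims}"
                )
        lat = ds["lat"].values
        lon = ds["lon"].values
        if len(lat) > 1 and not np.all(np.diff(lat) < 0):
            raise ValueError("lat must be strictly descending")
        if len(lon) > 1 and not np.all(np.diff(lon) > 0):
            raise ValueError("lon must be strictly ascending")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_arrays(cls, times, lats, lons, tmax, vpdmax) -> "ClimateGrid":
        """Build from plain arrays; ``tmax``/``vpdmax`` shaped (time, lat, lon)."""
        times = pd.DatetimeIndex(times)
        ds = xr.Dataset(
            {
                cls.TMAX: (("time", "lat", "lon"), np.asarray(tmax, dtype=float)),
                cls.VPDMAX: (("time", "lat", "lon"), np.asarray(vpdmax, dtype=float)),
            },
            coords={
                "time": times,
                "lat": np.asarray(lats, dtype=float),
                "lon": np.asarray(lons, dtype=float),
            },
        )
        ds[cls.TMAX].attrs["units"] = "degC"
        ds[cls.VPDMAX].attrs["units"] = "hPa"
        return cls(ds)

    @classmethod
    def from_netcdf(
        cls, path, tmax_var: str = "tmax", vpdmax_var: str = "vpdmax"
    ) -> "ClimateGrid":
        try:
            ds = xr.load_dataset(path, engine="scipy")
        except Exception as exc:  # noqa: BLE001 - re-raise with filename
            raise ValueError(f"cannot read climate NetCDF {path}: {exc}") from exc
        rename = {}
        if tmax_var != cls.TMAX:
            rename[tmax_var] = cls.TMAX
        if vpdmax_var != cls.VPDMAX:
            rename[vpdmax_var] = cls.VPDMAX
        if rename:
            ds = ds.rename(rename)
        return cls(ds)

    def to_netcdf(self, path) -> None:
        # NETCDF3 classic via the scipy engine: portable, text-tool friendly
        ds = self.ds.copy()
        ds["time"].encoding.update(units="days since 1970-01-01", calendar="standard")
        ds.to_netcdf(path, engine="scipy")

    # -- geometry ---------------------------------------------------------

    @property
    def lats(self) -> np.ndarray:
        return self.ds["lat"].values

    @property
    def lons(self) -> np.ndarray:
        return self.ds["lon"].values

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.ds["time"].values)

    @property
    def n_lat(self) -> int:
        return self.ds.sizes["lat"]

    @property
    def n_lon(self) -> int:
        return self.ds.sizes["lon"]

    @property
    def n_cells(self) -> int:
        return self.n_lat * self.n_lon

    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells)

    def cell_rowcol(self, cell_id) -> tuple[np.ndarray, np.ndarray]:
        cell_id = np.asarray(cell_id)
        return cell_id // self.n_lon, cell_id % self.n_lon

    def cell_centers(self) -> pd.DataFrame:
        """One row per cell: cell_id, row, col, lat, lon."""
        rows, cols = np.divmod(self.cell_ids(), self.n_lon)
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids(),
                "row": rows,
                "col": cols,
                "lat": self.lats[rows],
                "lon": self.lons[cols],
            }
        )

    def bounds(self) -> tuple[float, float, float, float]:
        """(lat_min, lat_max, lon_min, lon_max) of the cell-edge bounding box."""
        dlat = abs(np.diff(self.lats).mean()) if self.n_lat > 1 else 0.0
        dlon = abs(np.diff(self.lons).mean()) if self.n_lon > 1 else 0.0
        return (
            self.lats.min() - dlat / 2,
            self.lats.max() + dlat / 2,
            self.lons.min() - dlon / 2,
            self.lons.max() + dlon / 2,
        )

    # -- extraction -------------------------------------------------------

    def cell_series(self, cell_id: int) -> pd.DataFrame:
        """Daily (date, t_max, vpd_max) series at one cell."""
        row, col = self.cell_rowcol(int(cell_id))
        return pd.DataFrame(
            {
                "date": self.times,
                "t_max": self.ds[self.TMAX].values[:, row, col],
                "vpd_max": self.ds[self.VPDMAX].values[:, row, col],
            }
        )

    def values(self, var: str) -> np.ndarray:
        """(time, cell) matrix of one variable, cells in cell_id order."""
        arr = self.ds[var].values
        return arr.reshape(arr.shape[0], -1)


def assign_points_to_cells(lat, lon, grid: ClimateGrid) -> np.ndarray:
    """Nearest-cell-center assignment by great-circle distance.

    Ties break deterministically toward the lower cell_id. Points outside
    the grid's cell-edge bounding box raise, naming the offending point.
    """
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat_min, lat_max, lon_min, lon_max = grid.bounds()
    outside = (lat < lat_min) | (lat > lat_max) | (lon < lon_min) | (lon > lon_max)
    if outside.any():
        i = int(np.argmax(outside))
        raise ValueError(
            f"point {i} at (lat={lat[i]:.4f}, lon={lon[i]:.4f}) falls outside "
            f"the grid bounding box lat[{lat_min:.4f},{lat_max:.4f}] "
            f"lon[{lon_min:.4f},{lon_max:.4f}]"
        )
    centers = grid.cell_centers()
    # (n_points, n_cells) distance matrix; fine at the scale of one grid
    d = haversine_km(
        lat[:, None], lon[:, None],
        centers["lat"].values[None, :], centers["lon"].values[None, :],
    )
    # argmin returns the first (lowest cell_id) minimum, but guard against
    # float noise: snap distances within 1e-9 km of the minimum to it
    dmin = d.min(axis=1, keepdims=True)
    return np.argmax(d <= dmin + 1e-9, axis=1)
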