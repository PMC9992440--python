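"""Year-day surface-current climatology: gridding drifter fixes and sampling velocities.

The climatology is the substrate the Lagrangian tracker advects particles
through: a 365-slot mean annual cycle of the surface velocity field on a
regular lon/lat grid, in the spirit of climatologies gridded from the Global
Drifter Program archive.  Fixes are binned into grid cells within a circular
temporal window of year-days; empty cells are filled by nearest-neighbour
spatial fill up to a capped radius, else left at zero with ``n_obs == 0``.

Conventions: longitudes in [-180, 180); year-day is 0-based internally
(0 .. 364) and real-valued queries wrap circularly between day 364 and day 0;
leap days are stripped when converting calendar dates (Feb 29 maps to the
year-day of Mar 1).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

from .geo import normalize_lon

N_YEARDAYS = 365

__all__ = [
    "DrifterFixSet",
    "VelocityGrid",
    "WindGrid",
    "build_climatology",
    "sample_velocity",
    "read_fixes_csv",
    "write_fixes_csv",
    "yearday_from_date",
]


def yearday_from_date(date) -> int:
    """0-based year-day in a 365-day year; Feb 29 maps to the year-day of Mar 1 (59)."""
    ts = pd.Timestamp(date)
    yd = int(ts.dayofyear) - 1
    if ts.is_leap_year and yd >= 60:  # shift days after Feb 29 (0-based day 59)
        yd -= 1
    return yd


@dataclass
class DrifterFixSet:
    """Drifter fix records: one row per 6-hourly position/velocity fix.

    Columns: year, day (1-based year-day), hour (0/6/12/18), lon, lat,
    u, v (m/s eastward/northward), drogue (bool).
    """

    records: pd.DataFrame

    REQUIRED = ("year", "day", "hour", "lon", "lat", "u", "v", "drogue")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"drifter fix table missing columns: {missing}")
        rec = self.records.copy()
        rec["lon"] = normalize_lon(rec["lon"].to_numpy())
        if (np.abs(rec["lat"].to_numpy()) > 90).any():
            raise ValueError("latitudes must lie in [-90, 90]")
        bad_hours = set(np.unique(rec["hour"])) - {0, 6, 12, 18}
        if bad_hours:
            raise ValueError(f"fix hours must be in {{0,6,12,18}}, got {sorted(bad_hours)}")
        self.records = rec

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class VelocityGrid:
    """Gridded year-day velocity climatology with a land mask.

    Arrays are indexed ``[yearday, lat, lon]`` (year-day 0-based); land cells
    hold zero velocity by construction.
    """

    lon: np.ndarray
    lat: np.ndarray
    u: np.ndarray
    v: np.ndarray
    land_mask: np.ndarray
    n_obs: np.ndarray | None = None

    _U_NAME = "u"
    _V_NAME = "v"

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if np.any(np.diff(self.lon) <= 0) or np.any(np.diff(self.lat) <= 0):
            raise ValueError("grid axes must be strictly increasing")
        if self.u.shape != (N_YEARDAYS, self.lat.size, self.lon.size):
            raise ValueError(f"u has shape {self.u.shape}, expected (365, nlat, nlon)")
        self.land_mask = np.asarray(self.land_mask, dtype=bool)

    @property
    def dlon(self) -> float:
        return float(self.lon[1] - self.lon[0])

    @property
    def dlat(self) -> float:
        return float(self.lat[1] - self.lat[0])

    def contains(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon[0]) & (lon <= self.lon[-1]) & (lat >= self.lat[0]) & (lat <= self.lat[-1])
        )

    def is_land(self, lon, lat):
        """Land flag of the cell nearest to each query point."""
        i = np.clip(np.rint((np.asarray(lat, float) - self.lat[0]) / self.dlat).astype(int), 0, self.lat.size - 1)
        j = np.clip(np.rint((np.asarray(lon, float) - self.lon[0]) / self.dlon).astype(int), 0, self.lon.size - 1)
        return self.land_mask[i, j]

    def nearest_ocean(self, lon: float, lat: float, max_cells: int = 2) -> tuple[float, float]:
        """Snap a (possibly coastal) point to the nearest ocean cell center.

        Raises ``ValueError`` if no ocean cell lies within ``max_cells`` cells.
        """
        if not bool(self.contains(lon, lat)):
            raise ValueError(f"point ({lon}, {lat}) outside grid domain")
        if not bool(self.is_land(lon, lat)):
            return float(lon), float(lat)
        ii, jj = np.nonzero(~self.land_mask)
        di = (self.lat[ii] - lat) / self.dlat
        dj = (self.lon[jj] - lon) / self.dlon
        d2 = di**2 + dj**2
        k = int(np.argmin(d2))
        if d2[k] > max_cells**2:
            raise ValueError(f"no ocean cell within {max_cells} cells of ({lon}, {lat})")
        return float(self.lon[jj[k]]), float(self.lat[ii[k]])

    # --- interpolation -------------------------------------------------

    def sample(self, lon, lat, yearday, *, temporal: str = "linear"):
        """Bilinear (lon/lat) × linear-circular (year-day) velocity interpolation.

        ``yearday`` is real-valued in [0, 365), wrapping between day 364 and
        day 0.  Land cells hold zero velocity so the field tapers to zero at
        the coast; a query surrounded entirely by land returns (0, 0).
        Raises ``ValueError`` for points outside the grid bounds.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        scalar = lon.ndim == 0
        lon, lat = np.atleast_1d(lon), np.atleast_1d(lat)
        if not self.contains(lon, lat).all():
            raise ValueError("sample point outside grid domain")

        fx = (lon - self.lon[0]) / self.dlon
        fy = (lat - self.lat[0]) / self.dlat
        j0 = np.clip(np.floor(fx).astype(int), 0, self.lon.size - 2)
        i0 = np.clip(np.floor(fy).astype(int), 0, self.lat.size - 2)
        wx = fx - j0
        wy = fy - i0

        yd = np.asarray(yearday, dtype=float) % N_YEARDAYS
        t0 = np.floor(yd).astype(int) % N_YEARDAYS
        if temporal == "nearest":
            t0 = np.rint(yd).astype(int) % N_YEARDAYS
            wt = np.zeros_like(yd)
        else:
            wt = yd - np.floor(yd)
        t1 = (t0 + 1) % N_YEARDAYS
        t0 = np.broadcast_to(t0, lon.shape)
        t1 = np.broadcast_to(t1, lon.shape)
        wt = np.broadcast_to(wt, lon.shape)

        out = []
        for f in (self.u, self.v):
            def plane(t):
                return (
                    f[t, i0, j0] * (1 - wx) * (1 - wy)
                    + f[t, i0, j0 + 1] * wx * (1 - wy)
                    + f[t, i0 + 1, j0] * (1 - wx) * wy
                    + f[t, i0 + 1, j0 + 1] * wx * wy
                )

            val = plane(t0) * (1 - wt) + plane(t1) * wt
            out.append(val[0] if scalar else val)
        return out[0], out[1]

    # --- serialization -------------------------------------------------

    def to_dataset(self) -> xr.Dataset:
        coords = {"yearday": np.arange(N_YEARDAYS), "lat": self.lat, "lon": self.lon}
        data = {
            self._U_NAME: (("yearday", "lat", "lon"), self.u),
            self._V_NAME: (("yearday", "lat", "lon"), self.v),
            "land_mask": (("lat", "lon"), self.land_mask.astype(np.int8)),
        }
        if self.n_obs is not None:
            data["n_obs"] = (("yearday", "lat", "lon"), self.n_obs.astype(np.int32))
        ds = xr.Dataset(data, coords=coords)
        ds[self._U_NAME].attrs["units"] = "m s-1"
        ds[self._V_NAME].attrs["units"] = "m s-1"
        ds["lon"].attrs["units"] = "degrees_east"
        ds["lat"].attrs["units"] = "degrees_north"
        return ds

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "VelocityGrid":
        kwargs = dict(
            lon=ds["lon"].values,
            lat=ds["lat"].values,
            u=ds[cls._U_NAME].values.astype(float),
            v=ds[cls._V_NAME].values.astype(float),
            land_mask=ds["land_mask"].values.astype(bool),
        )
        if "n_obs" in ds:
            kwargs["n_obs"] = ds["n_obs"].values
        return cls(**kwargs)

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "VelocityGrid":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


@dataclass
class WindGrid(VelocityGrid):
    """10-m wind on the same axes as :class:`VelocityGrid`.

    ``u``/``v`` hold the u10/v10 components; serialized under those names.
    """

    _U_NAME = "u10"
    _V_NAME = "v10"


def build_climatology(
    fixes: DrifterFixSet,
    resolution: float,
    temporal_window: int = 15,
    drogue_only: bool = False,
    *,
    bounds: tuple[float, float, float, float] | None = None,
    fill_radius: int = 3,
    land_mask: np.ndarray | None = None,
) -> VelocityGrid:
    """Bin drifter fixes into a year-day velocity climatology.

    Each cell/year-day holds the mean of all fix velocities falling in that
    spatial cell within ± ``temporal_window``/2 year-days (circular).  Cells
    left empty are filled from the nearest observed cell within
    ``fill_radius`` cells (per year-day), otherwise zero with ``n_obs == 0``.

    Parameters
    ----------
    bounds : (lon_min, lon_max, lat_min, lat_max), optional
        Grid extent; inferred from the fix extent when omitted.
    drogue_only : bool
        Use only drogue-on fixes.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    rec = fixes.records
    if drogue_only:
        rec = rec[rec["drogue"].astype(bool)]
    if len(rec) == 0:
        raise ValueError("no drifter fixes to grid (empty set or all filtered)")

    lon_f = rec["lon"].to_numpy(float)
    lat_f = rec["lat"].to_numpy(float)
    if bounds is None:
        bounds = (lon_f.min(), lon_f.max(), lat_f.min(), lat_f.max())
    lon_min, lon_max, lat_min, lat_max = bounds
    nlon = max(int(np.round((lon_max - lon_min) / resolution)) + 1, 2)
    nlat = max(int(np.round((lat_max - lat_min) / resolution)) + 1, 2)
    lon_ax = lon_min + resolution * np.arange(nlon)
    lat_ax = lat_min + resolution * np.arange(nlat)

    j = np.rint((lon_f - lon_min) / resolution).astype(int)
    i = np.rint((lat_f - lat_min) / resolution).astype(int)
    inside = (j >= 0) & (j < nlon) & (i >= 0) & (i < nlat)
    if not inside.any():
        raise ValueError("all fixes fall outside the grid domain")
    rec = rec[inside]
    i, j = i[inside], j[inside]
    yd = rec["day"].to_numpy(int) - 1  # 1-based in records, 0-based on the grid
    u_f = rec["u"].to_numpy(float)
    v_f = rec["v"].to_numpy(float)

    half = temporal_window // 2
    usum = np.zeros((N_YEARDAYS, nlat, nlon))
    vsum = np.zeros_like(usum)
    cnt = np.zeros_like(usum)
    flat = np.ravel_multi_index((i, j), (nlat, nlon))
    for off in range(-half, half + 1):
        t = (yd + off) % N_YEARDAYS
        idx = t * (nlat * nlon) + flat
        np.add.at(usum.ravel(), idx, u_f)
        np.add.at(vsum.ravel(), idx, v_f)
        np.add.at(cnt.ravel(), idx, 1.0)

    observed = cnt > 0
    u = np.where(observed, usum / np.where(observed, cnt, 1.0), 0.0)
    v = np.where(observed, vsum / np.where(observed, cnt, 1.0), 0.0)

    # nearest-neighbour spatial fill per year-day, capped at fill_radius cells
    if fill_radius > 0:
        for t in range(N_YEARDAYS):
            obs_t = observed[t]
            if not obs_t.any() or obs_t.all():
                continue
            dist, (inear, jnear) = ndimage.distance_transform_edt(~obs_t, return_indices=True)
            fill = (~obs_t) & (dist <= fill_radius)
            u[t][fill] = u[t][inear[fill], jnear[fill]]
            v[t][fill] = v[t][inear[fill], jnear[fill]]

    if land_mask is None:
        land_mask = np.zeros((nlat, nlon), dtype=bool)
    u[:, land_mask] = 0.0
    v[:, land_mask] = 0.0
    return VelocityGrid(lon=lon_ax, lat=lat_ax, u=u, v=v, land_mask=land_mask, n_obs=cnt.astype(int))


def sample_velocity(grid: VelocityGrid, lon, lat, yearday, *, temporal: str = "linear"):
    """Interpolate the gridded velocity at a point; see :meth:`VelocityGrid.sample`."""
    return grid.sample(lon, lat, yearday, temporal=temporal)


_GDP_COLUMN_ORDER = ["year", "day", "hour", "lon", "lat", "u", "v", "drogue"]


def read_fixes_csv(path) -> DrifterFixSet:
    """Read a drifter fix CSV; tolerates headerless files in the compiled GDP column order."""
    df = pd.read_csv(path)
    if not set(DrifterFixSet.REQUIRED) <= set(df.columns):
        df = pd.read_csv(path, header=None, names=_GDP_COLUMN_ORDER)
    df["drogue"] = df["drogue"].astype(bool)
    return DrifterFixSet(df)


def write_fixes_csv(fixes: DrifterFixSet, path) -> None:
    fixes.records[_GDP_COLUMN_ORDER].to_csv(path, index=False)
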