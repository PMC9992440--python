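"""Environmental conditions at backtrack origins and midpoints, and their comparison.

For each simulation the pipeline looks up sea-surface temperature and
chlorophyll-a in a box of ~93,500 km² centred on (1) the backtracked origin
at the historical date one year before collection, and (2) the mean ensemble
position mid-way along the backtrack (183 days), at the date six months
before collection.  Differences between sub-origins and time periods are
tested with a two-factor PERMANOVA (sequential sums of squares, free row
permutations) on the bivariate (SST, sqrt(chl)) response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .permanova import PermanovaResult, permanova_factorial

logger = logging.getLogger(__name__)

__all__ = ["EnvGrid", "box_average", "extract_env_records", "env_permanova"]

KM_PER_DEG_LAT = 111.32


@dataclass
class EnvGrid:
    """Gridded 8-day composite SST (degC) and chlorophyll-a (mg/m3) fields.

    ``time_yearday`` holds the (0-based, possibly fractional) mid-composite
    year-days of each 8-day period; land/missing cells are NaN.
    """

    lon: np.ndarray
    lat: np.ndarray
    time_yearday: np.ndarray
    sst: np.ndarray
    chl: np.ndarray

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.time_yearday = np.asarray(self.time_yearday, dtype=float)
        if np.any(np.diff(self.time_yearday) <= 0):
            raise ValueError("composite time axis must be sorted")
        if np.nanmin(self.chl) < 0:
            raise ValueError("chlorophyll must be non-negative")
        if self.sst.shape != (self.time_yearday.size, self.lat.size, self.lon.size):
            raise ValueError("sst shape must be (time, lat, lon)")

    def nearest_composite(self, yearday: float) -> int:
        """Index of the composite whose mid-point is circularly closest to ``yearday``."""
        d = np.abs(self.time_yearday - (float(yearday) % 365.0))
        return int(np.argmin(np.minimum(d, 365.0 - d)))

    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(
            {
                "sst": (("time", "lat", "lon"), self.sst),
                "chl": (("time", "lat", "lon"), self.chl),
            },
            coords={"time": self.time_yearday, "lat": self.lat, "lon": self.lon},
        )
        ds["sst"].attrs["units"] = "degC"
        ds["chl"].attrs["units"] = "mg m-3"
        return ds

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "EnvGrid":
        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        return cls(
            lon=ds["lon"].values,
            lat=ds["lat"].values,
            time_yearday=ds["time"].values,
            sst=ds["sst"].values,
            chl=ds["chl"].values,
        )


def box_average(grid: EnvGrid, center: tuple[float, float], area_km2: float, yearday: float):
    """Mean SST and chl over a square box of ``area_km2`` centred on ``center``.

    The square's side in km is converted to degrees at the centre latitude
    (plate carrée); the composite nearest to ``yearday`` is used; the mean
    runs over non-missing ocean cells.  Raises ``ValueError`` when the box
    contains no valid cells.
    """
    if area_km2 <= 0:
        raise ValueError("box area must be positive")
    lon_c, lat_c = center
    side_km = float(np.sqrt(area_km2))
    half_lat = side_km / KM_PER_DEG_LAT / 2.0
    half_lon = side_km / (KM_PER_DEG_LAT * np.cos(np.radians(lat_c))) / 2.0

    sel_lon = (grid.lon >= lon_c - half_lon) & (grid.lon <= lon_c + half_lon)
    sel_lat = (grid.lat >= lat_c - half_lat) & (grid.lat <= lat_c + half_lat)
    if not sel_lon.any() or not sel_lat.any():
        raise ValueError("box lies outside the environmental grid")
    t = grid.nearest_composite(yearday)
    sst_box = grid.sst[t][np.ix_(sel_lat, sel_lon)]
    chl_box = grid.chl[t][np.ix_(sel_lat, sel_lon)]
    if np.isnan(sst_box).all():
        raise ValueError("box contains no valid (non-missing) cells")
    return float(np.nanmean(sst_box)), float(np.nanmean(chl_box))


def extract_env_records(results, labels, grid: EnvGrid, area_km2: float = 93_500.0) -> pd.DataFrame:
    """Two environmental records per simulation: at the origin and at the midpoint.

    ``results`` is a list of BacktrackResult; ``labels`` maps each
    simulation id to its sub-origin label ('A'/'B').  The origin record is
    evaluated 365 backtracked days before collection (same year-day in the
    365-day climatological year) at the ensemble centre of mass; the midpoint
    record 183 days before collection at the mean ensemble position on that
    day.  A box with no valid cells yields NaNs (logged), not a failure.
    """
    label_of = labels.labels if hasattr(labels, "labels") else dict(labels)
    rows = []
    for res in results:
        sim = res.simulation_id
        launch_yd = res.launch_yearday
        for period, days_back in (("origin", 365), ("midpoint", 183)):
            if days_back >= res.config.horizon_days:
                pos = res.center_of_mass
            else:
                pos = res.mean_position_at_day(days_back)
            yd = (launch_yd - days_back) % 365
            try:
                sst, chl = box_average(grid, pos, area_km2, yd)
            except ValueError:
                logger.warning("no environmental data for %s/%s at %s", sim, period, pos)
                sst, chl = np.nan, np.nan
            rows.append(
                {
                    "simulation": sim,
                    "period": period,
                    "suborigin": label_of[sim],
                    "lon": pos[0],
                    "lat": pos[1],
                    "sst_mean": sst,
                    "chl_mean": chl,
                }
            )
    return pd.DataFrame(rows)


def env_permanova(
    records: pd.DataFrame,
    n_perm: int = 9999,
    seed: int = 0,
    *,
    sqrt_chl: bool = True,
    standardize: bool = True,
) -> PermanovaResult:
    """Two-factor PERMANOVA of (SST, sqrt(chl)) on period, sub-origin and interaction.

    Chlorophyll is square-root transformed (tempers extreme values); both
    response columns are z-scored by default since degC and mg/m3 are not
    commensurable under Euclidean distance.  Sums of squares are sequential
    (period, then sub-origin, then interaction); significance by free row
    permutation with the +1 rule.
    """
    rec = records.dropna(subset=["sst_mean", "chl_mean"])
    periods = sorted(rec["period"].unique())
    groups = sorted(rec["suborigin"].unique())
    if len(periods) < 2 or len(groups) < 2:
        raise ValueError("need both time periods and both sub-origins represented")
    counts = rec.groupby(["period", "suborigin"]).size()
    if len(counts) < len(periods) * len(groups):
        raise ValueError("empty cell in the period x sub-origin design")

    chl = rec["chl_mean"].to_numpy(float)
    response = np.column_stack([rec["sst_mean"].to_numpy(float), np.sqrt(chl) if sqrt_chl else chl])
    if standardize:
        sd = response.std(axis=0, ddof=0)
        response = (response - response.mean(axis=0)) / np.where(sd == 0, 1.0, sd)

    factors = {
        "period": rec["period"].to_numpy(),
        "suborigin": rec["suborigin"].to_numpy(),
    }
    return permanova_factorial(response, factors, interaction=True, n_perm=n_perm, seed=seed)
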