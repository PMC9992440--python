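"""Synthetic inputs for the drift-origins pipeline.

Everything the pipeline consumes can be generated here: a kinematic surface
current/wind climatology with a planted seasonal two-pathway structure,
6-hourly drifter fixes advected through it, three-part morphotype
compositions whose mean differs by regime, and smooth SST / chlorophyll
fields with a latitudinal temperature gradient.

The planted circulation mimics, at desk scale, the two transport routes that
feed Sargassum to a Barbados-like target: pathway A, a long meandering
coastal jet from an equatorial eastern source running along a synthetic
NE-South-America coastline before turning north to the target; and pathway B,
a shorter direct zonal jet at the target's latitude from a north-eastern
source.  Both route branches are present year-round — a particle backtracked
for a year necessarily crosses seasons, so the routes themselves must persist
— while a gate within a few degrees of the target selects which branch feeds
the target on a given year-day.  Regime A year-days open the coastal
approach; regime B year-days open the zonal approach.  The gate blends
smoothly over ~10 year-days at regime boundaries.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .currents import N_YEARDAYS, DrifterFixSet, VelocityGrid, WindGrid, yearday_from_date
from .envstats import EnvGrid

logger = logging.getLogger(__name__)

__all__ = [
    "RegimeCalendar",
    "FieldConfig",
    "CompositionParams",
    "MorphotypeSample",
    "generate_current_field",
    "generate_drifter_fixes",
    "generate_morphotype_samples",
    "generate_env_fields",
    "samples_to_dataframe",
]

MORPHOTYPES = ("SNI", "SNVIII", "SFIII")


# ---------------------------------------------------------------------------
# configuration types


@dataclass(frozen=True)
class RegimeCalendar:
    """Partition of the 365 year-days into transport regimes A and B.

    ``intervals`` is a list of ``(yearday_start, yearday_end, regime)`` with
    inclusive 0-based endpoints; the intervals must tile all 365 year-days
    without overlap.  The default encodes the seasonal split seen in Barbados
    strandings: regime A from March to early August (year-days 60–218),
    regime B for the rest of the year.
    """

    intervals: tuple = ((60, 218, "A"), (219, 364, "B"), (0, 59, "B"))
    blend_days: int = 10

    def __post_init__(self) -> None:
        covered = np.zeros(N_YEARDAYS, dtype=int)
        regimes = set()
        for start, end, regime in self.intervals:
            if regime not in ("A", "B"):
                raise ValueError(f"unknown regime {regime!r}")
            if not (0 <= start <= 364 and 0 <= end <= 364):
                raise ValueError("interval endpoints must be year-days 0-364")
            regimes.add(regime)
            if start <= end:
                covered[start : end + 1] += 1
            else:  # wraps over new year
                covered[start:] += 1
                covered[: end + 1] += 1
        if not (covered == 1).all():
            raise ValueError("intervals must cover all 365 year-days exactly once")
        if regimes != {"A", "B"}:
            raise ValueError("calendar needs at least one interval per regime")

    def regime_of(self, yearday: int) -> str:
        yd = int(yearday) % N_YEARDAYS
        for start, end, regime in self.intervals:
            if (start <= end and start <= yd <= end) or (start > end and (yd >= start or yd <= end)):
                return regime
        raise ValueError(f"year-day {yearday} not covered")  # pragma: no cover

    def regime_of_date(self, date) -> str:
        return self.regime_of(yearday_from_date(date))

    def weight_a(self) -> np.ndarray:
        """Per-year-day weight of regime A, smoothed circularly over ``blend_days``."""
        ind = np.array([1.0 if self.regime_of(d) == "A" else 0.0 for d in range(N_YEARDAYS)])
        if self.blend_days <= 1:
            return ind
        n = int(self.blend_days)
        kernel = np.hanning(n + 2)[1:-1]
        kernel /= kernel.sum()
        pad = np.concatenate([ind[-n:], ind, ind[:n]])
        return np.convolve(pad, kernel, mode="same")[n : n + N_YEARDAYS]


@dataclass(frozen=True)
class FieldConfig:
    """Geometry and amplitudes of the synthetic two-pathway current field.

    The default domain (62–30° W, 5° S–22° N at 1/4°) is a desk-scale analog
    of the western Tropical Atlantic; jet speeds are free parameters chosen so
    that 365-day backtracks stay inside the domain.  Speeds in m/s, lengths
    in degrees.
    """

    lon_min: float = -62.0
    lon_max: float = -30.0
    lat_min: float = -5.0
    lat_max: float = 22.0
    resolution: float = 0.25
    target_lon: float = -59.56345
    target_lat: float = 13.26802
    jet_speed_a: float = 0.12
    jet_speed_b: float = 0.075
    approach_speed: float = 0.30
    jet_width: float = 1.2
    meander_amplitude: float = 0.6
    meander_wavelength: float = 8.0
    background_drift: float = 0.03
    gate_radius: float = 3.0
    wind_u10: float = -4.0
    wind_v10: float = 0.0
    windage_design: float = 0.005
    noise_level: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError("domain bounds must be ordered")
        if min(self.jet_speed_a, self.jet_speed_b, self.approach_speed) <= 0:
            raise ValueError("jet speeds must be positive")
        if not (
            self.lon_min < self.target_lon < self.lon_max and self.lat_min < self.target_lat < self.lat_max
        ):
            raise ValueError("target location must lie inside the domain")
        for lon, lat in self.pathway_a_waypoints() + self.pathway_b_waypoints():
            if not (
                self.lon_min + 0.5 <= lon <= self.lon_max + 0.01
                and self.lat_min + 0.5 <= lat <= self.lat_max - 0.5
            ):
                raise ValueError("domain too small to contain both transport pathways")

    # waypoint geometry is anchored to the target so alternative domains work
    def pathway_a_waypoints(self):
        t = self.target_lon
        return [
            (t + 23.56, 1.0),
            (t + 19.56, 1.2),
            (t + 13.56, 1.8),
            (t + 9.56, 4.0),
            (t + 4.56, 9.0),
            (t, self.target_lat),
        ]

    def pathway_b_waypoints(self):
        return [(self.lon_max - 0.6, self.target_lat), (self.target_lon, self.target_lat)]

    def lon_axis(self) -> np.ndarray:
        n = int(round((self.lon_max - self.lon_min) / self.resolution)) + 1
        return self.lon_min + self.resolution * np.arange(n)

    def lat_axis(self) -> np.ndarray:
        n = int(round((self.lat_max - self.lat_min) / self.resolution)) + 1
        return self.lat_min + self.resolution * np.arange(n)

    def coast_lat(self, lon) -> np.ndarray:
        """Latitude of the synthetic NE-South-America coastline at ``lon``."""
        return 8.0 - (13.0 / 27.0) * (np.asarray(lon, dtype=float) + 62.0)

    def land_mask(self) -> np.ndarray:
        lon2d, lat2d = np.meshgrid(self.lon_axis(), self.lat_axis())
        return lat2d < self.coast_lat(lon2d)


@dataclass(frozen=True)
class CompositionParams:
    """Per-regime Dirichlet parameters of the three-part morphotype composition.

    Mean vectors are over (S. natans I, S. natans VIII, S. fluitans III).
    Defaults plant the study's contrast: pathway A strandings dominated by
    S. fluitans III, pathway B strandings with elevated S. natans VIII.
    """

    mean_a: tuple = (0.10, 0.15, 0.75)
    mean_b: tuple = (0.08, 0.55, 0.37)
    concentration: float = 30.0
    clumps_per_date: int = 3
    mean_total_volume_ml: float = 250.0
    volume_log_sd: float = 0.3

    def __post_init__(self) -> None:
        for mean in (self.mean_a, self.mean_b):
            m = np.asarray(mean, dtype=float)
            if m.shape != (3,) or (m <= 0).any() or abs(m.sum() - 1.0) > 1e-9:
                raise ValueError("each mean vector must be strictly positive and sum to 1")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.clumps_per_date < 1:
            raise ValueError("need at least one clump per date")

    def mean_for(self, regime: str) -> np.ndarray:
        if regime == "A":
            return np.asarray(self.mean_a, dtype=float)
        if regime == "B":
            return np.asarray(self.mean_b, dtype=float)
        raise ValueError(f"unknown regime {regime!r}")


@dataclass(frozen=True)
class MorphotypeSample:
    """One beach clump: collection date plus displacement volumes (mL) per morphotype."""

    date: _date
    clump_id: int
    vol_sni_ml: float
    vol_snviii_ml: float
    vol_sfiii_ml: float

    def volumes(self) -> np.ndarray:
        return np.array([self.vol_sni_ml, self.vol_snviii_ml, self.vol_sfiii_ml], dtype=float)


def samples_to_dataframe(samples) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "date": [s.date for s in samples],
            "clump_id": [s.clump_id for s in samples],
            "vol_sni_ml": [s.vol_sni_ml for s in samples],
            "vol_snviii_ml": [s.vol_snviii_ml for s in samples],
            "vol_sfiii_ml": [s.vol_sfiii_ml for s in samples],
        }
    )


# ---------------------------------------------------------------------------
# current / wind field


def _densify(waypoints, step: float = 0.05) -> np.ndarray:
    """Resample a polyline to roughly uniform spacing (degrees)."""
    pts = np.asarray(waypoints, dtype=float)
    out = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        seg = np.hypot(*(b - a))
        n = max(int(np.ceil(seg / step)), 1)
        for k in range(1, n + 1):
            out.append(a + (b - a) * k / n)
    return np.asarray(out)


def _branch_velocity(config: FieldConfig, path: np.ndarray, speed: float, lon2d, lat2d):
    """Gaussian cross-section jet along ``path``; returns (u, v, gatedness).

    Distances are measured in a local equirectangular degree metric
    (dlon scaled by cos of latitude).  The flow points from the first path
    point toward the last (toward the target).  Speed ramps up to
    ``approach_speed`` within ``gate_radius`` of the target.
    """
    coslat = np.cos(np.radians(np.clip(lat2d, -60, 60)))
    scale = np.cos(np.radians(config.target_lat * 0.5))  # common metric scale for the KD-tree
    tree = cKDTree(np.column_stack([path[:, 0] * scale, path[:, 1]]))
    pts = np.column_stack([lon2d.ravel() * scale, lat2d.ravel()])
    dist, idx = tree.query(pts)

    nxt = np.clip(idx + 1, 0, len(path) - 1)
    prv = np.clip(idx - 1, 0, len(path) - 1)
    tx = (path[nxt, 0] - path[prv, 0]) * scale
    ty = path[nxt, 1] - path[prv, 1]
    norm = np.hypot(tx, ty)
    norm[norm == 0] = 1.0
    tx, ty = tx / norm, ty / norm

    amp = speed * np.exp(-((dist / config.jet_width) ** 2))
    # faster converging flow on the final approach to the target
    r_t = np.hypot((lon2d.ravel() - config.target_lon) * scale, lat2d.ravel() - config.target_lat)
    gz = np.exp(-((r_t / config.gate_radius) ** 2))
    amp = amp * (1.0 + (config.approach_speed / speed - 1.0) * gz)

    u = (amp * tx).reshape(lon2d.shape)
    v = (amp * ty).reshape(lon2d.shape)
    support = np.exp(-((dist / (2.0 * config.jet_width)) ** 2)).reshape(lon2d.shape)
    return u, v, gz.reshape(lon2d.shape), support


def generate_current_field(
    config: FieldConfig, calendar: RegimeCalendar | None = None
) -> tuple[VelocityGrid, WindGrid]:
    """Build the year-day velocity climatology with the planted two-pathway structure.

    Both route branches are permanent; within ``gate_radius`` of the target the
    pathway-A branch is weighted by the calendar's (smoothed) regime-A weight
    and the pathway-B branch by its complement, so the target is fed by the
    coastal route on regime-A year-days and by the zonal route on regime-B
    year-days.  Returns the current grid and a uniform trade-wind grid on the
    same axes.
    """
    calendar = calendar or RegimeCalendar()
    lon_ax, lat_ax = config.lon_axis(), config.lat_axis()
    lon2d, lat2d = np.meshgrid(lon_ax, lat_ax)
    land = config.land_mask()

    path_a = _densify(config.pathway_a_waypoints())
    # meander the equatorial stretch of pathway A
    taper = np.exp(-(((np.maximum(path_a[:, 1], 1.0) - 1.0) / 2.5) ** 2))
    s = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(path_a, axis=0).T))])
    path_a = path_a.copy()
    path_a[:, 1] += config.meander_amplitude * np.sin(2 * np.pi * s / config.meander_wavelength) * taper
    path_b = _densify(config.pathway_b_waypoints())

    ua, va, gz, supp_a = _branch_velocity(config, path_a, config.jet_speed_a, lon2d, lat2d)
    ub, vb, _, supp_b = _branch_velocity(config, path_b, config.jet_speed_b, lon2d, lat2d)

    # The planted pathways are pathways of the *total* drift velocity
    # (current + windage fraction of the wind): within the jet cores the
    # current embeds the offset that cancels the design windage, so drifting
    # material follows the route axes instead of slipping off diagonal
    # segments under the uniform trade wind.
    supp = 1.0 - (1.0 - supp_a) * (1.0 - supp_b)
    u_windcomp = -config.windage_design * config.wind_u10 * supp
    v_windcomp = -config.windage_design * config.wind_v10 * supp

    # weak permanent westward drift confined to the equatorial band where
    # pathway A is zonal (flushes the bloom-region box in the
    # forward-dispersal experiment without tilting the diagonal coastal
    # segment off-axis); tapered off near the eastern end of pathway A so
    # backtracked origins stay in-domain
    lon_taper = 0.5 * (1 - np.tanh((lon2d - (config.target_lon + 24.0)) / 1.5))
    lat_taper = 0.5 * (1 - np.tanh((lat2d - 2.5) / 1.0))
    u_bg = -config.background_drift * lon_taper * lat_taper

    rng = np.random.default_rng(np.random.Philox(key=config.seed))
    amp = config.noise_level * config.jet_speed_a

    def smooth_noise():
        w = rng.standard_normal(lon2d.shape)
        w = ndimage.gaussian_filter(w, sigma=4, mode="nearest")
        return amp * w / max(w.std(), 1e-12)

    u_noise, v_noise = smooth_noise(), smooth_noise()

    w_a = calendar.weight_a()[:, None, None]
    gate_a = (1.0 - gz) + gz * w_a          # (365, nlat, nlon)
    gate_b = (1.0 - gz) + gz * (1.0 - w_a)
    u = gate_a * ua + gate_b * ub + (u_bg + u_noise + u_windcomp)[None]
    v = gate_a * va + gate_b * vb + (v_noise + v_windcomp)[None]
    u[:, land] = 0.0
    v[:, land] = 0.0

    currents = VelocityGrid(lon=lon_ax, lat=lat_ax, u=u, v=v, land_mask=land)
    shape = (N_YEARDAYS, lat_ax.size, lon_ax.size)
    wind = WindGrid(
        lon=lon_ax,
        lat=lat_ax,
        u=np.broadcast_to(np.where(land, 0.0, config.wind_u10), shape).copy(),
        v=np.broadcast_to(np.where(land, 0.0, config.wind_v10), shape).copy(),
        land_mask=land,
    )
    return currents, wind


# ---------------------------------------------------------------------------
# drifter fixes


def generate_drifter_fixes(
    grid: VelocityGrid,
    n_drifters: int,
    duration_days: int,
    seed: int,
    noise_sd: float = 0.02,
    drogue_loss_rate: float = 0.0,
    start_year: int = 2010,
) -> DrifterFixSet:
    """Advect drifters forward through ``grid`` and record 6-hourly fixes.

    Each drifter is seeded at a random ocean location and a random start
    year-day, then advected with the pure grid velocity (no windage, no
    turbulence — drifters follow the currents).  Recorded velocities are the
    grid velocities sampled at the fix position plus Gaussian observation
    noise of sd ``noise_sd`` (m/s).  Drifters seeded on land are rejected
    and re-seeded (count logged).  ``drogue_loss_rate`` is the per-day
    probability of losing the drogue.
    """
    if n_drifters < 1 or duration_days < 1:
        raise ValueError("need n_drifters >= 1 and duration_days >= 1")
    rng = np.random.default_rng(np.random.Philox(key=seed))
    dt = 21600.0

    positions = np.empty((n_drifters, 2))
    rejected = 0
    for i in range(n_drifters):
        while True:
            lon = rng.uniform(grid.lon[0], grid.lon[-1])
            lat = rng.uniform(grid.lat[0], grid.lat[-1])
            if not bool(grid.is_land(lon, lat)):
                positions[i] = (lon, lat)
                break
            rejected += 1
    if rejected:
        logger.info("re-seeded %d drifter launch(es) that fell on land", rejected)

    start_yd = rng.integers(0, N_YEARDAYS, size=n_drifters)  # 0-based
    drogue = np.ones(n_drifters, dtype=bool)

    from .geo import meters_to_degrees  # local import to avoid cycle at module load

    rows = []
    n_steps = duration_days * 4
    lon, lat = positions[:, 0].copy(), positions[:, 1].copy()
    for step in range(n_steps):
        day_off, hour = divmod(step * 6, 24)
        yd = (start_yd + day_off) % N_YEARDAYS
        year = start_year + (start_yd + day_off) // N_YEARDAYS
        u, v = grid.sample(lon, lat, yd + hour / 24.0)
        u_obs = u + (rng.standard_normal(n_drifters) * noise_sd if noise_sd > 0 else 0.0)
        v_obs = v + (rng.standard_normal(n_drifters) * noise_sd if noise_sd > 0 else 0.0)
        if drogue_loss_rate > 0 and hour == 0:
            drogue &= rng.random(n_drifters) >= drogue_loss_rate
        for i in range(n_drifters):
            rows.append(
                (int(year[i]), int(yd[i]) + 1, hour, lon[i], lat[i], u_obs[i] if noise_sd > 0 else u[i],
                 v_obs[i] if noise_sd > 0 else v[i], bool(drogue[i]))
            )
        dlon, dlat = meters_to_degrees(u * dt, v * dt, lat)
        nlon = np.clip(lon + dlon, grid.lon[0], grid.lon[-1])
        nlat = np.clip(lat + dlat, grid.lat[0], grid.lat[-1])
        move = ~grid.is_land(nlon, nlat)  # drifters strand on land: stop moving
        lon = np.where(move, nlon, lon)
        lat = np.where(move, nlat, lat)

    df = pd.DataFrame(rows, columns=["year", "day", "hour", "lon", "lat", "u", "v", "drogue"])
    return DrifterFixSet(df)


# ---------------------------------------------------------------------------
# morphotype samples


def generate_morphotype_samples(
    dates,
    calendar: RegimeCalendar,
    params: CompositionParams,
    seed: int,
) -> list[MorphotypeSample]:
    """Draw clump volumes for each collection date from that date's regime Dirichlet.

    Per date, ``params.clumps_per_date`` clumps are drawn; each clump's total
    displacement volume is lognormal around ``mean_total_volume_ml`` and is
    split across the three morphotypes by a Dirichlet draw with the regime's
    mean vector and concentration.  Duplicate dates are allowed (multiple
    collections on one date).
    """
    dates = list(dates)
    if not dates:
        raise ValueError("date list must be non-empty")
    rng = np.random.default_rng(np.random.Philox(key=seed))
    samples = []
    for date in dates:
        regime = calendar.regime_of_date(date)
        alpha = params.mean_for(regime) * params.concentration
        for clump in range(params.clumps_per_date):
            total = params.mean_total_volume_ml * np.exp(rng.normal(0.0, params.volume_log_sd))
            p = rng.dirichlet(alpha)
            vols = total * p
            samples.append(MorphotypeSample(date, clump, *vols))
    return samples


# ---------------------------------------------------------------------------
# environmental fields


def generate_env_fields(config: FieldConfig, seed: int) -> EnvGrid:
    """Smooth SST and chlorophyll-a fields on an 8-day composite time axis.

    SST decreases monotonically poleward (warmer toward the equator) with a
    mild seasonal cycle; chlorophyll is elevated near the synthetic coast
    (river-plume/upwelling analog) with smooth lognormal spatial noise.
    Land cells are NaN.  One year yields 46 composites.
    """
    lon_ax, lat_ax = config.lon_axis(), config.lat_axis()
    lon2d, lat2d = np.meshgrid(lon_ax, lat_ax)
    land = config.land_mask()
    n_comp = int(np.ceil(N_YEARDAYS / 8))  # 46
    t_mid = 8.0 * np.arange(n_comp) + 3.5

    rng = np.random.default_rng(np.random.Philox(key=seed))

    def smooth(scale):
        w = ndimage.gaussian_filter(rng.standard_normal(lon2d.shape), sigma=6, mode="nearest")
        return scale * w / max(w.std(), 1e-12)

    sst_base = 28.8 - 0.24 * lat2d + smooth(0.25)
    season = 1.0 * np.cos(2 * np.pi * (t_mid - 15.0) / N_YEARDAYS)
    sst = sst_base[None] + season[:, None, None]
    sst = sst + 0.1 * rng.standard_normal(sst.shape)

    coast_dist = np.maximum(lat2d - config.coast_lat(lon2d), 0.0)
    chl_base = 0.08 + 0.9 * np.exp(-coast_dist / 2.5)
    chl = chl_base[None] * np.exp(smooth(0.4)[None] + 0.15 * rng.standard_normal(sst.shape))
    chl = np.clip(chl, 0.01, None)

    sst[:, land] = np.nan
    chl[:, land] = np.nan
    return EnvGrid(lon=lon_ax, lat=lat_ax, time_yearday=t_mid, sst=sst, chl=chl)
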