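"""Lagrangian particle advection with windage and stochastic sub-grid turbulence.

Particles are advected through the year-day current climatology by explicit
Euler steps at the 6-h cadence of the source drifter data.  At each step the
current sampled at the particle position is perturbed by the Lagrangian
stochastic model

    u' = u + c * s * Z_u,    v' = v + c * s * Z_v,

with s = sqrt(u^2 + v^2) the current speed, Z independent standard normal
draws and c the turbulence coefficient (default 0.1); a windage fraction
(default 0.5%) of the unperturbed 10-m wind is then added.  Backward
integration reverses the sign of the total velocity and walks the field's
year-day clock backwards.  Displacements are converted to degrees on an
R = 6371 km sphere with the cos(lat) longitude scaling.

Particles whose destination cell is land stall in place and are flagged
grounded (frozen thereafter); particles reaching the domain boundary are
frozen there and flagged.  The ensemble's centre of mass is the arithmetic
mean of endpoint lon/lat — safe because the domain does not span the
antimeridian (asserted).
"""

from __future__ import annotations

import json
import logging
from collections import namedtuple
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .currents import N_YEARDAYS, VelocityGrid, WindGrid, yearday_from_date
from .geo import haversine_km, meters_to_degrees

logger = logging.getLogger(__name__)

__all__ = [
    "TrackConfig",
    "Trajectory",
    "BacktrackResult",
    "RetentionCurve",
    "PerturbedVelocity",
    "perturb_velocity",
    "advect_step",
    "backtrack_sample",
    "forward_dispersal",
]

PerturbedVelocity = namedtuple("PerturbedVelocity", ["u", "v"])


@dataclass(frozen=True)
class TrackConfig:
    """Integration settings for one particle-ensemble simulation."""

    n_particles: int = 100
    horizon_days: int = 365
    dt: float = 21600.0
    windage: float = 0.005
    turbulence_coeff: float = 0.1
    seed: int = 0
    direction: str = "backward"
    include_grounded_in_com: bool = True

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("need at least one particle")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if (self.horizon_days * 86400) % self.dt != 0:
            raise ValueError("horizon must be an integer multiple of dt")
        if self.windage < 0 or self.turbulence_coeff < 0:
            raise ValueError("windage and turbulence coefficient must be non-negative")
        if self.direction not in ("backward", "forward"):
            raise ValueError("direction must be 'backward' or 'forward'")

    @property
    def n_steps(self) -> int:
        return int(self.horizon_days * 86400 / self.dt)

    @property
    def steps_per_day(self) -> int:
        return int(86400 / self.dt)


@dataclass
class Trajectory:
    """One particle's track: positions per step and the running path length."""

    positions: np.ndarray  # (n_steps + 1, 2) lon/lat
    cumulative_distance_km: np.ndarray  # (n_steps + 1,)
    grounded: bool
    grounding_step: int | None

    @property
    def total_distance_km(self) -> float:
        return float(self.cumulative_distance_km[-1])


@dataclass
class BacktrackResult:
    """Ensemble of back-trajectories launched from one collection point/date."""

    simulation_id: str
    launch: tuple  # (lon, lat)
    launch_yearday: int
    config: TrackConfig
    positions: np.ndarray  # (n_steps + 1, n_particles, 2)
    cumdist_km: np.ndarray  # (n_steps + 1, n_particles)
    grounded: np.ndarray  # (n_particles,) bool
    grounding_step: np.ndarray  # (n_particles,) int, -1 if never

    @property
    def endpoints(self) -> np.ndarray:
        return self.positions[-1]

    @property
    def center_of_mass(self) -> tuple[float, float]:
        pts = self.endpoints
        if not self.config.include_grounded_in_com and (~self.grounded).any():
            pts = pts[~self.grounded]
        lon = pts[:, 0]
        assert lon.max() - lon.min() < 180.0, "domain must not span the antimeridian"
        return float(lon.mean()), float(pts[:, 1].mean())

    @property
    def trajectories(self) -> list[Trajectory]:
        return [
            Trajectory(
                positions=self.positions[:, i],
                cumulative_distance_km=self.cumdist_km[:, i],
                grounded=bool(self.grounded[i]),
                grounding_step=int(self.grounding_step[i]) if self.grounding_step[i] >= 0 else None,
            )
            for i in range(self.positions.shape[1])
        ]

    def mean_position_at_day(self, days: int) -> tuple[float, float]:
        """Ensemble-mean particle position after ``days`` integration days."""
        step = int(days * self.config.steps_per_day)
        step = min(step, self.positions.shape[0] - 1)
        pts = self.positions[step]
        return float(pts[:, 0].mean()), float(pts[:, 1].mean())

    # --- serialization --------------------------------------------------

    def endpoints_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "particle": np.arange(self.positions.shape[1]),
                "lon": self.endpoints[:, 0],
                "lat": self.endpoints[:, 1],
                "distance_km": self.cumdist_km[-1],
                "grounded": self.grounded,
            }
        )

    def to_geojson(self, path=None, *, every: int = 4) -> dict:
        """GeoJSON with per-particle LineStrings (subsampled), endpoints and centre of mass."""
        features = []
        for i in range(self.positions.shape[1]):
            coords = self.positions[::every, i].tolist()
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "LineString", "coordinates": coords},
                    "properties": {"particle": i, "grounded": bool(self.grounded[i])},
                }
            )
        com = self.center_of_mass
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [com[0], com[1]]},
                "properties": {"role": "center_of_mass", "simulation": self.simulation_id},
            }
        )
        out = {
            "type": "FeatureCollection",
            "features": features,
            "properties": {
                "simulation": self.simulation_id,
                "launch": list(self.launch),
                "config": {k: v for k, v in vars(self.config).items()},
            },
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(out, fh)
        return out


def perturb_velocity(u, v, coeff: float, rng) -> PerturbedVelocity:
    """Lagrangian stochastic perturbation: add coeff * speed * N(0,1) per component.

    Draws are independent per element and per component; a zero current is
    left untouched (the perturbation scales with current speed).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if coeff == 0:
        return PerturbedVelocity(u, v)
    s = np.hypot(u, v)
    z = rng.standard_normal(u.shape + (2,)) if u.shape else rng.standard_normal(2)
    return PerturbedVelocity(u + coeff * s * z[..., 0], v + coeff * s * z[..., 1])


def _step(
    lon,
    lat,
    active,
    currents: VelocityGrid,
    wind: WindGrid | None,
    yearday: float,
    cfg: TrackConfig,
    rng,
):
    """One Euler step for an array of particles; returns new positions and newly-stuck mask."""
    uc, vc = currents.sample(lon, lat, yearday)
    up, vp = perturb_velocity(uc, vc, cfg.turbulence_coeff, rng)
    if wind is not None and cfg.windage > 0:
        uw, vw = wind.sample(lon, lat, yearday)
        up = up + cfg.windage * uw
        vp = vp + cfg.windage * vw
    sign = -1.0 if cfg.direction == "backward" else 1.0
    dlon, dlat = meters_to_degrees(sign * up * cfg.dt, sign * vp * cfg.dt, lat)

    new_lon = lon + dlon * active
    new_lat = lat + dlat * active

    # freeze at the domain boundary
    out = ~currents.contains(new_lon, new_lat)
    new_lon = np.clip(new_lon, currents.lon[0], currents.lon[-1])
    new_lat = np.clip(new_lat, currents.lat[0], currents.lat[-1])

    # grounding: destination cell is land -> stall in place
    landed = currents.is_land(new_lon, new_lat) & active
    new_lon = np.where(landed, lon, new_lon)
    new_lat = np.where(landed, lat, new_lat)
    stuck = (landed | (out & active))
    return new_lon, new_lat, stuck


def advect_step(pos, currents: VelocityGrid, wind: WindGrid | None, date_yearday: float, cfg: TrackConfig, rng):
    """Single-particle Euler step; returns the new (lon, lat).

    A particle whose destination cell is land stays in place; one leaving the
    domain is frozen at the boundary.  See :func:`backtrack_sample` for whole
    ensembles.
    """
    lon = np.atleast_1d(np.asarray(pos[0], dtype=float))
    lat = np.atleast_1d(np.asarray(pos[1], dtype=float))
    if bool(currents.is_land(lon, lat)[0]):
        return float(lon[0]), float(lat[0])
    new_lon, new_lat, _ = _step(lon, lat, np.ones_like(lon, dtype=bool), currents, wind, date_yearday, cfg, rng)
    return float(new_lon[0]), float(new_lat[0])


def _integrate(lon0, lat0, start_yearday, currents, wind, cfg, rng):
    """Integrate an ensemble; returns positions, cumulative distances, grounding info."""
    n = len(lon0)
    n_steps = cfg.n_steps
    positions = np.empty((n_steps + 1, n, 2))
    cumdist = np.zeros((n_steps + 1, n))
    positions[0, :, 0] = lon0
    positions[0, :, 1] = lat0
    active = np.ones(n, dtype=bool)
    grounding_step = np.full(n, -1, dtype=int)

    sign = -1.0 if cfg.direction == "backward" else 1.0
    lon, lat = np.array(lon0, dtype=float), np.array(lat0, dtype=float)
    day_frac = cfg.dt / 86400.0
    for k in range(n_steps):
        yd = (start_yearday + sign * k * day_frac) % N_YEARDAYS
        new_lon, new_lat, stuck = _step(lon, lat, active, currents, wind, yd, cfg, rng)
        newly = stuck & active
        grounding_step[newly] = k
        active &= ~stuck
        cumdist[k + 1] = cumdist[k] + haversine_km(lon, lat, new_lon, new_lat)
        lon, lat = new_lon, new_lat
        positions[k + 1, :, 0] = lon
        positions[k + 1, :, 1] = lat
    return positions, cumdist, grounding_step


def backtrack_sample(
    launch_lon: float,
    launch_lat: float,
    collection_date,
    currents: VelocityGrid,
    wind: WindGrid | None,
    cfg: TrackConfig,
    simulation_id: str | None = None,
) -> BacktrackResult:
    """Backtrack an ensemble of particles from a collection point and date.

    The launch point is snapped to the nearest ocean cell if coastal (within
    two cells, logged); all particles start there and are integrated for
    ``cfg.horizon_days`` with independent turbulence.  Deterministic for a
    fixed ``cfg.seed``.
    """
    snapped = currents.nearest_ocean(launch_lon, launch_lat, max_cells=2)
    if snapped != (launch_lon, launch_lat):
        logger.info("launch point snapped from (%s, %s) to %s", launch_lon, launch_lat, snapped)
    yd = yearday_from_date(collection_date)
    rng = np.random.default_rng(np.random.Philox(key=cfg.seed))
    n = cfg.n_particles
    positions, cumdist, grounding_step = _integrate(
        np.full(n, snapped[0]), np.full(n, snapped[1]), yd, currents, wind, cfg, rng
    )
    return BacktrackResult(
        simulation_id=simulation_id or str(collection_date),
        launch=snapped,
        launch_yearday=yd,
        config=cfg,
        positions=positions,
        cumdist_km=cumdist,
        grounded=grounding_step >= 0,
        grounding_step=grounding_step,
    )


@dataclass
class RetentionCurve:
    """Fraction of forward-dispersed particles remaining in the seed box per day."""

    days: np.ndarray
    fraction: np.ndarray
    box: tuple

    def first_day_below(self, threshold: float = 0.1) -> int | None:
        idx = np.nonzero(self.fraction <= threshold)[0]
        return int(self.days[idx[0]]) if idx.size else None


def forward_dispersal(
    box: tuple[float, float, float, float],
    n_particles: int,
    horizon_days: int,
    currents: VelocityGrid,
    wind: WindGrid | None,
    cfg: TrackConfig,
    start_yearday: float = 0.0,
) -> RetentionCurve:
    """Seed particles uniformly over the ocean part of ``box`` and advect forward.

    ``box`` is (lon_min, lon_max, lat_min, lat_max).  Returns the daily
    fraction of particles still inside the box; use
    :meth:`RetentionCurve.first_day_below` for the 10%-retention day.
    """
    lon_min, lon_max, lat_min, lat_max = box
    cfg = replace(cfg, direction="forward", horizon_days=horizon_days, n_particles=n_particles)
    rng = np.random.default_rng(np.random.Philox(key=cfg.seed))

    lon0 = np.empty(n_particles)
    lat0 = np.empty(n_particles)
    filled = 0
    for _ in range(1000):
        need = n_particles - filled
        if need == 0:
            break
        lon_try = rng.uniform(lon_min, lon_max, size=need)
        lat_try = rng.uniform(lat_min, lat_max, size=need)
        ok = ~currents.is_land(lon_try, lat_try) & currents.contains(lon_try, lat_try)
        k = int(ok.sum())
        lon0[filled : filled + k] = lon_try[ok]
        lat0[filled : filled + k] = lat_try[ok]
        filled += k
    if filled < n_particles:
        raise ValueError("seed box appears to be (almost) entirely land")

    positions, _, _ = _integrate(lon0, lat0, start_yearday, currents, wind, cfg, rng)
    spd = cfg.steps_per_day
    daily = positions[::spd]  # (horizon_days + 1, n, 2)
    inside = (
        (daily[:, :, 0] >= lon_min)
        & (daily[:, :, 0] <= lon_max)
        & (daily[:, :, 1] >= lat_min)
        & (daily[:, :, 1] <= lat_max)
    )
    return RetentionCurve(days=np.arange(daily.shape[0]), fraction=inside.mean(axis=1), box=box)
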