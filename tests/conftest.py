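"""Shared fixtures: analytic grids and the default synthetic field (session-scoped)."""

from __future__ import annotations

import numpy as np
import pytest

from sargasso.currents import N_YEARDAYS, VelocityGrid, WindGrid
from sargasso.synthetic_data import FieldConfig, RegimeCalendar, generate_current_field


def make_uniform_grid(
    u=0.1,
    v=0.0,
    lon_min=-60.0,
    lon_max=-20.0,
    lat_min=-10.0,
    lat_max=20.0,
    resolution=1.0,
    land=None,
):
    """Spatially uniform, time-constant velocity grid for analytic advection checks."""
    lon = np.arange(lon_min, lon_max + resolution / 2, resolution)
    lat = np.arange(lat_min, lat_max + resolution / 2, resolution)
    shape = (N_YEARDAYS, lat.size, lon.size)
    land_mask = np.zeros((lat.size, lon.size), dtype=bool) if land is None else land
    uu = np.full(shape, float(u))
    vv = np.full(shape, float(v))
    uu[:, land_mask] = 0.0
    vv[:, land_mask] = 0.0
    return VelocityGrid(lon=lon, lat=lat, u=uu, v=vv, land_mask=land_mask)


def make_uniform_wind(u10=0.0, v10=0.0, **kw):
    g = make_uniform_grid(u=u10, v=v10, **kw)
    return WindGrid(lon=g.lon, lat=g.lat, u=g.u, v=g.v, land_mask=g.land_mask)


@pytest.fixture(scope="session")
def default_field():
    """The default planted two-pathway field at 1/4 degree (shared; read-only)."""
    cfg = FieldConfig()
    currents, wind = generate_current_field(cfg, RegimeCalendar())
    return cfg, currents, wind


@pytest.fixture(scope="session")
def steady_field():
    """A time-invariant single-regime field (regime B all year) for reversibility checks."""
    cfg = FieldConfig()
    near_all_b = RegimeCalendar(intervals=((0, 0, "A"), (1, 364, "B")), blend_days=1)
    currents, wind = generate_current_field(cfg, near_all_b)
    # freeze every year-day to mid-year (pure regime B) for exact steadiness
    currents.u[:] = currents.u[182].copy()
    currents.v[:] = currents.v[182].copy()
    return cfg, currents, wind
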