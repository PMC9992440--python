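"""Lagrangian tracker: turbulence model, Euler step, ensembles, dispersal."""

import datetime

import numpy as np
import pytest

from sargasso.geo import M_PER_DEG, haversine_km
from sargasso.tracker import (
    BacktrackResult,
    TrackConfig,
    advect_step,
    backtrack_sample,
    forward_dispersal,
    perturb_velocity,
)

from conftest import make_uniform_grid, make_uniform_wind


class TestPerturbVelocity:
    def test_zero_current_is_never_perturbed(self):
        rng = np.random.default_rng(0)
        u, v = perturb_velocity(0.0, 0.0, 0.5, rng)
        assert (u, v) == (0.0, 0.0)

    def test_zero_coefficient_is_identity(self):
        rng = np.random.default_rng(0)
        u, v = perturb_velocity(1.3, -0.4, 0.0, rng)
        assert (u, v) == (1.3, -0.4)

    def test_perturbation_scale_matches_coeff_times_speed(self):
        # (u,v)=(3,4): speed 5, coeff 0.1 -> sd of u'-u is 0.5
        rng = np.random.default_rng(0)
        n = 100_000
        u, v = perturb_velocity(np.full(n, 3.0), np.full(n, 4.0), 0.1, rng)
        du = u - 3.0
        sd_se = 0.5 / np.sqrt(2 * n)  # MC se of a sample sd
        mean_se = 0.5 / np.sqrt(n)
        assert abs(du.std(ddof=1) - 0.5) < 3 * sd_se
        assert abs(du.mean()) < 3 * mean_se
        dv = v - 4.0
        assert abs(np.corrcoef(du, dv)[0, 1]) < 0.02  # independent components


class TestAdvectStep:
    def test_backward_step_in_uniform_westward_current(self):
        # u = -0.5145 m/s at the equator, dt = 21600 s, backward -> eastward
        # displacement 0.5145*21600 / (R*pi/180) degrees with R = 6371 km
        grid = make_uniform_grid(u=-0.5145, v=0.0)
        cfg = TrackConfig(turbulence_coeff=0.0, windage=0.0, direction="backward")
        rng = np.random.default_rng(0)
        lon1, lat1 = advect_step((-40.0, 0.0), grid, None, 100.0, cfg, rng)
        expected = 0.5145 * 21600 / M_PER_DEG
        assert lon1 - (-40.0) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.1, abs=1e-3)  # ~0.1 degree per 6 h at 1 knot
        assert lat1 == 0.0

    def test_windage_equals_equivalent_current(self):
        grid = make_uniform_grid(u=0.0, v=0.0)
        wind = make_uniform_wind(u10=10.0)
        cfg = TrackConfig(turbulence_coeff=0.0, windage=0.005, direction="forward")
        rng = np.random.default_rng(0)
        lon1, _ = advect_step((-40.0, 0.0), grid, wind, 0.0, cfg, rng)
        grid2 = make_uniform_grid(u=0.05, v=0.0)  # 0.5% of 10 m/s
        lon2, _ = advect_step((-40.0, 0.0), grid2, None, 0.0, cfg, rng)
        assert lon1 == pytest.approx(lon2, abs=1e-12)

    def test_particle_on_land_stays_put(self):
        land = np.zeros((31, 41), dtype=bool)
        land[10, 20] = True
        grid = make_uniform_grid(u=0.5, land=land)
        cfg = TrackConfig(turbulence_coeff=0.0, windage=0.0)
        pos = (grid.lon[20], grid.lat[10])
        new = advect_step(pos, grid, None, 0.0, cfg, np.random.default_rng(0))
        assert new == pos

    def test_cos_lat_scaling_of_longitude_step(self):
        grid = make_uniform_grid(u=0.2, v=0.0)
        cfg = TrackConfig(turbulence_coeff=0.0, windage=0.0, direction="forward")
        rng = np.random.default_rng(0)
        lon_eq, _ = advect_step((-40.0, 0.0), grid, None, 0.0, cfg, rng)
        lon_60, _ = advect_step((-40.0, 18.0), grid, None, 0.0, cfg, rng)
        dl_eq = lon_eq + 40.0
        dl_18 = lon_60 + 40.0
        assert dl_18 == pytest.approx(dl_eq / np.cos(np.radians(18.0)), rel=1e-12)


class TestBacktrackSample:
    DATE = datetime.date(2021, 5, 10)

    def test_deterministic_flow_collapses_ensemble(self):
        grid = make_uniform_grid(u=-0.1, v=0.02)
        cfg = TrackConfig(n_particles=20, horizon_days=30, turbulence_coeff=0.0, windage=0.0, seed=1)
        res = backtrack_sample(-40.0, 5.0, self.DATE, grid, None, cfg)
        ends = res.endpoints
        assert np.ptp(ends[:, 1]) == 0.0
        # backward integration reverses the northward component
        expected_lat = 5.0 - 0.02 * 21600 * cfg.n_steps / M_PER_DEG
        assert ends[0, 1] == pytest.approx(expected_lat, abs=1e-9)
        com = res.center_of_mass
        assert com[1] == pytest.approx(expected_lat, abs=1e-9)

    def test_zonal_closed_form_365_days(self):
        grid = make_uniform_grid(u=-0.05, v=0.0)
        cfg = TrackConfig(n_particles=2, horizon_days=365, turbulence_coeff=0.0, windage=0.0, seed=1)
        res = backtrack_sample(-40.0, 0.0, self.DATE, grid, None, cfg)
        expected_lon = -40.0 + 0.05 * 86400 * 365 / M_PER_DEG
        assert res.endpoints[0, 0] == pytest.approx(expected_lon, abs=1e-6)

    def test_same_seed_reproduces_result(self, default_field):
        _, currents, wind = default_field
        cfg = TrackConfig(n_particles=10, horizon_days=20, seed=7)
        r1 = backtrack_sample(-59.56, 13.27, self.DATE, currents, wind, cfg)
        r2 = backtrack_sample(-59.56, 13.27, self.DATE, currents, wind, cfg)
        assert np.array_equal(r1.positions, r2.positions)
        assert np.array_equal(r1.cumdist_km, r2.cumdist_km)

    def test_cumulative_distance_bounds_displacement(self, default_field):
        _, currents, wind = default_field
        cfg = TrackConfig(n_particles=10, horizon_days=60, seed=3)
        res = backtrack_sample(-59.56, 13.27, self.DATE, currents, wind, cfg)
        ends = res.endpoints
        direct = haversine_km(res.launch[0], res.launch[1], ends[:, 0], ends[:, 1])
        assert np.all(res.cumdist_km[-1] + 1e-9 >= direct)
        assert np.all(np.diff(res.cumdist_km, axis=0) >= -1e-12)

    def test_ensemble_com_near_deterministic_endpoint_in_uniform_flow(self):
        # MC error of the centre of mass ~ coeff*s*sqrt(T*dt)/sqrt(n)
        speed = 0.2
        grid = make_uniform_grid(u=-speed, v=0.0)
        cfg = TrackConfig(n_particles=100, horizon_days=60, turbulence_coeff=0.1, windage=0.0, seed=11)
        res = backtrack_sample(-40.0, 0.0, self.DATE, grid, None, cfg)
        det_lon = -40.0 + speed * 86400 * 60 / M_PER_DEG
        diffusion_m = 0.1 * speed * np.sqrt(cfg.n_steps) * cfg.dt  # random-walk sd after N steps
        tol_deg = 3 * (diffusion_m / M_PER_DEG) / np.sqrt(cfg.n_particles)
        assert abs(res.center_of_mass[0] - det_lon) < tol_deg

    def test_launch_far_from_ocean_raises(self):
        land = np.ones((31, 41), dtype=bool)
        land[25:, :] = False
        grid = make_uniform_grid(u=0.1, land=land)
        cfg = TrackConfig(n_particles=2, horizon_days=1)
        with pytest.raises(ValueError):
            backtrack_sample(grid.lon[20], grid.lat[5], self.DATE, grid, None, cfg)

    def test_grounded_particle_freezes_and_flags(self):
        land = np.zeros((31, 41), dtype=bool)
        land[:, :18] = True  # western half land; westward forward flow grounds particles
        grid = make_uniform_grid(u=-0.5, v=0.0, land=land)
        cfg = TrackConfig(n_particles=3, horizon_days=30, turbulence_coeff=0.0, windage=0.0, direction="forward")
        res = backtrack_sample(grid.lon[19], grid.lat[15], self.DATE, grid, None, cfg)
        assert res.grounded.all()
        assert np.all(res.grounding_step >= 0)
        stop = res.grounding_step[0]
        assert np.array_equal(res.positions[stop], res.positions[-1])


class TestForwardDispersal:
    def test_domain_wide_box_retains_everything(self):
        grid = make_uniform_grid(u=-0.3, v=0.1)
        cfg = TrackConfig(seed=2, turbulence_coeff=0.1)
        box = (grid.lon[0], grid.lon[-1], grid.lat[0], grid.lat[-1])
        curve = forward_dispersal(box, 50, 30, grid, None, cfg)
        assert np.all(curve.fraction == 1.0)

    def test_uniform_jet_flushes_box_at_analytic_transit_time(self):
        speed = 0.3
        grid = make_uniform_grid(u=-speed, v=0.0, lat_min=-2.0, lat_max=2.0)
        cfg = TrackConfig(seed=5, turbulence_coeff=0.0, windage=0.0)
        box = (-45.0, -35.0, -1.0, 1.0)
        width_m = 10.0 * M_PER_DEG * np.cos(np.radians(0.0))  # ~10 deg at low lat
        transit_days = width_m / (speed * 86400)
        curve = forward_dispersal(box, 200, 60, grid, None, cfg)
        assert np.all(np.diff(curve.fraction) <= 1e-12)
        assert np.all((curve.fraction >= 0) & (curve.fraction <= 1))
        empty_day = np.argmax(curve.fraction == 0.0)
        assert empty_day <= np.ceil(transit_days) + 1
        assert curve.fraction[int(transit_days) - 2] > 0.0

    def test_all_land_box_raises(self):
        land = np.ones((31, 41), dtype=bool)
        land[:3, :3] = False
        grid = make_uniform_grid(u=0.1, land=land)
        cfg = TrackConfig(seed=0)
        with pytest.raises(ValueError):
            forward_dispersal((grid.lon[30], grid.lon[40], grid.lat[20], grid.lat[30]), 20, 5, grid, None, cfg)


def test_track_config_validation():
    with pytest.raises(ValueError):
        TrackConfig(dt=-1)
    with pytest.raises(ValueError):
        TrackConfig(horizon_days=1, dt=86400 * 0.7)
    with pytest.raises(ValueError):
        TrackConfig(direction="sideways")
    with pytest.raises(ValueError):
        TrackConfig(n_particles=0)
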