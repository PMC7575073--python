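import numpy as np
import pytest

from reefcool import (SolverConfig, TracerState, InjectionSite, StabilityError,
                      step, run_age, run_injection, volume_integral, stable_dt,
                      make_forcing, flow_from_streamfunction)
from reefcool.tracer_engine import states_to_netcdf, states_from_netcdf

from conftest import (uniform_grid, channel_grid, sealed_basin_grid,
                      steady_uniform_flow, closed_gyre_flow)

DAY = 86400.0


def zero_flow(grid, K=0.0):
    psi = np.zeros((grid.ny + 1, grid.nx + 1))
    return flow_from_streamfunction(grid, psi, times=np.array([0.0, 1e8]), K=K)


class TestStep:
    def test_no_flow_no_diffusion_no_source_is_identity(self):
        grid = uniform_grid(6, 8, 10.0)
        flow = zero_flow(grid)
        rng = np.random.default_rng(0)
        c0 = rng.random((6, 8))
        state = TracerState(values=c0.copy(), time=0.0)
        out = step(state, grid, flow, SolverConfig(dt=600.0))
        assert np.array_equal(out.values, c0)
        assert out.time == 600.0

    def test_uniform_tracer_preserved_by_nondivergent_flow(self):
        # constancy preservation of conservative upwind, variable depth
        rng = np.random.default_rng(1)
        depth = 10.0 + 5.0 * rng.random((8, 8))
        grid = uniform_grid(8, 8, 10.0)
        grid = type(grid)(dx=grid.dx, dy=grid.dy, depth=depth)
        flow = closed_gyre_flow(grid, 200.0)
        cfg = SolverConfig(dt=0.9 * stable_dt(grid, flow),
                           open_boundaries=False)
        state = TracerState(values=np.full((8, 8), 3.7), time=0.0)
        for _ in range(50):
            state = step(state, grid, flow, cfg, boundary_value=3.7)
        assert np.allclose(state.values[grid.wet_mask], 3.7, rtol=0, atol=1e-12)

    def test_tophat_centroid_advects_at_flow_speed(self):
        # analytic oracle: a passive patch translates at u, so its
        # mass-weighted centroid moves u*t
        grid = channel_grid(nx=120, ny=3, dx=10.0, depth=5.0)
        u = 0.1
        flow = steady_uniform_flow(grid, u, 5.0)
        c = np.zeros((3, 120))
        c[:, 20:30] = 1.0
        state = TracerState(values=c, time=0.0)
        cfg = SolverConfig(dt=0.9 * stable_dt(grid, flow))
        t_end = 4000.0
        n = int(round(t_end / cfg.dt))
        for _ in range(n):
            state = step(state, grid, flow, cfg, boundary_value=0.0)
        x = grid.x
        c0_centroid = np.sum(x * c[1]) / np.sum(c[1])
        centroid = np.sum(x * state.values[1]) / np.sum(state.values[1])
        assert abs(centroid - (c0_centroid + u * n * cfg.dt)) < grid.dx

    def test_refuses_unstable_step_and_reports_required_dt(self):
        grid = channel_grid(nx=40, ny=3, dx=10.0, depth=5.0)
        flow = steady_uniform_flow(grid, 0.5, 5.0)
        state = TracerState(values=np.zeros((3, 40)), time=0.0)
        with pytest.raises(StabilityError) as err:
            step(state, grid, flow, SolverConfig(dt=1e4))
        dt_ok = err.value.required_dt
        assert 0 < dt_ok < 1e4
        step(state, grid, flow, SolverConfig(dt=dt_ok))  # must not raise

    def test_closed_domain_conserves_tracer_per_step(self):
        grid = uniform_grid(10, 10, 20.0, dx=50.0)
        flow = closed_gyre_flow(grid, 300.0, K=2.0)
        rng = np.random.default_rng(2)
        state = TracerState(values=rng.random((10, 10)), time=0.0)
        cfg = SolverConfig(dt=0.8 * stable_dt(grid, flow),
                           open_boundaries=False)
        total0 = volume_integral(state, grid)
        prev = total0
        for _ in range(100):
            state = step(state, grid, flow, cfg)
            total = volume_integral(state, grid)
            assert abs(total - prev) <= 1e-12 * abs(total0)
            prev = total

    def test_advection_error_decreases_under_refinement(self):
        # L1 error of the advected top-hat vs the exact translation shrinks
        # monotonically as dx is refined
        u, t_end = 0.1, 3000.0
        errors = []
        for nx, dx in ((60, 40.0), (120, 20.0), (240, 10.0)):
            grid = channel_grid(nx=nx, ny=3, dx=dx, depth=5.0)
            flow = steady_uniform_flow(grid, u, 5.0)
            c = np.where((grid.x >= 400.0) & (grid.x < 800.0), 1.0, 0.0)
            state = TracerState(values=np.tile(c, (3, 1)), time=0.0)
            cfg = SolverConfig(dt=0.5 * stable_dt(grid, flow))
            n = int(round(t_end / cfg.dt))
            for _ in range(n):
                state = step(state, grid, flow, cfg, boundary_value=0.0)
            exact = np.where((grid.x >= 400.0 + u * n * cfg.dt)
                             & (grid.x < 800.0 + u * n * cfg.dt), 1.0, 0.0)
            errors.append(np.abs(state.values[1] - exact).sum() * dx)
        assert errors[0] > errors[1] > errors[2]


class TestRunAge:
    def test_sealed_reef_basin_age_equals_elapsed_time(self):
        grid = sealed_basin_grid(depth=5.0)  # < 10 m: a reef cell
        flow = zero_flow(grid)
        states = run_age(grid, flow, SolverConfig(dt=1800.0),
                         duration=2 * DAY, sample_interval=6 * 3600.0)
        for s in states:
            assert s.values[1, 1] == pytest.approx(s.time / DAY, rel=1e-9)

    def test_age_bounded_by_elapsed_time(self, island_grid):
        from reefcool import make_tidal_flow
        flow = make_tidal_flow(island_grid, 0.3, 0.1, K=2.0)
        states = run_age(island_grid, flow, SolverConfig(dt=60.0),
                         duration=DAY, sample_interval=3 * 3600.0)
        for s in states:
            vals = s.values[island_grid.wet_mask]
            assert vals.min() >= 0.0
            assert vals.max() <= s.time / DAY + 1e-9

    def test_steady_channel_age_matches_distance_over_speed(self):
        # analytic oracle: age at the strip exit is strip length / velocity
        u = 0.1
        grid = channel_grid(nx=100, ny=3, dx=20.0, depth=15.0,
                            reef_cols=slice(25, 75))  # 1000 m reef strip
        flow = steady_uniform_flow(grid, u, 2.0)
        states = run_age(grid, flow, SolverConfig(dt=30.0),
                         duration=40000.0, sample_interval=4000.0)
        exit_age_days = states[-1].values[1, 74]
        assert exit_age_days == pytest.approx(1000.0 / u / DAY, rel=0.05)

    def test_upstream_cells_never_age(self):
        grid = channel_grid(nx=100, ny=3, dx=20.0, depth=15.0,
                            reef_cols=slice(50, 75))
        flow = steady_uniform_flow(grid, 0.1, 2.0)
        states = run_age(grid, flow, SolverConfig(dt=30.0),
                         duration=30000.0, sample_interval=5000.0)
        assert np.all(states[-1].values[:, :50] == 0.0)


class TestRunInjection:
    def make_setup(self):
        grid = uniform_grid(8, 8, 10.0, dx=50.0)
        flow = closed_gyre_flow(grid, 100.0, K=1.0)
        forcing = make_forcing(28.0, source_temp=27.0)
        return grid, flow, forcing

    def test_zero_rate_matches_control(self):
        grid, flow, forcing = self.make_setup()
        sites = [InjectionSite(cell=(4, 4), Q=0.0, T_inj=27.0)]
        ctrl, inj = run_injection(grid, flow, SolverConfig(dt=60.0), forcing,
                                  sites, duration=6 * 3600.0,
                                  sample_interval=3600.0)
        for a, b in zip(ctrl, inj):
            assert np.array_equal(a.values, b.values)

    def test_ambient_temperature_injection_matches_control(self):
        grid, flow, forcing = self.make_setup()
        sites = [InjectionSite(cell=(4, 4), Q=2.0, T_inj=forcing.mean_temp)]
        ctrl, inj = run_injection(grid, flow, SolverConfig(dt=60.0), forcing,
                                  sites, duration=6 * 3600.0,
                                  sample_interval=3600.0)
        for a, b in zip(ctrl, inj):
            assert np.allclose(a.values, b.values, rtol=0, atol=1e-12)

    def test_temperature_stays_in_convex_hull(self):
        grid, flow, forcing = self.make_setup()
        sites = [InjectionSite(cell=(4, 4), Q=5.0, T_inj=27.0)]
        _, inj = run_injection(grid, flow, SolverConfig(dt=120.0), forcing,
                               sites, duration=DAY, sample_interval=3 * 3600.0)
        for s in inj:
            vals = s.values[grid.wet_mask]
            assert vals.min() >= 27.0 - 1e-12
            assert vals.max() <= 28.0 + 1e-12

    def test_closed_basin_exponential_flushing(self):
        # analytic oracle: a sealed well-mixed basin relaxes to T_inj as
        # T(t) = T_inj + (T_a - T_inj) exp(-Q t / V)
        grid = sealed_basin_grid(depth=10.0, dx=40.0)
        vol = float(grid.cell_volume[1, 1])
        flow = zero_flow(grid)
        forcing = make_forcing(28.0, source_temp=27.0)
        Q = 0.05
        sites = [InjectionSite(cell=(1, 1), Q=Q, T_inj=27.0)]
        duration = 2.0 * vol / Q
        _, inj = run_injection(grid, flow, SolverConfig(dt=500.0), forcing,
                               sites, duration=duration,
                               sample_interval=duration / 16)
        for s in inj[1:]:
            expected = 27.0 + 1.0 * np.exp(-Q * s.time / vol)
            assert s.values[1, 1] == pytest.approx(expected, rel=0.01)

    def test_daily_window_schedule_only_injects_in_window(self):
        site = InjectionSite(cell=(1, 1), Q=1.0, T_inj=27.0,
                             schedule=(11.0, 14.0))
        assert not site.active(10.99 * 3600.0)
        assert site.active(11.0 * 3600.0)
        assert site.active(13.5 * 3600.0)
        assert not site.active(14.0 * 3600.0)
        assert site.active((24 + 12) * 3600.0)

        grid = sealed_basin_grid(depth=10.0)
        flow = zero_flow(grid)
        forcing = make_forcing(28.0, source_temp=27.0)
        _, inj = run_injection(grid, flow, SolverConfig(dt=600.0), forcing,
                               [site], duration=DAY, sample_interval=3600.0)
        temps = np.array([s.values[1, 1] for s in inj])
        # stagnant sealed basin: temperature moves only during 11:00-14:00
        assert np.all(temps[:12] == 28.0)
        assert temps[14] < temps[11]
        assert np.all(temps[14:] == temps[14])

    def test_site_on_land_rejected(self, island_grid):
        flow = zero_flow(island_grid)
        forcing = make_forcing(28.0, source_temp=27.0)
        land_cell = tuple(np.argwhere(island_grid.land_mask)[0])
        with pytest.raises(ValueError, match="land"):
            run_injection(island_grid, flow, SolverConfig(dt=60.0), forcing,
                          [InjectionSite(cell=land_cell, Q=1.0, T_inj=27.0)],
                          duration=3600.0)

    def test_site_outside_grid_rejected(self):
        grid = uniform_grid(5, 5, 10.0)
        flow = zero_flow(grid)
        forcing = make_forcing(28.0, source_temp=27.0)
        with pytest.raises(ValueError, match="outside"):
            run_injection(grid, flow, SolverConfig(dt=60.0), forcing,
                          [InjectionSite(cell=(9, 1), Q=1.0, T_inj=27.0)],
                          duration=3600.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            InjectionSite(cell=(0, 0), Q=-1.0, T_inj=27.0)

    def test_schedule_window_validated(self):
        with pytest.raises(ValueError):
            InjectionSite(cell=(0, 0), Q=1.0, T_inj=27.0, schedule=(11.0, 25.0))


def test_trajectory_netcdf_roundtrip(tmp_path):
    grid = sealed_basin_grid(depth=5.0)
    flow = zero_flow(grid)
    states = run_age(grid, flow, SolverConfig(dt=1800.0), duration=DAY,
                     sample_interval=6 * 3600.0)
    path = tmp_path / "age.nc"
    states_to_netcdf(states, grid, path)
    back = states_from_netcdf(path)
    assert len(back) == len(states)
    for a, b in zip(states, back):
        assert a.time == b.time and a.kind == b.kind
        assert np.array_equal(a.values, b.values)
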