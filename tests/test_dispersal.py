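"""Tracer solver: schedules, conservation, closed-form limits, exposure maps."""

import math

import numpy as np
import pytest

from deltarisk import dispersal, synth
from deltarisk.dispersal import (
    CageRelease,
    CFLError,
    ConcentrationHistory,
    FlowField,
    Grid,
    TracerParams,
    build_schedule,
    max_map,
    simulate,
    step,
    time_above,
)


def uniform_flow(u, v, duration_s=1e9):
    return FlowField(times=[0.0, duration_s], u=[u, u], v=[v, v])


class TestSchedule:
    positions = [(100.0 * i, 0.0) for i in range(10)]

    def test_seven_cages_span_three_days(self):
        sched = build_schedule(7, 12.0, self.positions)
        assert [r.start for r in sched] == [0, 12, 24, 36, 48, 60, 72]

    def test_single_cage(self):
        (rel,) = build_schedule(1, 12.0, self.positions)
        assert rel.start == 0.0

    def test_released_mass_is_volume_times_concentration(self):
        (rel,) = build_schedule(1, 0.0, self.positions, treatment_conc=2000.0, pen_volume=5000.0)
        # 5000 m^3 = 5e6 L at 2000 ng/L -> 1e10 ng = 10 g per cage
        assert rel.mass == pytest.approx(1e10)

    def test_negative_interval_rejected(self):
        with pytest.raises(ValueError):
            build_schedule(2, -1.0, self.positions)


class TestStep:
    grid = Grid(nx=30, ny=30, dx=10.0)

    def test_no_flow_no_mixing_leaves_field_unchanged(self):
        c = np.zeros((30, 30))
        c[15, 15] = 7.0
        params = TracerParams(diffusivity=0.0, dt=1.0)
        out = step(c, (0.0, 0.0), params, self.grid)
        np.testing.assert_array_equal(out, c)

    def test_uniform_flow_displaces_centroid_by_u_dt(self):
        c = np.zeros((30, 30))
        c[14:17, 14:17] = 1.0
        u, dt = 2.0, 2.5
        params = TracerParams(diffusivity=0.0, dt=dt)
        out = step(c, (u, 0.0), params, self.grid, boundary="closed")
        x = self.grid.x
        before = (c.sum(axis=0) * x).sum() / c.sum()
        after = (out.sum(axis=0) * x).sum() / out.sum()
        assert after - before == pytest.approx(u * dt, rel=1e-12)

    def test_pure_diffusion_matches_gaussian(self):
        """Point release under pure diffusion vs the 2-D heat kernel, sigma^2 = 2Dt."""
        grid = Grid(nx=101, ny=101, dx=1.0)
        c = np.zeros((101, 101))
        c[50, 50] = 1.0
        D, dt, nsteps = 0.2, 1.0, 100
        params = TracerParams(diffusivity=D, dt=dt)
        for _ in range(nsteps):
            c = step(c, (0.0, 0.0), params, grid, boundary="closed")
        t = nsteps * dt
        xs, ys = np.meshgrid(grid.x - grid.x[50], grid.y - grid.y[50])
        gauss = np.exp(-(xs**2 + ys**2) / (4 * D * t)) / (4 * math.pi * D * t)
        rel_l2 = np.linalg.norm(c - gauss) / np.linalg.norm(gauss)
        assert rel_l2 < 0.02

    def test_unit_courant_advection_is_exact_translation(self):
        c = np.zeros((30, 30))
        c[10:14, 10:14] = np.arange(16.0).reshape(4, 4)
        params = TracerParams(diffusivity=0.0, dt=5.0)  # u*dt/dx = 1 exactly
        out = step(c, (2.0, 0.0), params, self.grid, boundary="closed")
        np.testing.assert_allclose(out[:, 1:], c[:, :-1], atol=1e-12)

    def test_advective_cfl_violation_names_ratio(self):
        c = np.zeros((30, 30))
        with pytest.raises(CFLError, match=r"dt/dx"):
            step(c, (3.0, 0.0), TracerParams(dt=5.0), self.grid)

    def test_diffusive_stability_violation_names_ratio(self):
        c = np.zeros((30, 30))
        with pytest.raises(CFLError, match=r"dx\^2"):
            step(c, (0.0, 0.0), TracerParams(diffusivity=30.0, dt=1.0), self.grid)

    def test_positivity_preserved_on_random_fields(self, rng):
        params = TracerParams(diffusivity=5.0, dt=1.0)
        for _ in range(20):
            c = rng.random((30, 30)) * rng.exponential(5.0)
            out = step(c, (rng.uniform(-8, 8), rng.uniform(-8, 8)), params, self.grid)
            assert (out >= 0).all()

    def test_closed_boundaries_conserve_mass_exactly(self, rng):
        params = TracerParams(diffusivity=5.0, dt=1.0)
        c = rng.random((30, 30))
        total = c.sum()
        for _ in range(50):
            c = step(c, (4.0, -3.0), params, self.grid, boundary="closed")
        assert c.sum() == pytest.approx(total, rel=1e-12)


class TestSimulate:
    grid = Grid(nx=40, ny=40, dx=100.0)
    centre = (2000.0, 2000.0)

    def test_empty_schedule_stays_zero(self):
        h = simulate(self.grid, uniform_flow(0.05, 0.0), [],
                     TracerParams(dt=300.0, duration=0.5))
        assert np.all(h.fields == 0)

    def test_mass_conserved_with_closed_boundaries(self):
        sched = build_schedule(3, 6.0, [self.centre] * 3)
        h = simulate(self.grid, uniform_flow(0.03, 0.02), sched,
                     TracerParams(dt=300.0, duration=1.0), boundary="closed")
        mass = h.mass_series()
        assert mass[-1] == pytest.approx(h.released_mass[-1], rel=1e-3)
        # and at every snapshot after the first release
        np.testing.assert_allclose(mass[1:], h.released_mass[1:], rtol=1e-3)

    def test_open_boundaries_lose_mass_monotonically_after_last_release(self):
        sched = build_schedule(1, 0.0, [self.centre])
        h = simulate(self.grid, uniform_flow(0.1, 0.0), sched,
                     TracerParams(dt=200.0, duration=1.0), boundary="open")
        mass = h.mass_series()
        assert (np.diff(mass) <= 1e-9 * mass.max()).all()

    def test_decay_halves_mass_over_one_half_life(self):
        """First-order decay at the literature seawater half-life of 17.9 days."""
        half_life = 17.9
        sched = build_schedule(1, 0.0, [self.centre])
        params = TracerParams(
            diffusivity=0.0, decay_rate=math.log(2) / half_life,
            dt=half_life * 86400 / 200, duration=half_life,
        )
        h = simulate(self.grid, uniform_flow(0.0, 0.0), sched, params,
                     boundary="closed", snapshot_interval=half_life * 24 / 10)
        mass = h.mass_series()
        assert mass[-1] / mass[0] == pytest.approx(0.5, rel=1e-9)

    def test_release_outside_grid_rejected(self):
        sched = [CageRelease(position=(1e6, 0.0), start=0.0, volume=100.0)]
        with pytest.raises(ValueError):
            simulate(self.grid, uniform_flow(0, 0), sched, TracerParams(dt=300.0, duration=0.1))

    def test_dilution_peak_nonincreasing_between_releases(self):
        sched = build_schedule(2, 12.0, [self.centre] * 2)
        h = simulate(self.grid, uniform_flow(0.02, 0.0), sched,
                     TracerParams(diffusivity=1.0, dt=300.0, duration=1.0))
        peaks = h.fields.max(axis=(1, 2))
        within_first_release = peaks[1:12]  # hourly snapshots before the 12-h release
        assert (np.diff(within_first_release) <= 1e-12).all()


def make_history(fields, dt_h=1.0):
    fields = np.asarray(fields, dtype=float)
    grid = Grid(nx=fields.shape[2], ny=fields.shape[1], dx=100.0)
    return ConcentrationHistory(
        times=np.arange(fields.shape[0]) * dt_h, fields=fields, grid=grid, mixing_depth=10.0
    )


class TestExposureMaps:
    def test_max_map_of_single_snapshot_is_that_snapshot(self, rng):
        f = rng.random((1, 5, 5))
        np.testing.assert_array_equal(max_map(make_history(f)), f[0])

    def test_max_map_of_decaying_field_is_first_snapshot(self):
        base = np.full((4, 4), 8.0)
        f = np.array([base * (0.5**k) for k in range(5)])
        np.testing.assert_array_equal(max_map(make_history(f)), base)

    def test_max_map_dominates_every_snapshot(self, rng):
        f = rng.random((6, 5, 5))
        mm = max_map(make_history(f))
        assert (mm[None, :, :] >= f).all()

    def test_time_above_zero_when_threshold_exceeds_peak(self, rng):
        f = rng.random((5, 4, 4))
        assert np.all(time_above(make_history(f), 2.0) == 0)

    def test_time_above_zero_threshold_counts_everything(self):
        f = np.ones((5, 3, 3))
        np.testing.assert_array_equal(time_above(make_history(f), 0.0), np.full((3, 3), 5.0))

    def test_square_pulse_duration_recovered(self):
        """A 6-h pulse above threshold, sampled hourly, reads back 6 h +/- one interval."""
        nt = 24
        f = np.zeros((nt, 3, 3))
        f[5:11, 1, 1] = 10.0  # 6 hourly snapshots above the threshold
        hours = time_above(make_history(f), 2.0)[1, 1]
        assert abs(hours - 6.0) <= 1.0

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            max_map(make_history(np.zeros((0, 3, 3))))


class TestSyntheticCurrents:
    def test_plume_reaches_beyond_regulatory_distance(self):
        """With default residual currents the lethal contour passes 1 km from the pens,
        far beyond the 500 m zone within which releases are prohibited."""
        grid = Grid(nx=80, ny=80, dx=100.0)
        flow = synth.gen_flow_field(synth.FlowFieldSpec(seed=7), grid, 36.0, 300.0)
        centre = (4000.0, 4000.0)
        sched = build_schedule(3, 12.0, [centre] * 3)
        h = simulate(grid, flow, sched, TracerParams(dt=300.0, duration=1.5))
        from deltarisk.impact import max_extent

        extent_km = max_extent(max_map(h), 2.0, centre, grid)
        assert extent_km > 1.0
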