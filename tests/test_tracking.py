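"""Release schedules, interpolation, RK4 integration and the bulk tracker."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from reefdrift import tracking
from reefdrift.ocean import DomainConfig, generate_domain
from reefdrift.tracking import (
    PLD_DAYS,
    ReleaseSchedule,
    depth_for_age,
    interpolate_velocity,
    make_release_schedule,
    rk4_step,
    track_particles,
)

from conftest import make_rotation_field, make_uniform_field


def manual_schedule(positions, release_hours=None, counts=None):
    """Schedule with explicit start positions (one entry per particle group)."""
    n = len(positions)
    release_hours = release_hours if release_hours is not None else [0.0] * n
    counts = counts if counts is not None else [1] * n
    rows = [
        (i + 1, 1, 0, 0, x, y, int(rh // 24), float(rh), c)
        for i, ((x, y), rh, c) in enumerate(zip(positions, release_hours, counts))
    ]
    entries = pd.DataFrame(
        rows,
        columns=[
            "reef_id", "region_id", "cell_iy", "cell_ix",
            "x_km", "y_km", "release_day", "release_hour", "count",
        ],
    )
    return ReleaseSchedule(entries=entries, rate=0, release_days=np.array([0]))


class TestDepthSchedule:
    @pytest.mark.parametrize(
        "age,depth",
        [(0.0, 1.0), (0.5, 1.0), (1.0, 3.0), (10.0, 3.0), (19.99, 3.0),
         (20.0, 6.0), (23.0, 6.0), (25.0, 6.0)],
    )
    def test_piecewise_mapping(self, age, depth):
        assert depth_for_age(age) == depth

    @pytest.mark.parametrize("age", [-0.1, 25.01, 100.0])
    def test_out_of_range_rejected(self, age):
        with pytest.raises(ValueError):
            depth_for_age(age)

    @given(st.floats(min_value=0.0, max_value=25.0, allow_nan=False))
    def test_depth_always_one_of_three_layers(self, age):
        assert depth_for_age(age) in (1.0, 3.0, 6.0)


class TestReleaseSchedule:
    def test_particle_arithmetic(self):
        cfg = DomainConfig(
            n_sectors=1, rows_per_sector=1, bands=("inshore",),
            n_regions=1, n_reefs_total=3,
        )
        dom = generate_domain(cfg, seed=0)
        sched = make_release_schedule(dom, rate=100, release_days=2)
        assert sched.n_particles == 600  # 3 cells × 2 days × 100

    def test_zero_rate_is_empty(self, small_domain):
        sched = make_release_schedule(small_domain, rate=0, release_days=5)
        assert sched.n_particles == 0
        assert len(sched.entries) == 0

    def test_full_scale_count(self, default_domain):
        sched = make_release_schedule(default_domain, rate=100, release_days=92)
        assert sched.n_particles == 1_297_200  # 141 × 92 × 100

    def test_window_beyond_field_coverage_rejected(self, small_domain):
        fld = make_uniform_field(n_hours=100)  # < 25 d of coverage
        with pytest.raises(ValueError, match="coverage"):
            make_release_schedule(small_domain, rate=1, release_days=1, field=fld)


class TestInterpolation:
    def test_node_and_snapshot_coincidence(self):
        fld = make_uniform_field(n_hours=3, ny=4, nx=4)
        fld.u[1, 0, 2, 1] = 0.7
        u, v = interpolate_velocity(fld, (fld.grid_x[1], fld.grid_y[2]), 1.0, 1.0)
        assert u == pytest.approx(0.7)
        assert v == pytest.approx(0.0)

    def test_uniform_field_everywhere(self):
        fld = make_uniform_field(u=0.5, n_hours=3, ny=4, nx=4)
        u, _ = interpolate_velocity(fld, (17.3, 22.9), 1.4, 1.0)
        assert u == pytest.approx(0.5)

    def test_linear_time_interpolation(self):
        fld = make_uniform_field(n_hours=2, ny=4, nx=4)
        fld.u[0] = 0.0
        fld.u[1] = 1.0
        u, _ = interpolate_velocity(fld, (20.0, 20.0), 0.5, 1.0)
        assert u == pytest.approx(0.5)

    def test_out_of_hull_and_span_rejected(self):
        fld = make_uniform_field(n_hours=3, ny=4, nx=4)
        with pytest.raises(ValueError, match="hull"):
            interpolate_velocity(fld, (1000.0, 20.0), 1.0, 1.0)
        with pytest.raises(ValueError, match="span"):
            interpolate_velocity(fld, (20.0, 20.0), 10.0, 1.0)


class TestRK4:
    def test_constant_field_exact_displacement(self):
        fld = make_uniform_field(u=0.1, v=0.0, n_hours=3, ny=6, nx=6)
        x1, y1 = rk4_step(fld, (20.0, 20.0), 0.0, 3600.0, 1.0)
        # exact up to the float32 representation of 0.1 m/s
        assert x1 - 20.0 == pytest.approx(0.36, rel=1e-7)  # 0.1 m/s × 1 h
        assert y1 == pytest.approx(20.0)

    def test_zero_field_fixed_point(self):
        fld = make_uniform_field(n_hours=3, ny=6, nx=6)
        assert rk4_step(fld, (25.0, 30.0), 0.5, 1800.0, 1.0) == (25.0, 30.0)

    def test_rotation_orbit_closes(self):
        period_s = 50 * 3600.0
        omega = 2 * np.pi / period_s
        fld, (xc, yc) = make_rotation_field(omega, n_hours=60)
        radius = 30.0
        pos = (xc + radius, yc)
        dt = period_s / 100
        t = 0.0
        for _ in range(100):
            pos = rk4_step(fld, pos, t / 3600.0, dt, 1.0)
            t += dt
        err = np.hypot(pos[0] - (xc + radius), pos[1] - yc)
        assert err < 1e-3 * radius

    def test_fourth_order_convergence(self):
        period_s = 50 * 3600.0
        omega = 2 * np.pi / period_s
        fld, (xc, yc) = make_rotation_field(omega, n_hours=60)
        radius = 30.0
        errors = []
        for n_steps in (10, 20, 40, 80):
            pos = (xc + radius, yc)
            dt = period_s / n_steps
            t = 0.0
            for _ in range(n_steps):
                pos = rk4_step(fld, pos, t / 3600.0, dt, 1.0)
                t += dt
            errors.append(np.hypot(pos[0] - (xc + radius), pos[1] - yc))
        rates = [e0 / e1 for e0, e1 in zip(errors, errors[1:])]
        # classical RK4: halving dt cuts the error ~16x
        assert all(r > 8 for r in rates)

    def test_invalid_dt_rejected(self):
        fld = make_uniform_field(n_hours=3, ny=6, nx=6)
        with pytest.raises(ValueError):
            rk4_step(fld, (20.0, 20.0), 0.0, -1.0, 1.0)


class TestTracker:
    def test_uniform_drift_full_pld(self):
        # 0.1 m/s northward for 25 days = exactly 216 km
        fld = make_uniform_field(u=0.0, v=0.1, n_hours=601, ny=24, nx=8)
        sched = manual_schedule([(40.0, 5.0), (20.0, 10.0)])
        res = track_particles(sched, fld)
        assert res.counts == {"released": 2, "settled": 0, "pelagic": 2, "lost": 0}
        y0 = sched.entries["y_km"].to_numpy()
        assert res.y - y0 == pytest.approx(216.0, rel=1e-7)
        assert res.age_days == pytest.approx(PLD_DAYS)

    def test_depth_schedule_changes_advection(self):
        # layer speeds 0.1 / 0.2 / 0.3 m/s: piecewise displacement
        # (0.1·1 + 0.2·19 + 0.3·5) × 86.4 = 466.56 km
        fld = make_uniform_field(
            n_hours=601, ny=4, nx=50, n_layers=3,
            layer_values=[(0.1, 0.0), (0.2, 0.0), (0.3, 0.0)],
        )
        sched = manual_schedule([(5.0, 20.0)])
        res = track_particles(sched, fld)
        assert res.x[0] - 5.0 == pytest.approx(466.56, rel=1e-7)

    def test_boundary_exit_is_lost_and_terminal(self):
        fld = make_uniform_field(u=0.0, v=0.5, n_hours=601, ny=10, nx=8)  # exits north fast
        sched = manual_schedule([(40.0, 50.0)])
        res = track_particles(sched, fld)
        assert res.counts["lost"] == 1
        assert res[0].status == "lost"
        assert res.age_days[0] < PLD_DAYS

    def test_count_conservation_and_determinism(self, small_domain):
        from reefdrift.ocean import SeasonConfig, generate_velocity_field
        fld = generate_velocity_field(small_domain, -10.0, SeasonConfig(n_days=27), seed=4)
        sched = make_release_schedule(small_domain, rate=2, release_days=2, field=fld)
        res1 = track_particles(sched, fld, diffusion_m2s=5.0, seed=42)
        res2 = track_particles(sched, fld, diffusion_m2s=5.0, seed=42)
        c = res1.counts
        assert c["released"] == c["settled"] + c["pelagic"] + c["lost"]
        assert np.array_equal(res1.x, res2.x) and np.array_equal(res1.y, res2.y)
        assert np.array_equal(res1.status, res2.status)

    def test_zero_diffusion_is_seed_independent(self):
        fld = make_uniform_field(u=0.02, v=0.03, n_hours=601, ny=24, nx=8)
        sched = manual_schedule([(20.0, 20.0)])
        a = track_particles(sched, fld, diffusion_m2s=0.0, seed=1)
        b = track_particles(sched, fld, diffusion_m2s=0.0, seed=999)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)

    def test_diffusion_spreads_particles(self):
        fld = make_uniform_field(u=0.001, v=0.001, n_hours=601, ny=24, nx=24, spacing=10.0)
        sched = manual_schedule([(120.0, 120.0)] * 50)
        res = track_particles(sched, fld, diffusion_m2s=2.0, seed=3)
        # random walk std per axis ≈ sqrt(2·K·T) ≈ 2.94 km over 25 d
        spread = np.std(res.x)
        assert 1.0 < spread < 6.0

    def test_stored_trajectories_align_with_final_state(self):
        fld = make_uniform_field(u=0.05, v=0.0, n_hours=601, ny=8, nx=24)
        sched = manual_schedule([(20.0, 30.0)])
        res = track_particles(sched, fld, store_trajectories=True, save_every=2)
        traj = res[0]
        assert traj.positions is not None
        assert traj.positions[0] == pytest.approx([20.0, 30.0])
        assert traj.positions[-1] == pytest.approx([res.x[0], res.y[0]])
        # hourly saves over 25 days
        assert len(traj.positions) == 601

    def test_invalid_dt_rejected(self, small_domain):
        fld = make_uniform_field(n_hours=601)
        sched = manual_schedule([(20.0, 20.0)])
        with pytest.raises(ValueError, match="divisor"):
            track_particles(sched, fld, dt_s=7000.0)
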