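"""Lagrangian particle release and advection.

Particles are released at a constant rate per reef seed cell per day,
advected with a classical fourth-order Runge–Kutta step through the hourly
velocity field (bilinear in space, linear in time), and follow an
age-dependent behavioural depth schedule: day 1 at 1 m, days 2–20 at 3 m,
days 21–25 at 6 m. Tracking stops at the 25-day pelagic larval duration
(PLD), at settlement (first sensory-zone contact at competent age, when a
zone raster is supplied), or when a particle leaves the open boundary
("lost"). Velocities are zero on land and taper to zero near the coast, so
particles stall rather than beach; a step that would land a particle on a
land cell is rejected and the particle stays put.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ocean import Domain, VelocityField

__all__ = [
    "PLD_DAYS",
    "DEPTH_SCHEDULE",
    "STATUS_PELAGIC",
    "STATUS_SETTLED",
    "STATUS_LOST",
    "ReleaseSchedule",
    "make_release_schedule",
    "depth_for_age",
    "interpolate_velocity",
    "rk4_step",
    "Trajectory",
    "TrackingResult",
    "track_particles",
]

PLD_DAYS = 25.0
#: (age_upper_bound_days, depth_m); intervals are [0,1), [1,20), [20,25]
DEPTH_SCHEDULE = ((1.0, 1.0), (20.0, 3.0), (PLD_DAYS, 6.0))

STATUS_PELAGIC = 0
STATUS_SETTLED = 1
STATUS_LOST = 2
_STATUS_NAMES = {STATUS_PELAGIC: "pelagic", STATUS_SETTLED: "settled", STATUS_LOST: "lost"}


def depth_for_age(age: float) -> float:
    """Behavioural depth layer (m) for a larva of the given age (days)."""
    if not 0.0 <= age <= PLD_DAYS:
        raise ValueError(f"age {age} d outside [0, {PLD_DAYS}]")
    for bound, depth in DEPTH_SCHEDULE[:-1]:
        if age < bound:
            return depth
    return DEPTH_SCHEDULE[-1][1]


@dataclass
class ReleaseSchedule:
    """Uniform-rate release plan: ``rate`` particles per seed cell per day.

    ``entries`` has one row per (seed cell, release day): columns
    ``reef_id``, ``region_id``, ``cell_iy``, ``cell_ix``, ``x_km``, ``y_km``,
    ``release_day`` (integer day offset from the field's start),
    ``release_hour`` and ``count``.
    """

    entries: pd.DataFrame
    rate: int
    release_days: np.ndarray  # integer day offsets

    @property
    def n_particles(self) -> int:
        return int(self.entries["count"].sum())

    def region_release_totals(self, domain: Domain) -> pd.Series:
        """Particles released per region_id (zero for silent regions)."""
        totals = self.entries.groupby("region_id")["count"].sum()
        return totals.reindex([r.region_id for r in domain.regions], fill_value=0)

    def expand(self) -> pd.DataFrame:
        """One row per particle (particle_id, reef, region, x, y, release_hour)."""
        reps = self.entries["count"].to_numpy()
        df = self.entries.loc[self.entries.index.repeat(reps)].reset_index(drop=True)
        df.insert(0, "particle_id", np.arange(len(df)))
        return df.drop(columns=["count"])


def make_release_schedule(
    domain: Domain,
    rate: int = 100,
    release_days: int | np.ndarray = 92,
    field: VelocityField | None = None,
    pld_days: float = PLD_DAYS,
) -> ReleaseSchedule:
    """Build the uniform release schedule over the seeding window.

    ``release_days`` is either the number of consecutive daily releases
    starting at the field origin (default 92: October–December) or an
    explicit array of day offsets. Releases happen at 00:00 of each day.
    If ``field`` is given, the window is validated against its coverage:
    every release must fit a full PLD inside the field's time span.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    days = (
        np.arange(int(release_days)) if np.isscalar(release_days) else np.asarray(release_days, int)
    )
    if field is not None and days.size:
        last_needed_h = days.max() * 24 + pld_days * 24
        if last_needed_h > field.time_hours[-1]:
            raise ValueError(
                f"release window needs coverage to hour {last_needed_h:.0f} but the "
                f"velocity field ends at hour {field.time_hours[-1]:.0f}"
            )
    rows = []
    if rate > 0:
        for rf in domain.reefs:
            iy, ix = rf.seed_cell
            for d in days:
                rows.append(
                    (
                        rf.reef_id, rf.region_id, iy, ix,
                        domain.grid_x[ix], domain.grid_y[iy],
                        int(d), int(d) * 24.0, rate,
                    )
                )
    entries = pd.DataFrame(
        rows,
        columns=[
            "reef_id", "region_id", "cell_iy", "cell_ix",
            "x_km", "y_km", "release_day", "release_hour", "count",
        ],
    )
    return ReleaseSchedule(entries=entries, rate=int(rate), release_days=days)


# ---------------------------------------------------------------------------
# Interpolation and RK4
# ---------------------------------------------------------------------------


def _interp_arrays(
    field: VelocityField, x, y, time_h: float, layer: int
):
    """Vectorized bilinear(x,y)+linear(t) interpolation; no bounds checks."""
    gx, gy = field.grid_x, field.grid_y
    dx = gx[1] - gx[0]
    dy = gy[1] - gy[0]
    fx = (x - gx[0]) / dx
    fy = (y - gy[0]) / dy
    ix = np.clip(np.floor(fx).astype(np.int64), 0, gx.size - 2)
    iy = np.clip(np.floor(fy).astype(np.int64), 0, gy.size - 2)
    wx = fx - ix
    wy = fy - iy
    nt = field.time_hours.size
    ft = (time_h - field.time_hours[0]) / 1.0
    it = min(max(int(np.floor(ft)), 0), nt - 2) if nt > 1 else 0
    wt = ft - it if nt > 1 else 0.0
    out = []
    for comp in (field.u, field.v):
        a = comp[it, layer]
        b = comp[it + 1, layer] if nt > 1 else a
        v00 = (1 - wt) * a[iy, ix] + wt * b[iy, ix]
        v01 = (1 - wt) * a[iy, ix + 1] + wt * b[iy, ix + 1]
        v10 = (1 - wt) * a[iy + 1, ix] + wt * b[iy + 1, ix]
        v11 = (1 - wt) * a[iy + 1, ix + 1] + wt * b[iy + 1, ix + 1]
        out.append(
            (1 - wy) * ((1 - wx) * v00 + wx * v01) + wy * ((1 - wx) * v10 + wx * v11)
        )
    return out[0], out[1]


def _interp_layered(field: VelocityField, x, y, time_h: float, layer: np.ndarray):
    """Bilinear+linear-time interpolation with a per-particle layer array.

    Flat-index gather formulation used by the bulk tracker; numerically
    identical to :func:`_interp_arrays` per layer.
    """
    gx, gy = field.grid_x, field.grid_y
    dx = gx[1] - gx[0]
    dy = gy[1] - gy[0]
    nt, nd, ny, nx = field.u.shape
    fx = (x - gx[0]) / dx
    fy = (y - gy[0]) / dy
    ix = np.clip(np.floor(fx).astype(np.int64), 0, nx - 2)
    iy = np.clip(np.floor(fy).astype(np.int64), 0, ny - 2)
    wx = fx - ix
    wy = fy - iy
    ft = time_h - field.time_hours[0]
    it = min(max(int(np.floor(ft)), 0), nt - 2) if nt > 1 else 0
    wt = ft - it if nt > 1 else 0.0
    base0 = ((it * nd + layer) * ny + iy) * nx + ix
    base1 = base0 + nd * ny * nx if nt > 1 else base0
    w00 = (1 - wy) * (1 - wx)
    w01 = (1 - wy) * wx
    w10 = wy * (1 - wx)
    w11 = wy * wx
    out = []
    for comp in (field.u, field.v):
        flat = comp.reshape(-1)
        s0 = (
            w00 * flat[base0]
            + w01 * flat[base0 + 1]
            + w10 * flat[base0 + nx]
            + w11 * flat[base0 + nx + 1]
        )
        if nt > 1 and wt != 0.0:
            s1 = (
                w00 * flat[base1]
                + w01 * flat[base1 + 1]
                + w10 * flat[base1 + nx]
                + w11 * flat[base1 + nx + 1]
            )
            out.append((1 - wt) * s0 + wt * s1)
        else:
            out.append(s0)
    return out[0], out[1]


def interpolate_velocity(
    field: VelocityField,
    position: tuple[float, float],
    time_h: float,
    depth_layer: float,
) -> tuple[float, float]:
    """Sample (u, v) in m s⁻¹ at a point, time (hours) and depth layer.

    Bilinear in (x, y) inside the stored layer, linear in time between hourly
    snapshots; exact at grid nodes and snapshot times. Raises for queries
    outside the grid hull (the rectangle of cell centers) or the time span.
    """
    x, y = position
    gx, gy = field.grid_x, field.grid_y
    if not (gx[0] <= x <= gx[-1] and gy[0] <= y <= gy[-1]):
        raise ValueError(f"position ({x:.2f}, {y:.2f}) km outside the grid hull")
    t0, t1 = field.time_hours[0], field.time_hours[-1]
    if not t0 <= time_h <= t1:
        raise ValueError(f"time {time_h} h outside field span [{t0}, {t1}]")
    layer = field.layer_index(depth_layer)
    u, v = _interp_arrays(field, np.asarray([x]), np.asarray([y]), time_h, layer)
    return float(u[0]), float(v[0])


def rk4_step(
    field: VelocityField,
    position: tuple[float, float],
    time_h: float,
    dt_s: float,
    depth_layer: float,
) -> tuple[float, float]:
    """One classical RK4 advection step; position in km, ``dt_s`` in seconds.

    Stage velocities are sampled with :func:`interpolate_velocity`; the
    m s⁻¹ → km conversion is internal. Raises if any stage falls outside the
    grid hull or time span.
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    x, y = position
    dt_h = dt_s / 3600.0
    k = dt_s / 1000.0  # (m/s) * s -> km
    u1, v1 = interpolate_velocity(field, (x, y), time_h, depth_layer)
    u2, v2 = interpolate_velocity(
        field, (x + 0.5 * k * u1, y + 0.5 * k * v1), time_h + 0.5 * dt_h, depth_layer
    )
    u3, v3 = interpolate_velocity(
        field, (x + 0.5 * k * u2, y + 0.5 * k * v2), time_h + 0.5 * dt_h, depth_layer
    )
    u4, v4 = interpolate_velocity(
        field, (x + k * u3, y + k * v3), time_h + dt_h, depth_layer
    )
    return (
        x + k * (u1 + 2 * u2 + 2 * u3 + u4) / 6.0,
        y + k * (v1 + 2 * v2 + 2 * v3 + v4) / 6.0,
    )


# ---------------------------------------------------------------------------
# Bulk tracker
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Per-particle track summary (positions kept only when requested)."""

    particle_id: int
    reef_id: int
    region_id: int
    release_hour: float
    status: str
    age_days: float
    final_position: tuple[float, float]
    contact_reef_id: int = -1  # first sensory-zone contact, -1 if none
    contact_age_days: float = float("nan")
    times_h: np.ndarray | None = None
    positions: np.ndarray | None = None  # (n_saved, 2) km


@dataclass
class TrackingResult:
    """Structure-of-arrays result of a bulk tracking run.

    Behaves as a sequence of :class:`Trajectory`. ``counts`` satisfies
    released = settled + pelagic + lost.
    """

    particles: pd.DataFrame  # release info per particle
    status: np.ndarray  # int8 codes
    age_days: np.ndarray
    x: np.ndarray
    y: np.ndarray
    contact_reef_id: np.ndarray
    contact_age_days: np.ndarray
    saved_times_h: np.ndarray | None = None
    saved_positions: np.ndarray | None = None  # (n_saved, n, 2)

    def __len__(self) -> int:
        return len(self.particles)

    def __getitem__(self, i: int) -> Trajectory:
        row = self.particles.iloc[i]
        traj = Trajectory(
            particle_id=int(row["particle_id"]),
            reef_id=int(row["reef_id"]),
            region_id=int(row["region_id"]),
            release_hour=float(row["release_hour"]),
            status=_STATUS_NAMES[int(self.status[i])],
            age_days=float(self.age_days[i]),
            final_position=(float(self.x[i]), float(self.y[i])),
            contact_reef_id=int(self.contact_reef_id[i]),
            contact_age_days=float(self.contact_age_days[i]),
        )
        if self.saved_positions is not None:
            pos = self.saved_positions[:, i, :]
            ok = np.isfinite(pos[:, 0])
            traj.times_h = self.saved_times_h[ok]
            traj.positions = pos[ok]
        return traj

    @property
    def counts(self) -> dict[str, int]:
        return {
            "released": len(self),
            "settled": int((self.status == STATUS_SETTLED).sum()),
            "pelagic": int((self.status == STATUS_PELAGIC).sum()),
            "lost": int((self.status == STATUS_LOST).sum()),
        }


def track_particles(
    schedule: ReleaseSchedule,
    field: VelocityField,
    dt_s: float = 1800.0,
    diffusion_m2s: float = 0.0,
    seed: int = 0,
    zone_raster=None,
    competency_start_days: float = 0.0,
    pld_days: float = PLD_DAYS,
    store_trajectories: bool = False,
    save_every: int = 2,
) -> TrackingResult:
    """Advect all scheduled particles through the velocity field.

    A single vectorized time loop advances every active particle with RK4 at
    step ``dt_s`` (default 0.5 h, which must divide the hourly field
    spacing). Optional horizontal diffusion adds an independent Gaussian
    displacement of standard deviation √(2·K·dt) per axis and step. If a
    ``zone_raster`` (from :meth:`reefdrift.biology.SensoryZoneSet.rasterize`)
    is given, particles at age ≥ ``competency_start_days`` settle at their
    first zone contact and stop. Particles whose RK4 stages leave the grid
    hull become "lost"; a particle still unsettled at the PLD stays
    "pelagic". Deterministic for fixed seed; with zero diffusion the seed is
    never consulted.
    """
    if diffusion_m2s < 0:
        raise ValueError("diffusion must be >= 0")
    n_sub = 3600.0 / dt_s
    if abs(n_sub - round(n_sub)) > 1e-9 or dt_s <= 0:
        raise ValueError("dt must be a positive divisor of 1 hour")

    df = schedule.expand()
    n = len(df)
    gx, gy = field.grid_x, field.grid_y
    land = _land_from_field(field)
    dt_h = dt_s / 3600.0
    k_km = dt_s / 1000.0
    pld_h = pld_days * 24.0

    x = df["x_km"].to_numpy(dtype=float).copy()
    y = df["y_km"].to_numpy(dtype=float).copy()
    release_h = df["release_hour"].to_numpy(dtype=float)
    status = np.full(n, STATUS_PELAGIC, dtype=np.int8)
    done = np.zeros(n, dtype=bool)
    contact_reef = np.full(n, -1, dtype=np.int64)
    contact_age = np.full(n, np.nan)
    age_h = np.zeros(n)

    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(3,)))
    depth_bounds_h = np.array([b * 24.0 for b, _ in DEPTH_SCHEDULE])
    n_steps_total = int(round(field.time_hours[-1] / dt_h))

    saved_times = None
    saved_pos = None
    if store_trajectories:
        save_idx = np.arange(0, n_steps_total + 1, save_every)
        saved_times = save_idx * dt_h
        saved_pos = np.full((save_idx.size, n, 2), np.nan)
        save_lookup = {int(s): j for j, s in enumerate(save_idx)}

    def _maybe_save(step: int, mask: np.ndarray) -> None:
        if saved_pos is not None and step in save_lookup:
            j = save_lookup[step]
            saved_pos[j, mask, 0] = x[mask]
            saved_pos[j, mask, 1] = y[mask]

    def _check_contact(idx: np.ndarray, t_h: float) -> None:
        if zone_raster is None or idx.size == 0:
            return
        age = t_h - release_h[idx]
        comp = age >= competency_start_days * 24.0 - 1e-9
        idx = idx[comp]
        if idx.size == 0:
            return
        reef = zone_raster.lookup(x[idx], y[idx])
        hit = reef >= 0
        hidx = idx[hit]
        if hidx.size:
            status[hidx] = STATUS_SETTLED
            done[hidx] = True
            contact_reef[hidx] = reef[hit]
            contact_age[hidx] = (t_h - release_h[hidx]) / 24.0
            age_h[hidx] = t_h - release_h[hidx]

    release_steps = np.rint(release_h / dt_h).astype(np.int64)
    max_layer = min(len(DEPTH_SCHEDULE), field.depths.size) - 1

    for step in range(n_steps_total):
        t_h = step * dt_h
        newly = np.where(release_steps == step)[0]
        if newly.size:
            _maybe_save(step, newly)
            _check_contact(newly, t_h)
        active = np.where(~done & (release_steps <= step))[0]
        if active.size == 0:
            continue
        age = t_h - release_h[active]
        layer = np.searchsorted(depth_bounds_h, age, side="right")
        layer = np.minimum(layer, max_layer)
        x0 = x[active]
        y0 = y[active]
        oob = np.zeros(active.size, dtype=bool)
        sum_u = np.zeros(active.size)
        sum_v = np.zeros(active.size)
        px, py = x0, y0
        for stage, (toff, wgt) in enumerate(
            ((0.0, 1.0), (0.5, 2.0), (0.5, 2.0), (1.0, 1.0))
        ):
            out = (px < gx[0]) | (px > gx[-1]) | (py < gy[0]) | (py > gy[-1])
            oob |= out
            pxc = np.clip(px, gx[0], gx[-1])
            pyc = np.clip(py, gy[0], gy[-1])
            su, sv = _interp_layered(field, pxc, pyc, t_h + toff * dt_h, layer)
            sum_u += wgt * su
            sum_v += wgt * sv
            if stage < 3:
                frac = 0.5 if stage < 2 else 1.0
                px = x0 + frac * k_km * su
                py = y0 + frac * k_km * sv
        xn = x0 + k_km * sum_u / 6.0
        yn = y0 + k_km * sum_v / 6.0
        if diffusion_m2s > 0:
            sd_km = np.sqrt(2.0 * diffusion_m2s * dt_s) / 1000.0
            xn = xn + rng.normal(0.0, sd_km, size=active.size)
            yn = yn + rng.normal(0.0, sd_km, size=active.size)
        out_final = oob | (xn < gx[0]) | (xn > gx[-1]) | (yn < gy[0]) | (yn > gy[-1])
        # land rejection: revert the step if the end point is on a land cell
        ix = np.clip(np.rint((xn - gx[0]) / (gx[1] - gx[0])).astype(np.int64), 0, gx.size - 1)
        iy = np.clip(np.rint((yn - gy[0]) / (gy[1] - gy[0])).astype(np.int64), 0, gy.size - 1)
        on_land = land[iy, ix] & ~out_final
        xn[on_land] = x0[on_land]
        yn[on_land] = y0[on_land]
        x[active] = np.where(out_final, x0, xn)
        y[active] = np.where(out_final, y0, yn)
        lost_idx = active[out_final]
        status[lost_idx] = STATUS_LOST
        done[lost_idx] = True
        age_h[lost_idx] = t_h + dt_h - release_h[lost_idx]
        alive = active[~out_final]
        _maybe_save(step + 1, alive)
        _check_contact(alive, t_h + dt_h)
        expired = alive[(t_h + dt_h - release_h[alive]) >= pld_h - 1e-9]
        exp_mask = ~done[expired]
        age_h[expired[exp_mask]] = pld_h
        done[expired] = True

    age_h[~done & (status == STATUS_PELAGIC)] = np.minimum(
        np.maximum(n_steps_total * dt_h - release_h[~done & (status == STATUS_PELAGIC)], 0.0),
        pld_h,
    )
    return TrackingResult(
        particles=df,
        status=status,
        age_days=age_h / 24.0,
        x=x,
        y=y,
        contact_reef_id=contact_reef,
        contact_age_days=contact_age,
        saved_times_h=saved_times,
        saved_positions=saved_pos,
    )


def _land_from_field(field: VelocityField) -> np.ndarray:
    """Infer the land mask as cells with identically zero currents at all times."""
    speed = np.abs(field.u).max(axis=(0, 1)) + np.abs(field.v).max(axis=(0, 1))
    return speed == 0.0
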