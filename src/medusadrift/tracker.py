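"""Lagrangian advection-diffusion particle tracking with windage.

Particles are advected by the space-time-interpolated current field plus a
leeway term (a fixed fraction of the wind vector, 4 per mille by default),
integrated with a Runge-Kutta scheme for the deterministic part, and
dispersed by an uncorrelated random walk with per-axis increments of
standard deviation sqrt(2 K dt) (Euler-Maruyama).  Transport is purely
horizontal.

Terminal events: geometric coastline contact (stranding), crossing an exit
gate after having entered the strait, or crossing the outer open boundary
(left_domain).  Positions are recorded at a fixed output cadence (hourly
by default), which is also the cadence at which strait entries are
detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import ConfigurationError, ReleaseSchedule, TrackerConfig
from .flowfield import FlowField, WindSeries
from .geometry import DomainGeometry

STATUS_ACTIVE = 0
STATUS_STRANDED = 1
STATUS_EXITED_TYRRHENIAN = 2
STATUS_EXITED_IONIAN = 3
STATUS_LEFT_DOMAIN = 4
STATUS_NAMES = {
    STATUS_ACTIVE: "active",
    STATUS_STRANDED: "stranded",
    STATUS_EXITED_TYRRHENIAN: "exited_tyrrhenian",
    STATUS_EXITED_IONIAN: "exited_ionian",
    STATUS_LEFT_DOMAIN: "left_domain",
}


def _velocity(px, py, t, flow: FlowField, wind: Optional[WindSeries], alpha):
    u, v = flow.sample(px, py, t)
    if wind is not None and alpha > 0:
        wu, wv = wind.sample(t)
        u = u + alpha * wu
        v = v + alpha * wv
    return u, v


def _advect(px, py, t, dt, flow, wind, config: TrackerConfig):
    """One deterministic integration step (euler / rk2 / rk4)."""
    a = config.windage_alpha
    if config.integrator == "euler":
        u, v = _velocity(px, py, t, flow, wind, a)
        return px + u * dt, py + v * dt
    if config.integrator == "rk2":
        u1, v1 = _velocity(px, py, t, flow, wind, a)
        u2, v2 = _velocity(px + u1 * dt, py + v1 * dt, t + dt, flow, wind, a)
        return px + 0.5 * (u1 + u2) * dt, py + 0.5 * (v1 + v2) * dt
    u1, v1 = _velocity(px, py, t, flow, wind, a)
    u2, v2 = _velocity(px + 0.5 * u1 * dt, py + 0.5 * v1 * dt,
                       t + 0.5 * dt, flow, wind, a)
    u3, v3 = _velocity(px + 0.5 * u2 * dt, py + 0.5 * v2 * dt,
                       t + 0.5 * dt, flow, wind, a)
    u4, v4 = _velocity(px + u3 * dt, py + v3 * dt, t + dt, flow, wind, a)
    return (px + dt / 6.0 * (u1 + 2 * u2 + 2 * u3 + u4),
            py + dt / 6.0 * (v1 + 2 * v2 + 2 * v3 + v4))


def step(position, time, flow: FlowField, wind: Optional[WindSeries],
         config: TrackerConfig, rng: Optional[np.random.Generator] = None):
    """Advance one or many particle positions by one time step.

    ``position`` is ``(2,)`` or ``(n, 2)``.  The deterministic displacement
    is the integral of current + windage velocity over ``dt``; if the
    diffusivity is positive and ``rng`` is given, independent per-axis
    Gaussian increments of std ``sqrt(2 K dt)`` are added.
    """
    pos = np.asarray(position, dtype=float)
    single = pos.ndim == 1
    pos = np.atleast_2d(pos)
    px, py = pos[:, 0], pos[:, 1]
    u, v = flow.sample(px, py, time)  # also validates time coverage
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise ValueError("NaN velocity sampled at a water point")
    flow._check_time(time + config.dt)
    nx, ny = _advect(px, py, time, config.dt, flow, wind, config)
    if config.diffusivity > 0 and rng is not None:
        sigma = np.sqrt(2.0 * config.diffusivity * config.dt)
        nx = nx + rng.normal(0.0, sigma, size=nx.shape)
        ny = ny + rng.normal(0.0, sigma, size=ny.shape)
    out = np.column_stack([nx, ny])
    return out[0] if single else out


def seed_uniform(region, n: int, rng: np.random.Generator,
                 domain: Optional[DomainGeometry] = None) -> np.ndarray:
    """Uniform random positions in the water part of a region.

    Rejection sampling over the region's bounding box; points on land (when
    a domain is supplied) are rejected, so the accepted density is uniform
    over region-intersect-water.
    """
    minx, miny, maxx, maxy = region.bounds
    if maxx <= minx or maxy <= miny:
        raise ValueError("region has empty extent")
    import shapely
    out = np.empty((n, 2))
    got = 0
    attempts = 0
    while got < n:
        m = max(4 * (n - got), 128)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        ok = shapely.intersects_xy(region, xs, ys)
        if domain is not None:
            ok &= ~domain.on_land(xs, ys)
        xs, ys = xs[ok], ys[ok]
        take = min(len(xs), n - got)
        out[got:got + take, 0] = xs[:take]
        out[got:got + take, 1] = ys[:take]
        got += take
        attempts += 1
        if attempts > 200 and got == 0:
            raise ValueError("region has no water area to seed")
    return out


@dataclass
class ParticleTrajectory:
    """Per-particle view into a :class:`TrajectorySet`."""

    particle_id: int
    source_position: np.ndarray
    release_time: float
    status: str
    status_time: float  # nan while active
    first_strait_entry_age: float  # seconds, nan if never entered
    stranding_segment_id: Optional[str]
    times: np.ndarray  # output times at which the particle was in the water
    positions: np.ndarray  # (k, 2), empty if positions were not stored


@dataclass
class TrajectorySet:
    """Column-oriented trajectories of one experiment run."""

    release_time: np.ndarray  # (n,)
    source_position: np.ndarray  # (n, 2)
    status: np.ndarray  # (n,) int codes
    status_time: np.ndarray  # (n,) seconds, nan while active
    first_entry_time: np.ndarray  # (n,) seconds, nan if never entered
    stranding_segment: np.ndarray  # (n,) object: segment id or None
    final_position: np.ndarray  # (n, 2)
    output_times: np.ndarray  # (m,)
    in_strait: np.ndarray  # (m, n) bool, False before release/after exit
    positions: Optional[np.ndarray] = None  # (m, n, 2) float32, NaN when absent
    duration: float = 0.0

    @property
    def n_particles(self) -> int:
        return len(self.release_time)

    @property
    def first_entry_age(self) -> np.ndarray:
        return self.first_entry_time - self.release_time

    def status_names(self) -> np.ndarray:
        return np.array([STATUS_NAMES[s] for s in self.status])

    def counts_at(self, t: float) -> dict:
        """Particle accounting at an output time (released = sum of states)."""
        released = self.release_time <= t + 1e-9
        terminal = released & np.isfinite(self.status_time) \
            & (self.status_time <= t + 1e-9)
        out = {"released": int(released.sum()),
               "active": int((released & ~terminal).sum())}
        for code, name in STATUS_NAMES.items():
            if code == STATUS_ACTIVE:
                continue
            out[name] = int((terminal & (self.status == code)).sum())
        return out

    def particles(self):
        for i in range(self.n_particles):
            if self.positions is not None:
                valid = np.isfinite(self.positions[:, i, 0])
                times = self.output_times[valid]
                pos = self.positions[valid, i, :].astype(float)
            else:
                times = np.empty(0)
                pos = np.empty((0, 2))
            yield ParticleTrajectory(
                particle_id=i,
                source_position=self.source_position[i],
                release_time=float(self.release_time[i]),
                status=STATUS_NAMES[int(self.status[i])],
                status_time=float(self.status_time[i]),
                first_strait_entry_age=float(self.first_entry_time[i]
                                             - self.release_time[i]),
                stranding_segment_id=self.stranding_segment[i],
                times=times, positions=pos)

    def save(self, path) -> None:
        """Persist to a compressed .npz archive."""
        seg = np.array(["" if s is None else s for s in self.stranding_segment])
        np.savez_compressed(
            path, release_time=self.release_time,
            source_position=self.source_position, status=self.status,
            status_time=self.status_time, first_entry_time=self.first_entry_time,
            stranding_segment=seg, final_position=self.final_position,
            output_times=self.output_times, in_strait=self.in_strait,
            positions=(np.empty(0, dtype=np.float32) if self.positions is None
                       else self.positions),
            duration=np.array(self.duration))

    @classmethod
    def load(cls, path) -> "TrajectorySet":
        with np.load(path, allow_pickle=False) as z:
            seg = np.array([None if s == "" else str(s)
                            for s in z["stranding_segment"]], dtype=object)
            positions = z["positions"]
            return cls(
                release_time=z["release_time"],
                source_position=z["source_position"], status=z["status"],
                status_time=z["status_time"],
                first_entry_time=z["first_entry_time"], stranding_segment=seg,
                final_position=z["final_position"],
                output_times=z["output_times"], in_strait=z["in_strait"],
                positions=None if positions.size == 0 else positions,
                duration=float(z["duration"]))

    def terminal_events_frame(self) -> pd.DataFrame:
        """Terminal events table (particle_id, status, time, x, y, segment)."""
        idx = np.flatnonzero(self.status != STATUS_ACTIVE)
        return pd.DataFrame({
            "particle_id": idx,
            "status": [STATUS_NAMES[int(s)] for s in self.status[idx]],
            "time": self.status_time[idx],
            "x": self.final_position[idx, 0],
            "y": self.final_position[idx, 1],
            "segment_id": [self.stranding_segment[i] for i in idx],
        })


def run_experiment(flow: FlowField, wind: Optional[WindSeries],
                   domain: DomainGeometry, schedule: ReleaseSchedule,
                   config: TrackerConfig, duration: float) -> TrajectorySet:
    """Release particles on a schedule and track them for ``duration`` seconds.

    Every released particle ends the run with exactly one terminal status
    or remains active; hourly (``output_interval``) positions and strait
    membership are recorded.  Strait entries are detected at the output
    cadence (matching an hourly-positions analysis); exit-gate and open-
    boundary crossings are checked every time step.
    """
    if wind is None:
        wind = WindSeries.calm(duration)
    dt = config.dt
    n_steps = int(round(duration / dt))
    steps_per_out = int(round(config.output_interval / dt))
    out_steps = np.arange(0, n_steps + 1, steps_per_out)
    output_times = out_steps * dt

    seq = np.random.SeedSequence(config.rng_seed)
    seed_rng, diff_rng = (np.random.default_rng(s) for s in seq.spawn(2))

    release_times = schedule.release_times()
    if len(release_times) == 0:
        raise ConfigurationError("schedule produces no releases")
    release_steps = np.round(release_times / dt).astype(int)
    ppr = schedule.particles_per_release
    n_total = len(release_times) * ppr

    # seed all cohorts up front (deterministic order)
    source = np.empty((n_total, 2))
    release_time_arr = np.empty(n_total)
    for k, (rt, rstep) in enumerate(zip(release_times, release_steps)):
        sl = slice(k * ppr, (k + 1) * ppr)
        source[sl] = seed_uniform(schedule.region, ppr, seed_rng, domain)
        release_time_arr[sl] = rstep * dt
    order = np.argsort(release_time_arr, kind="stable")
    source = source[order]
    release_time_arr = release_time_arr[order]
    release_step_arr = np.round(release_time_arr / dt).astype(int)

    pos = np.full((n_total, 2), np.nan)
    status = np.zeros(n_total, dtype=np.int8)
    status_time = np.full(n_total, np.nan)
    first_entry = np.full(n_total, np.nan)
    strand_seg = np.full(n_total, None, dtype=object)
    released = np.zeros(n_total, dtype=bool)
    entered = np.zeros(n_total, dtype=bool)

    n_out = len(output_times)
    in_strait_rec = np.zeros((n_out, n_total), dtype=bool)
    pos_rec = (np.full((n_out, n_total, 2), np.nan, dtype=np.float32)
               if config.store_positions else None)

    # cheap land prefilter: dilated land mask on the forcing grid
    land_any = flow.land_mask.any()
    if land_any:
        dil = ndimage.binary_dilation(flow.land_mask, iterations=3)
        gx0, gdx = flow.x_coords[0], flow.x_coords[1] - flow.x_coords[0]
        gy0, gdy = flow.y_coords[0], flow.y_coords[1] - flow.y_coords[0]
        nyg, nxg = dil.shape

        def land_candidates(xs, ys):
            ix = np.clip(np.round((xs - gx0) / gdx).astype(int), 0, nxg - 1)
            iy = np.clip(np.round((ys - gy0) / gdy).astype(int), 0, nyg - 1)
            return dil[iy, ix]
    else:
        have_land = len(domain.land_polygons) > 0

        def land_candidates(xs, ys):
            return (domain.on_land(xs, ys) if have_land
                    else np.zeros(len(xs), dtype=bool))

    bx0, by0, bx1, by1 = domain.open_boundary.bounds
    gates = []
    for label, (gate, normal) in domain.exit_gates.items():
        code = (STATUS_EXITED_TYRRHENIAN if label.startswith("tyrrhenian")
                else STATUS_EXITED_IONIAN)
        gates.append((code, gate.coords[0], normal))

    sigma = np.sqrt(2.0 * config.diffusivity * dt) if config.diffusivity > 0 else 0.0
    absorb = config.land_interaction == "absorb"
    rel_ptr = 0  # next particle to release (release times are sorted)

    def record(oi, t):
        act = released & (status == STATUS_ACTIVE)
        if act.any():
            xs, ys = pos[act, 0], pos[act, 1]
            ins = domain.in_strait(xs, ys)
            in_strait_rec[oi, act] = ins
            idx = np.flatnonzero(act)
            newly = idx[ins & ~entered[idx]]
            entered[newly] = True
            first_entry[newly] = t
            if pos_rec is not None:
                pos_rec[oi, act] = pos[act]

    def do_releases(istep):
        nonlocal rel_ptr
        while rel_ptr < n_total and release_step_arr[rel_ptr] == istep:
            j = rel_ptr
            while j < n_total and release_step_arr[j] == istep:
                j += 1
            pos[rel_ptr:j] = source[rel_ptr:j]
            released[rel_ptr:j] = True
            rel_ptr = j

    do_releases(0)  # releases at t = 0 are visible in the first snapshot
    record(0, 0.0)
    oi = 1
    for istep in range(n_steps):
        t = istep * dt
        do_releases(istep)
        act = np.flatnonzero(released & (status == STATUS_ACTIVE))
        if len(act):
            px, py = pos[act, 0], pos[act, 1]
            nx, ny = _advect(px, py, t, dt, flow, wind, config)
            if sigma > 0:
                nx = nx + diff_rng.normal(0.0, sigma, size=len(act))
                ny = ny + diff_rng.normal(0.0, sigma, size=len(act))
            if not (np.all(np.isfinite(nx)) and np.all(np.isfinite(ny))):
                raise ValueError("NaN velocity sampled at a water point")
            t_new = t + dt

            # stranding: geometric contact along the displacement segment
            cand = np.flatnonzero(land_candidates(nx, ny))
            for c in cand:
                i = act[c]
                hit = domain.detect_stranding((px[c], py[c]), (nx[c], ny[c]))
                if hit is None:
                    continue
                label, segment, contact = hit
                if absorb:
                    status[i] = STATUS_STRANDED
                    status_time[i] = t_new
                    strand_seg[i] = segment.id if segment is not None else None
                    nx[c], ny[c] = contact
                else:  # reflect: reject the move
                    nx[c], ny[c] = px[c], py[c]
            pos[act, 0] = nx
            pos[act, 1] = ny

            live = status[act] == STATUS_ACTIVE
            # exit gates apply only to particles that have entered the strait
            ent = act[live & entered[act]]
            if len(ent):
                exited = np.zeros(len(ent), dtype=bool)
                for code, (gx, gy), (nrx, nry) in gates:
                    side = ((pos[ent, 0] - gx) * nrx
                            + (pos[ent, 1] - gy) * nry) > 0
                    hitm = side & ~exited
                    status[ent[hitm]] = code
                    status_time[ent[hitm]] = t_new
                    exited |= side
            # open boundary
            live_idx = act[status[act] == STATUS_ACTIVE]
            if len(live_idx):
                outb = ((pos[live_idx, 0] < bx0) | (pos[live_idx, 0] > bx1)
                        | (pos[live_idx, 1] < by0) | (pos[live_idx, 1] > by1))
                gone = live_idx[outb]
                status[gone] = STATUS_LEFT_DOMAIN
                status_time[gone] = t_new

        if oi < n_out and istep + 1 == out_steps[oi]:
            record(oi, output_times[oi])
            oi += 1

    return TrajectorySet(
        release_time=release_time_arr, source_position=source,
        status=status, status_time=status_time, first_entry_time=first_entry,
        stranding_segment=strand_seg, final_position=pos.copy(),
        output_times=output_times, in_strait=in_strait_rec,
        positions=pos_rec, duration=duration)
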