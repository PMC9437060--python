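"""Configuration objects for forcing generation, particle tracking and runs.

All lengths are metres, times seconds, speeds m s^-1, on a local flat
Cartesian plane (the idealized domain is order 100 km across, so no
geographic projection is used).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import yaml

M2_PERIOD = 44_712.0  # semi-diurnal (M2) tidal period, seconds

#: Compass sectors used for the wind-direction categorical draw ("from"
#: bearings, degrees clockwise from north).
WIND_SECTORS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")
WIND_BEARINGS = {s: 45.0 * i for i, s in enumerate(WIND_SECTORS)}

#: Monthly prevalence of north-westerly winds (Jan..Dec).  Anchored to the
#: observed regime: ~50% of the year overall, peaking in May (95%) and June
#: (80%) and dropping to 8% in October; the remaining probability is split
#: evenly across the other seven sectors.
DEFAULT_NW_PREVALENCE = (
    0.55, 0.60, 0.65, 0.75, 0.95, 0.80, 0.40, 0.35, 0.25, 0.08, 0.30, 0.45,
)


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


def nw_prevalence_table(nw_by_month: Sequence[float]) -> np.ndarray:
    """Build a (12, 8) monthly direction-prevalence table from NW shares.

    Row ``m`` gives the probability of each sector in ``WIND_SECTORS`` for
    month ``m+1``; the non-NW remainder is spread uniformly.
    """
    nw = np.asarray(nw_by_month, dtype=float)
    if nw.shape != (12,) or np.any(nw < 0) or np.any(nw > 1):
        raise ConfigurationError("NW prevalence must be 12 values in [0, 1]")
    table = np.empty((12, 8))
    table[:] = ((1.0 - nw) / 7.0)[:, None]
    table[:, WIND_SECTORS.index("NW")] = nw
    return table


@dataclass
class FlowConfig:
    """Parameters of the idealized strait + basin forcing.

    Defaults emulate the target regime: semi-diurnal tidal currents
    exceeding 2 m s^-1 at peak over the sill, residual through-flow of
    0.2-0.3 m s^-1 with an anticyclonic recirculation cell just north of
    the sill, and a weak (5-10 cm s^-1) drift in the western basin around
    the island obstacles.
    """

    tidal_period: float = M2_PERIOD
    tidal_peak_speed: float = 2.2
    residual_speed: float = 0.25
    basin_speed: float = 0.08

    # Anticyclonic (clockwise) recirculation cell north of the sill.
    eddy_center: tuple[float, float] = (62_000.0, 24_000.0)
    eddy_radius: float = 1_500.0
    eddy_peak_speed: Optional[float] = None  # default: residual_speed / 2

    # Geometry of the idealized domain (see synthetic.make_idealized_domain).
    domain_size: tuple[float, float] = (80_000.0, 60_000.0)
    channel_x: tuple[float, float] = (60_000.0, 64_000.0)
    channel_top_y: float = 40_000.0
    sill_y: float = 20_000.0
    gate_y: tuple[float, float] = (6_000.0, 34_000.0)  # (ionian, tyrrhenian)
    tidal_sigma_y: float = 5_000.0
    tidal_sigma_x: float = 2_000.0

    grid_spacing: float = 500.0
    snapshot_interval: float = 3_600.0

    # Wind: per-interval categorical direction draw + Rayleigh speeds.
    wind_nw_prevalence: Sequence[float] = DEFAULT_NW_PREVALENCE
    wind_direction_table: Optional[np.ndarray] = None  # (12, 8) overrides
    wind_speed_scale: float = 4.5  # Rayleigh scale, m s^-1 (mean ~5.6)
    wind_interval: float = 10_800.0

    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tidal_peak_speed", "residual_speed", "basin_speed",
                     "wind_speed_scale"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.tidal_period <= 0:
            raise ConfigurationError("tidal_period must be > 0")
        if self.grid_spacing <= 0:
            raise ConfigurationError("grid_spacing must be > 0")
        if self.eddy_radius <= 0:
            raise ConfigurationError("eddy_radius must be > 0")
        if self.wind_interval <= 0:
            raise ConfigurationError("wind_interval must be > 0")

    @property
    def eddy_speed(self) -> float:
        return (self.residual_speed / 2.0 if self.eddy_peak_speed is None
                else self.eddy_peak_speed)

    @property
    def channel_width(self) -> float:
        return self.channel_x[1] - self.channel_x[0]

    def direction_table(self) -> np.ndarray:
        if self.wind_direction_table is not None:
            table = np.asarray(self.wind_direction_table, dtype=float)
            if table.shape != (12, 8):
                raise ConfigurationError("wind_direction_table must be (12, 8)")
            if not np.allclose(table.sum(axis=1), 1.0, atol=1e-9):
                raise ConfigurationError(
                    "wind direction prevalence rows must each sum to 1")
            return table
        return nw_prevalence_table(self.wind_nw_prevalence)


@dataclass
class TrackerConfig:
    """Numerical parameters of the advection-diffusion particle tracker."""

    dt: float = 300.0
    windage_alpha: float = 0.004  # leeway: 4 per mille of wind speed
    diffusivity: float = 5.0  # horizontal eddy diffusivity K, m^2 s^-1
    integrator: str = "rk4"  # euler | rk2 | rk4 (deterministic part)
    output_interval: float = 3_600.0
    rng_seed: int = 0
    land_interaction: str = "absorb"  # absorb | reflect
    store_positions: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if not 0.0 <= self.windage_alpha <= 1.0:
            raise ConfigurationError("windage_alpha must be in [0, 1]")
        if self.diffusivity < 0:
            raise ConfigurationError("diffusivity must be >= 0")
        if self.integrator not in ("euler", "rk2", "rk4"):
            raise ConfigurationError(f"unknown integrator {self.integrator!r}")
        if self.land_interaction not in ("absorb", "reflect"):
            raise ConfigurationError(
                f"unknown land_interaction {self.land_interaction!r}")
        ratio = self.output_interval / self.dt
        if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
            raise ConfigurationError("output_interval must be a multiple of dt")


@dataclass
class ReleaseSchedule:
    """Repeated uniform releases of particles within a region.

    The default cadence is semi-diurnal (one pulse per M2 period),
    matching the seeding frequency of the connectivity experiments.
    """

    region: object  # shapely polygon
    start_time: float
    end_time: float
    particles_per_release: int
    release_interval: float = M2_PERIOD
    spatial_law: str = "uniform"

    def __post_init__(self) -> None:
        if not self.start_time < self.end_time:
            raise ConfigurationError("start_time must be < end_time")
        if self.particles_per_release < 1:
            raise ConfigurationError("particles_per_release must be >= 1")
        if self.release_interval <= 0:
            raise ConfigurationError("release_interval must be > 0")
        if self.spatial_law != "uniform":
            raise ConfigurationError("only uniform spatial seeding is supported")

    def release_times(self) -> np.ndarray:
        """Pulse times: start, start + interval, ... strictly before end."""
        n = int(np.floor((self.end_time - self.start_time)
                         / self.release_interval)) + 1
        times = self.start_time + self.release_interval * np.arange(n)
        return times[times < self.end_time]

    @property
    def total_particles(self) -> int:
        return len(self.release_times()) * self.particles_per_release


def config_to_yaml(cfg) -> str:
    d = asdict(cfg)
    d.pop("region", None)
    for k, v in list(d.items()):
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
    return yaml.safe_dump({type(cfg).__name__: d}, sort_keys=True)


def flow_config_from_yaml(text: str) -> FlowConfig:
    d = yaml.safe_load(text)
    d = d.get("FlowConfig", d)
    for key in ("domain_size", "channel_x", "gate_y", "eddy_center"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return FlowConfig(**d)


def tracker_config_from_yaml(text: str) -> TrackerConfig:
    d = yaml.safe_load(text)
    return TrackerConfig(**d.get("TrackerConfig", d))
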