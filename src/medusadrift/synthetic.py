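"""Idealized forcing: domain, strait/basin currents, wind, analytic fields.

The generator abstracts the study region into a flat rectangular seascape:
a western basin holding a small volcanic archipelago (the spawning
grounds), two mainland blocks whose facing walls form a narrow north-south
tidal channel, and two cross-channel gates bounding the strait proper.
The current field is the sum of

* a weak basin drift funnelling water toward the channel mouth,
* a residual through-flow along the channel with an anticyclonic
  (clockwise) recirculation cell just north of the sill, and
* a semi-diurnal along-channel tidal oscillation whose amplitude peaks
  over the sill and decays away from it.

Wind is spatially uniform, drawn per interval from a monthly direction
prevalence table (north-westerlies dominating in late spring) with
Rayleigh-distributed speeds.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import LineString, Polygon, box

from .config import (ConfigurationError, FlowConfig, WIND_BEARINGS,
                     WIND_SECTORS)
from .flowfield import FlowField, GriddedFlowField, HarmonicFlowField, WindSeries
from .geometry import DomainGeometry, segment_coastline
from .timeutil import month_of_time

#: Island obstacles in the western basin: name -> (centre, radius in m).
DEFAULT_ISLANDS = {
    "lipari": ((14_000.0, 46_000.0), 2_000.0),
    "salina": ((20_000.0, 51_000.0), 1_800.0),
    "vulcano": ((26_000.0, 44_000.0), 1_600.0),
    "panarea": ((30_000.0, 52_000.0), 1_200.0),
}

SEGMENT_LENGTH = 5_000.0  # coastal stranding bins, m


def grid_axes(config: FlowConfig):
    """Cell-centre axes of the forcing grid."""
    lx, ly = config.domain_size
    h = config.grid_spacing
    x = np.arange(h / 2, lx, h)
    y = np.arange(h / 2, ly, h)
    return x, y


def make_idealized_domain(config: FlowConfig, islands=None) -> tuple:
    """Build the idealized coastline and named regions.

    Returns ``(DomainGeometry, (x_axis, y_axis))``.  Raises
    :class:`ConfigurationError` on degenerate geometry (e.g. a channel
    narrower than two grid cells or islands outside the basin).
    """
    lx, ly = config.domain_size
    cx0, cx1 = config.channel_x
    top = config.channel_top_y
    if config.channel_width <= 2 * config.grid_spacing:
        raise ConfigurationError("channel width must exceed two grid cells")
    if not (0 < cx0 < cx1 < lx) or not (0 < top < ly):
        raise ConfigurationError("channel must lie strictly inside the domain")
    gy_ion, gy_tyr = config.gate_y
    if not (0 < gy_ion < gy_tyr < top):
        raise ConfigurationError("gates must be ordered inside the channel")

    sicily_west = 48_000.0 if lx >= 60_000 else 0.6 * lx
    land = {
        "sicily_side": box(sicily_west, 0.0, cx0, top),
        "calabria_side": box(cx1, 0.0, lx, top),
    }
    if islands is None:
        islands = DEFAULT_ISLANDS
    basin = box(0.0, 0.0, sicily_west, ly)
    for name, (centre, radius) in islands.items():
        poly = Polygon(_circle(centre, radius))
        if not basin.contains(poly):
            raise ConfigurationError(f"island {name!r} must lie inside the basin")
        land[f"island:{name}"] = poly

    spawning = box(5_000.0, 36_000.0, 35_000.0, 56_000.0)
    strait = box(cx0, gy_ion, cx1, gy_tyr)
    gates = {
        "tyrrhenian_gate": (LineString([(cx0, gy_tyr), (cx1, gy_tyr)]), (0.0, 1.0)),
        "ionian_gate": (LineString([(cx0, gy_ion), (cx1, gy_ion)]), (0.0, -1.0)),
    }

    segments = []
    # Sicilian coast: west wall up, across the top, down the strait wall
    # (ids run clockwise when north is up).
    sic = np.array([[sicily_west, 0.0], [sicily_west, top],
                    [cx0, top], [cx0, 0.0]])
    segments += segment_coastline(sic, SEGMENT_LENGTH, coast="sicily_side",
                                  id_prefix="Sic")
    # Calabrian coast: up the strait wall then east along the top
    # (counter-clockwise ids).
    cal = np.array([[cx1, 0.0], [cx1, top], [lx, top]])
    segments += segment_coastline(cal, SEGMENT_LENGTH, coast="calabria_side",
                                  id_prefix="Cal")
    for name, (centre, radius) in islands.items():
        ring = _circle(centre, radius)
        segments += segment_coastline(
            np.vstack([ring, ring[:1]]), SEGMENT_LENGTH,
            coast=f"island:{name}", id_prefix=f"{name.capitalize()}")

    domain = DomainGeometry(
        land_polygons=land, spawning_region=spawning, strait_region=strait,
        exit_gates=gates, open_boundary=box(0.0, 0.0, lx, ly),
        segments=segments)
    return domain, grid_axes(config)


def _circle(centre, radius, n=48):
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([centre[0] + radius * np.cos(theta),
                            centre[1] + radius * np.sin(theta)])


def make_strait_field(config: FlowConfig, domain: DomainGeometry,
                      duration: float,
                      include_residual: bool = True,
                      include_tide: bool = True,
                      include_eddy: bool = True) -> HarmonicFlowField:
    """Residual + tidal forcing over the idealized domain.

    The flags switch individual components off (e.g. a tidal-only regime
    for retention comparisons).  ``duration`` must cover at least one
    tidal period.
    """
    if duration < config.tidal_period:
        raise ConfigurationError("duration must cover at least one tidal period")
    x, y = grid_axes(config)
    xx, yy = np.meshgrid(x, y)
    mask = domain.land_mask(x, y)

    cx0, cx1 = config.channel_x
    cxm = 0.5 * (cx0 + cx1)
    half_w = 0.5 * config.channel_width
    top = config.channel_top_y

    # channel proximity weight: 1 inside the channel, smooth Gaussian decay
    # outside its x-range and above its mouth
    dx_out = np.maximum(np.abs(xx - cxm) - half_w, 0.0)
    # through-flow weight: zero outside the channel walls (so along-wall
    # basin flow rounds the mouth corners), ramping up 1 km inside them
    gx = (np.clip((xx - cx0) / 1_000.0, 0.0, 1.0)
          * np.clip((cx1 - xx) / 1_000.0, 0.0, 1.0))
    dy_out = np.maximum(yy - top, 0.0)
    gy = np.exp(-dy_out**2 / (2 * 5_000.0**2))
    w_channel = gx * gy

    ru = np.zeros_like(xx)
    rv = np.zeros_like(xx)
    if include_residual:
        # basin drift toward a focus just north of the channel mouth
        focus = (cxm, top + 4_000.0)
        dxf = focus[0] - xx
        dyf = focus[1] - yy
        r = np.hypot(dxf, dyf)
        r = np.where(r < 1.0, 1.0, r)
        taper = np.clip(r / 4_000.0, 0.0, 1.0)  # stall smoothly at the focus
        bu = config.basin_speed * dxf / r * taper
        bv = config.basin_speed * dyf / r * taper
        # coastal boundary current: the mean drift has no onshore component
        # at the mainland top wall, so coastal losses there are driven by
        # wind and diffusion fluctuations, not by the mean flow
        near_wall = np.exp(-np.maximum(yy - top, 0.0)**2 / (2 * 2_500.0**2))
        near_wall = np.where(yy >= top, near_wall, 0.0)
        lift = config.basin_speed * near_wall * (1 - w_channel)
        bv = np.maximum(bv, 0.0) * near_wall + bv * (1 - near_wall) + lift
        # southward through-flow in the channel
        ru = (1 - w_channel) * bu
        rv = (1 - w_channel) * bv + w_channel * (-config.residual_speed)
        if include_eddy and config.eddy_speed > 0:
            ex, ey = config.eddy_center
            dxe = xx - ex
            dye = yy - ey
            re = np.hypot(dxe, dye)
            re_safe = np.where(re < 1.0, 1.0, re)
            # Lamb-Oseen-style profile peaking at the eddy radius
            rr = re_safe / config.eddy_radius
            vt = config.eddy_speed * rr * np.exp(0.5 * (1.0 - rr**2))
            # clockwise (anticyclonic) rotation
            ru = ru + vt * dye / re_safe
            rv = rv - vt * dxe / re_safe

    au = np.zeros_like(xx)
    av = np.zeros_like(xx)
    if include_tide and config.tidal_peak_speed > 0:
        hx = np.exp(-dx_out**2 / (2 * config.tidal_sigma_x**2))
        hy = np.exp(-(yy - config.sill_y)**2 / (2 * config.tidal_sigma_y**2))
        av = config.tidal_peak_speed * hx * hy

    omega = 2 * np.pi / config.tidal_period
    return HarmonicFlowField(x, y, residual_u=ru, residual_v=rv,
                             amp_u=au, amp_v=av, omega=omega,
                             duration=duration, land_mask=mask)


def make_wind_series(config: FlowConfig, duration: float,
                     rng=None) -> WindSeries:
    """Per-interval wind draws from the monthly direction prevalence table.

    Direction is a categorical draw over eight compass sectors ("from"
    convention: a NW wind blows toward the south-east); speed is Rayleigh
    with scale ``wind_speed_scale``.  Reproducible for a fixed seed.
    """
    table = config.direction_table()  # validates rows
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    times = np.arange(0.0, duration, config.wind_interval)
    if len(times) < 2:
        times = np.array([0.0, duration])
    months = month_of_time(times) - 1
    n = len(times)
    u = np.empty(n)
    v = np.empty(n)
    speeds = rng.rayleigh(scale=config.wind_speed_scale, size=n) \
        if config.wind_speed_scale > 0 else np.zeros(n)
    uniforms = rng.random(n)
    cdf = np.cumsum(table, axis=1)
    sector_idx = np.empty(n, dtype=int)
    for m in range(12):
        sel = months == m
        if not sel.any():
            continue
        sector_idx[sel] = np.searchsorted(cdf[m], uniforms[sel], side="right")
    sector_idx = np.clip(sector_idx, 0, 7)
    bearings = np.array([WIND_BEARINGS[s] for s in WIND_SECTORS])
    theta = np.deg2rad(bearings[sector_idx])
    # "from" bearing theta -> velocity toward theta + 180 deg
    u = -speeds * np.sin(theta)
    v = -speeds * np.cos(theta)
    return WindSeries(times=times, wind_u=u, wind_v=v)


def wind_sector_labels(series: WindSeries) -> np.ndarray:
    """Back out the compass sector of each interval from its velocity."""
    theta = np.rad2deg(np.arctan2(-series.wind_u, -series.wind_v)) % 360.0
    idx = (np.round(theta / 45.0).astype(int)) % 8
    return np.array(WIND_SECTORS)[idx]


def make_analytic_field(kind: str, params: dict, grid) -> GriddedFlowField:
    """Closed-form oracle fields on a grid: uniform, solid_rotation, double_gyre.

    ``grid`` is ``(x_axis, y_axis)``; the returned field is steady (two
    identical snapshots spanning ``params.get('duration', 1e9)`` seconds).

    * ``uniform``: constant ``(u, v)``.
    * ``solid_rotation``: counter-clockwise rigid rotation at angular rate
      ``omega`` about ``center``; speed grows linearly with radius.
    * ``double_gyre``: steady two-cell streamfunction flow
      ``psi = A sin(pi x / L) sin(pi y / L)`` on ``[0, 2L] x [0, L]``.
    """
    x, y = (np.asarray(a, dtype=float) for a in grid)
    xx, yy = np.meshgrid(x, y)
    if kind == "uniform":
        u = np.full_like(xx, float(params["u"]))
        v = np.full_like(xx, float(params["v"]))
    elif kind == "solid_rotation":
        omega = float(params["omega"])
        cxc, cyc = params.get("center", (0.0, 0.0))
        u = -omega * (yy - cyc)
        v = omega * (xx - cxc)
    elif kind == "double_gyre":
        amp = float(params["A"])
        scale = float(params["L"])
        u = -np.pi * amp / scale * np.sin(np.pi * xx / scale) \
            * np.cos(np.pi * yy / scale)
        v = np.pi * amp / scale * np.cos(np.pi * xx / scale) \
            * np.sin(np.pi * yy / scale)
    else:
        raise ValueError(f"unknown analytic field kind {kind!r}")
    duration = float(params.get("duration", 1e9))
    times = np.array([0.0, duration])
    return GriddedFlowField(x, y, times, np.stack([u, u]), np.stack([v, v]))
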