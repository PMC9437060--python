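"""Gridded velocity forcing: containers, interpolation and NetCDF I/O.

Two field flavours share one sampling interface:

* :class:`GriddedFlowField` - velocity snapshots on a uniform (time, y, x)
  grid, bilinear in space and linear in time, the CF-style exchange format.
* :class:`HarmonicFlowField` - a residual pattern plus one tidal harmonic
  (amplitude pattern x cos(omega t + phase)), exact in time.  Year-long
  simulations sample it analytically instead of materialising thousands of
  hourly snapshots; :meth:`HarmonicFlowField.to_gridded` produces the
  equivalent snapshot stack when the gridded contract is needed.

Velocities stored on land cells are zero by construction.  For sampling,
land cells are pre-filled with the nearest water value so that bilinear
stencils touching the coast do not produce an artificial slowdown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr
from scipy import ndimage


class FieldCoverageError(ValueError):
    """Requested time lies outside the field's coverage."""


def _check_axis(a, name):
    a = np.asarray(a, dtype=float)
    if a.ndim != 1 or len(a) < 2:
        raise ValueError(f"{name} must be 1-D with >= 2 points")
    steps = np.diff(a)
    if np.any(steps <= 0):
        raise ValueError(f"{name} must be strictly increasing")
    if not np.allclose(steps, steps[0], rtol=1e-6):
        raise ValueError(f"{name} must be uniformly spaced")
    return a


def fill_land_nearest(arr: np.ndarray, land_mask: np.ndarray) -> np.ndarray:
    """Replace land-cell values by the nearest water-cell value."""
    if not land_mask.any():
        return arr
    if land_mask.all():
        raise ValueError("field is all land")
    _, (iy, ix) = ndimage.distance_transform_edt(land_mask, return_indices=True)
    return arr[..., iy, ix]


class _SpatialGrid:
    """Uniform x/y axes with a land mask and a vectorised bilinear sampler."""

    def __init__(self, x, y, land_mask=None):
        self.x = _check_axis(x, "x_coords")
        self.y = _check_axis(y, "y_coords")
        self.dx = float(self.x[1] - self.x[0])
        self.dy = float(self.y[1] - self.y[0])
        if land_mask is None:
            land_mask = np.zeros((len(self.y), len(self.x)), dtype=bool)
        self.land_mask = np.asarray(land_mask, dtype=bool)
        if self.land_mask.shape != (len(self.y), len(self.x)):
            raise ValueError("land_mask shape must be (ny, nx)")

    def bilinear_weights(self, px, py):
        """Corner indices and weights for bilinear interpolation, edge-clamped."""
        fx = np.clip((np.asarray(px, float) - self.x[0]) / self.dx,
                     0.0, len(self.x) - 1.000001)
        fy = np.clip((np.asarray(py, float) - self.y[0]) / self.dy,
                     0.0, len(self.y) - 1.000001)
        ix = fx.astype(np.intp)
        iy = fy.astype(np.intp)
        tx = fx - ix
        ty = fy - iy
        w00 = (1 - tx) * (1 - ty)
        w10 = tx * (1 - ty)
        w01 = (1 - tx) * ty
        w11 = tx * ty
        return (iy, ix), (w00, w10, w01, w11)

    @staticmethod
    def apply_weights(arr, idx, w):
        (iy, ix), (w00, w10, w01, w11) = idx, w
        return (w00 * arr[iy, ix] + w10 * arr[iy, ix + 1]
                + w01 * arr[iy + 1, ix] + w11 * arr[iy + 1, ix + 1])


@dataclass
class WindSeries:
    """Spatially uniform wind velocity, piecewise constant per interval."""

    times: np.ndarray  # interval start times, seconds, uniform
    wind_u: np.ndarray
    wind_v: np.ndarray

    def __post_init__(self):
        self.times = _check_axis(self.times, "times") if len(self.times) > 1 \
            else np.asarray(self.times, dtype=float)
        self.wind_u = np.asarray(self.wind_u, dtype=float)
        self.wind_v = np.asarray(self.wind_v, dtype=float)
        if not (np.all(np.isfinite(self.wind_u))
                and np.all(np.isfinite(self.wind_v))):
            raise ValueError("wind speeds must be finite")
        if len(self.wind_u) != len(self.times) or len(self.wind_v) != len(self.times):
            raise ValueError("wind components must match the time axis")

    def sample(self, t):
        """Wind vector at time(s) t (held constant within each interval)."""
        i = np.clip(np.searchsorted(self.times, t, side="right") - 1,
                    0, len(self.times) - 1)
        return self.wind_u[i], self.wind_v[i]

    @classmethod
    def calm(cls, duration: float) -> "WindSeries":
        return cls(times=np.array([0.0, duration]),
                   wind_u=np.zeros(2), wind_v=np.zeros(2))


class FlowField:
    """Base class: uniform spatial grid + ``sample(x, y, t)``."""

    def __init__(self, x, y, land_mask=None):
        self.grid = _SpatialGrid(x, y, land_mask)

    @property
    def x_coords(self):
        return self.grid.x

    @property
    def y_coords(self):
        return self.grid.y

    @property
    def land_mask(self):
        return self.grid.land_mask

    @property
    def t_min(self):
        raise NotImplementedError

    @property
    def t_max(self):
        raise NotImplementedError

    def _check_time(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < self.t_min - 1e-6) or np.any(t > self.t_max + 1e-6):
            raise FieldCoverageError(
                f"time {t} outside field coverage [{self.t_min}, {self.t_max}]")
        return np.clip(t, self.t_min, self.t_max)

    def sample(self, px, py, t):
        raise NotImplementedError


class GriddedFlowField(FlowField):
    """Velocity snapshots indexed (time, y, x); the CF exchange container."""

    def __init__(self, x, y, times, u, v, land_mask=None):
        super().__init__(x, y, land_mask)
        self.times = _check_axis(times, "times")
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        expected = (len(self.times), len(self.y_coords), len(self.x_coords))
        if u.shape != expected or v.shape != expected:
            raise ValueError(f"u, v must have shape {expected}")
        water = ~self.land_mask
        if not (np.all(np.isfinite(u[:, water])) and np.all(np.isfinite(v[:, water]))):
            raise ValueError("velocities must be finite on water cells")
        # public arrays carry the zero-on-land invariant;
        # private fill arrays back the interpolation stencil
        self.u = np.where(self.land_mask, 0.0, u)
        self.v = np.where(self.land_mask, 0.0, v)
        self._uf = fill_land_nearest(self.u, self.land_mask)
        self._vf = fill_land_nearest(self.v, self.land_mask)

    @property
    def t_min(self):
        return float(self.times[0])

    @property
    def t_max(self):
        return float(self.times[-1])

    def sample(self, px, py, t):
        t = self._check_time(t)
        dt = self.times[1] - self.times[0]
        ft = np.clip((t - self.times[0]) / dt, 0.0, len(self.times) - 1.000001)
        it = int(ft) if np.ndim(ft) == 0 else ft.astype(np.intp)
        wt = ft - it
        idx, w = self.grid.bilinear_weights(px, py)
        if np.ndim(it) == 0:
            u0 = self.grid.apply_weights(self._uf[it], idx, w)
            u1 = self.grid.apply_weights(self._uf[it + 1], idx, w)
            v0 = self.grid.apply_weights(self._vf[it], idx, w)
            v1 = self.grid.apply_weights(self._vf[it + 1], idx, w)
            return (1 - wt) * u0 + wt * u1, (1 - wt) * v0 + wt * v1
        # heterogeneous times per particle (rare path)
        u = np.empty(np.shape(px), dtype=float)
        v = np.empty(np.shape(px), dtype=float)
        for k in np.unique(it):
            sel = it == k
            sidx = (idx[0][sel], idx[1][sel])
            sw = tuple(wi[sel] for wi in w)
            u0 = self.grid.apply_weights(self._uf[k], sidx, sw)
            u1 = self.grid.apply_weights(self._uf[k + 1], sidx, sw)
            v0 = self.grid.apply_weights(self._vf[k], sidx, sw)
            v1 = self.grid.apply_weights(self._vf[k + 1], sidx, sw)
            u[sel] = (1 - wt[sel]) * u0 + wt[sel] * u1
            v[sel] = (1 - wt[sel]) * v0 + wt[sel] * v1
        return u, v

    def to_dataset(self) -> xr.Dataset:
        """CF-style dataset (u, v over time/y/x; land_mask as byte flag)."""
        ds = xr.Dataset(
            {
                "u": (("time", "y", "x"), self.u,
                      {"units": "m s-1", "standard_name": "eastward_sea_water_velocity"}),
                "v": (("time", "y", "x"), self.v,
                      {"units": "m s-1", "standard_name": "northward_sea_water_velocity"}),
                "land_mask": (("y", "x"), self.land_mask.astype(np.int8),
                              {"flag_values": [0, 1],
                               "flag_meanings": "water land"}),
            },
            coords={
                "time": ("time", self.times, {"units": "seconds since run start"}),
                "y": ("y", self.y_coords, {"units": "m"}),
                "x": ("x", self.x_coords, {"units": "m"}),
            },
            attrs={"Conventions": "CF-1.8",
                   "coordinate_system": "local Cartesian metres"},
        )
        return ds

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "GriddedFlowField":
        with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
            ds = ds.load()
        return cls(x=ds["x"].values, y=ds["y"].values, times=ds["time"].values,
                   u=ds["u"].values, v=ds["v"].values,
                   land_mask=ds["land_mask"].values.astype(bool))


class HarmonicFlowField(FlowField):
    """Residual pattern + one tidal harmonic, analytic in time.

    u(x, y, t) = u_res(x, y) + u_amp(x, y) * cos(omega t + phase), same for v.
    """

    def __init__(self, x, y, residual_u, residual_v, amp_u, amp_v,
                 omega, duration, phase=0.0, land_mask=None):
        super().__init__(x, y, land_mask)
        shape = (len(self.y_coords), len(self.x_coords))
        for name, arr in (("residual_u", residual_u), ("residual_v", residual_v),
                          ("amp_u", amp_u), ("amp_v", amp_v)):
            arr = np.asarray(arr, dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}")
        lm = self.land_mask
        self.residual_u = np.where(lm, 0.0, residual_u)
        self.residual_v = np.where(lm, 0.0, residual_v)
        self.amp_u = np.where(lm, 0.0, amp_u)
        self.amp_v = np.where(lm, 0.0, amp_v)
        self._ruf = fill_land_nearest(self.residual_u, lm)
        self._rvf = fill_land_nearest(self.residual_v, lm)
        self._auf = fill_land_nearest(self.amp_u, lm)
        self._avf = fill_land_nearest(self.amp_v, lm)
        self.omega = float(omega)
        self.phase = float(phase)
        self.duration = float(duration)

    @property
    def t_min(self):
        return 0.0

    @property
    def t_max(self):
        return self.duration

    def sample(self, px, py, t):
        t = self._check_time(t)
        idx, w = self.grid.bilinear_weights(px, py)
        c = np.cos(self.omega * t + self.phase)
        u = (self.grid.apply_weights(self._ruf, idx, w)
             + c * self.grid.apply_weights(self._auf, idx, w))
        v = (self.grid.apply_weights(self._rvf, idx, w)
             + c * self.grid.apply_weights(self._avf, idx, w))
        return u, v

    def snapshot(self, t):
        """(u, v) 2-D arrays at time t, zero on land."""
        t = float(self._check_time(t))
        c = np.cos(self.omega * t + self.phase)
        return self.residual_u + c * self.amp_u, self.residual_v + c * self.amp_v

    def to_gridded(self, times=None, interval=3_600.0) -> GriddedFlowField:
        """Materialise hourly (or custom) snapshots as a gridded field."""
        if times is None:
            times = np.arange(0.0, self.duration + 0.5 * interval, interval)
        times = np.asarray(times, dtype=float)
        nt = len(times)
        c = np.cos(self.omega * times + self.phase)[:, None, None]
        u = np.broadcast_to(self.residual_u, (nt,) + self.residual_u.shape) \
            + c * self.amp_u
        v = np.broadcast_to(self.residual_v, (nt,) + self.residual_v.shape) \
            + c * self.amp_v
        return GriddedFlowField(self.x_coords, self.y_coords, times,
                                np.ascontiguousarray(u), np.ascontiguousarray(v),
                                land_mask=self.land_mask)
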