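"""Connectivity, retention and stranding statistics from trajectory sets.

The central quantity is the Normalized Source Index (NSI): for each source
cell, the ratio of particles that reached the strait to particles released
there, averaged over release cohorts and normalized by the maximum cell
value, so NSI = 1 marks the best-connected source waters.  Companion
metrics are the per-cell mean travel time (particle age at first strait
entry), the daily cumulative entry ratio, daily strait occupancy, the
cumulative Tyrrhenian exit (retention) ratio, and per-coastal-segment
stranding shares.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .timeutil import DAYS_PER_YEAR, SECONDS_PER_DAY
from .tracker import (STATUS_EXITED_TYRRHENIAN, STATUS_LEFT_DOMAIN,
                      TrajectorySet)


@dataclass
class SourceGrid:
    """Regular source bins over release positions with per-cell statistics."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    released: np.ndarray  # (ny, nx) counts
    entered: np.ndarray  # (ny, nx) counts of first entries
    ratio: np.ndarray  # cohort-averaged entered/released, NaN where no release
    nsi: np.ndarray  # ratio / max ratio, NaN where undefined
    nsi_defined: bool  # False when no particle entered anywhere
    mean_travel_time: Optional[np.ndarray] = None  # seconds, NaN where undefined

    @property
    def cell_centers(self):
        cx = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        cy = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        return cx, cy

    def to_dataframe(self) -> pd.DataFrame:
        cx, cy = self.cell_centers
        xx, yy = np.meshgrid(cx, cy)
        d = {"x": xx.ravel(), "y": yy.ravel(),
             "released": self.released.ravel(),
             "entered": self.entered.ravel(),
             "ratio": self.ratio.ravel(), "nsi": self.nsi.ravel()}
        if self.mean_travel_time is not None:
            d["mean_travel_time_days"] = (self.mean_travel_time.ravel()
                                          / SECONDS_PER_DAY)
        return pd.DataFrame(d)

    def to_geojson(self) -> dict:
        feats = []
        ttime = self.mean_travel_time
        for iy in range(len(self.y_edges) - 1):
            for ix in range(len(self.x_edges) - 1):
                if self.released[iy, ix] == 0:
                    continue
                x0, x1 = self.x_edges[ix], self.x_edges[ix + 1]
                y0, y1 = self.y_edges[iy], self.y_edges[iy + 1]
                props = {"released": int(self.released[iy, ix]),
                         "entered": int(self.entered[iy, ix]),
                         "ratio": _none_if_nan(self.ratio[iy, ix]),
                         "nsi": _none_if_nan(self.nsi[iy, ix])}
                if ttime is not None:
                    props["mean_travel_time_s"] = _none_if_nan(ttime[iy, ix])
                feats.append({
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [[
                        [x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]]},
                    "properties": props})
        return {"type": "FeatureCollection",
                "properties": {"crs": "local Cartesian metres (planar)",
                               "nsi_defined": self.nsi_defined},
                "features": feats}


def _none_if_nan(v):
    return None if not np.isfinite(v) else float(v)


def _bin_edges(values, bin_size):
    lo = np.floor(values.min() / bin_size) * bin_size
    hi = np.ceil(values.max() / bin_size) * bin_size
    if hi <= lo:
        hi = lo + bin_size
    return np.arange(lo, hi + 0.5 * bin_size, bin_size)


def compute_nsi(traj: TrajectorySet, bin_size: float = 2_000.0) -> SourceGrid:
    """Normalized Source Index on regular bins over the release positions.

    Per cell and per release cohort, the ratio of particles that entered
    the strait to particles released; cohort ratios are averaged (cohorts
    with no release in a cell do not contribute), then divided by the
    maximum cell value.  Cells with no releases are NaN (undefined, not
    zero).  If no particle entered anywhere the normalization is
    impossible: all NSI are NaN and ``nsi_defined`` is False.
    """
    if traj.n_particles < 1:
        raise ValueError("need at least one released particle")
    x = traj.source_position[:, 0]
    y = traj.source_position[:, 1]
    x_edges = _bin_edges(x, bin_size)
    y_edges = _bin_edges(y, bin_size)
    nx, ny = len(x_edges) - 1, len(y_edges) - 1
    ix = np.clip(np.digitize(x, x_edges) - 1, 0, nx - 1)
    iy = np.clip(np.digitize(y, y_edges) - 1, 0, ny - 1)
    cell = iy * nx + ix
    entered = np.isfinite(traj.first_entry_time)

    released_tot = np.bincount(cell, minlength=nx * ny).reshape(ny, nx)
    entered_tot = np.bincount(cell[entered], minlength=nx * ny).reshape(ny, nx)

    ratio_sum = np.zeros(nx * ny)
    cohort_n = np.zeros(nx * ny)
    for rt in np.unique(traj.release_time):
        sel = traj.release_time == rt
        rel = np.bincount(cell[sel], minlength=nx * ny).astype(float)
        ent = np.bincount(cell[sel & entered], minlength=nx * ny).astype(float)
        has = rel > 0
        ratio_sum[has] += ent[has] / rel[has]
        cohort_n[has] += 1
    with np.errstate(invalid="ignore"):
        ratio = np.where(cohort_n > 0, ratio_sum / np.maximum(cohort_n, 1),
                         np.nan).reshape(ny, nx)

    defined = np.isfinite(ratio)
    max_ratio = np.nanmax(ratio) if defined.any() else np.nan
    if not np.isfinite(max_ratio) or max_ratio <= 0:
        nsi = np.full_like(ratio, np.nan)
        return SourceGrid(x_edges, y_edges, released_tot, entered_tot,
                          ratio, nsi, nsi_defined=False)
    nsi = ratio / max_ratio
    return SourceGrid(x_edges, y_edges, released_tot, entered_tot,
                      ratio, nsi, nsi_defined=True)


def travel_time_map(traj: TrajectorySet, source_grid: SourceGrid,
                    nsi_threshold: float = 0.6) -> np.ndarray:
    """Mean particle age at first strait entry, per well-connected cell.

    Defined only for cells with NSI strictly above the threshold and at
    least one entering particle; elsewhere NaN.  The array is also stored
    on ``source_grid.mean_travel_time``.
    """
    x_edges, y_edges = source_grid.x_edges, source_grid.y_edges
    nx, ny = len(x_edges) - 1, len(y_edges) - 1
    ix = np.clip(np.digitize(traj.source_position[:, 0], x_edges) - 1, 0, nx - 1)
    iy = np.clip(np.digitize(traj.source_position[:, 1], y_edges) - 1, 0, ny - 1)
    cell = iy * nx + ix
    entered = np.isfinite(traj.first_entry_time)
    ages = traj.first_entry_age
    age_sum = np.bincount(cell[entered], weights=ages[entered],
                          minlength=nx * ny).reshape(ny, nx)
    n_ent = np.bincount(cell[entered], minlength=nx * ny).reshape(ny, nx)
    with np.errstate(invalid="ignore"):
        mean_age = np.where(n_ent > 0, age_sum / np.maximum(n_ent, 1), np.nan)
    mean_age = np.where(source_grid.nsi > nsi_threshold, mean_age, np.nan)
    source_grid.mean_travel_time = mean_age
    return mean_age


def _daily_index(traj: TrajectorySet):
    n_days = int(np.ceil(traj.duration / SECONDS_PER_DAY))
    return np.arange(1, n_days + 1)  # 1-based day numbers


def entry_ratio_series(traj: TrajectorySet,
                       by_day_of_year: bool = False) -> pd.Series:
    """Daily cumulative entrants over cumulative released still in domain.

    Numerator: distinct particles that have entered the strait by the end
    of each day.  Denominator: particles released minus particles that
    left the domain through the open boundary by then.  Days with a zero
    denominator are NaN.  With ``by_day_of_year`` multi-year runs are
    averaged on the day-of-year.
    """
    days = _daily_index(traj)
    ends = days * SECONDS_PER_DAY
    rel = np.searchsorted(np.sort(traj.release_time), ends, side="right")
    ent_t = np.sort(traj.first_entry_time[np.isfinite(traj.first_entry_time)])
    ent = np.searchsorted(ent_t, ends, side="right")
    left_t = traj.status_time[traj.status == STATUS_LEFT_DOMAIN]
    left = np.searchsorted(np.sort(left_t), ends, side="right")
    denom = (rel - left).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom > 0, ent / denom, np.nan)
    series = pd.Series(ratio, index=pd.Index(days, name="day"),
                       name="entry_ratio")
    if by_day_of_year:
        doy = (days - 1) % DAYS_PER_YEAR + 1
        series = series.groupby(doy).mean()
        series.index.name = "day_of_year"
    return series


def occupancy_series(traj: TrajectorySet) -> pd.Series:
    """Daily mean (over the day's output snapshots) of particles in the strait."""
    counts = traj.in_strait.sum(axis=1).astype(float)
    day = np.floor_divide(traj.output_times, SECONDS_PER_DAY).astype(int) + 1
    series = pd.Series(counts).groupby(day).mean()
    series.index.name = "day"
    series.name = "occupancy"
    return series


def retention_ratio_series(traj: TrajectorySet) -> pd.Series:
    """Daily cumulative Tyrrhenian exits over cumulative strait entrants.

    Values in [0, 1]; low values mean the strait is retaining what it
    receives.  Days with no entrants yet are NaN.
    """
    days = _daily_index(traj)
    ends = days * SECONDS_PER_DAY
    ent_t = np.sort(traj.first_entry_time[np.isfinite(traj.first_entry_time)])
    ent = np.searchsorted(ent_t, ends, side="right")
    exit_t = traj.status_time[traj.status == STATUS_EXITED_TYRRHENIAN]
    exits = np.searchsorted(np.sort(exit_t), ends, side="right")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ent > 0, exits / ent.astype(float), np.nan)
    series = pd.Series(ratio, index=pd.Index(days, name="day"),
                       name="retention_ratio")
    return series


@dataclass
class StrandingShares:
    """Per-segment stranding percentages and the coast ratio."""

    table: pd.DataFrame  # columns: segment_id, coast, count, share_pct
    coast_totals: dict
    coast_ratio: float  # Calabria / Sicily, NaN if undefined

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


def stranding_shares(traj_or_segments, segments=None) -> StrandingShares:
    """Share (%) of stranding events per coastal segment plus coast totals.

    Accepts a :class:`TrajectorySet` (with stranding segment ids) or a
    sequence of segment ids, together with the segment list.  Shares sum
    to 100% whenever any stranding occurred; the coast ratio is the
    Calabria total over the Sicily total (NaN when Sicily is zero or
    nothing stranded).
    """
    if segments is None:
        raise TypeError("segments are required")
    if isinstance(traj_or_segments, TrajectorySet):
        ids = [s for s in traj_or_segments.stranding_segment if s is not None]
    else:
        ids = list(traj_or_segments)
    seg_ids = [s.id for s in segments]
    coasts = {s.id: s.coast for s in segments}
    counts = pd.Series(ids).value_counts() if ids else pd.Series(dtype=int)
    count_col = np.array([int(counts.get(sid, 0)) for sid in seg_ids])
    total = count_col.sum()
    share = 100.0 * count_col / total if total > 0 else np.zeros(len(seg_ids))
    table = pd.DataFrame({"segment_id": seg_ids,
                          "coast": [coasts[s] for s in seg_ids],
                          "count": count_col, "share_pct": share})
    coast_totals = table.groupby("coast")["count"].sum().to_dict()
    sic = coast_totals.get("sicily_side", 0)
    cal = coast_totals.get("calabria_side", 0)
    ratio = cal / sic if sic > 0 else np.nan
    return StrandingShares(table=table, coast_totals=coast_totals,
                           coast_ratio=ratio)


def mean_strait_residence(traj: TrajectorySet) -> float:
    """Mean time spent inside the strait per particle, seconds.

    Counts output snapshots flagged in-strait, scaled by the output
    interval; averaged over all released particles.
    """
    if traj.n_particles == 0:
        return np.nan
    out_dt = float(traj.output_times[1] - traj.output_times[0])
    hours_in = traj.in_strait.sum(axis=0).astype(float)
    return float(hours_in.mean() * out_dt)


@dataclass
class ConnectivityResult:
    """Bundle of the connectivity products of one experiment run."""

    source_grid: Optional[SourceGrid] = None
    entry_ratio: Optional[pd.Series] = None
    occupancy: Optional[pd.Series] = None
    retention: Optional[pd.Series] = None
    stranding: Optional[StrandingShares] = None

    def write(self, outdir) -> None:
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        if self.source_grid is not None:
            self.source_grid.to_dataframe().to_csv(out / "source_grid.csv",
                                                   index=False)
            with open(out / "source_grid.geojson", "w") as fh:
                json.dump(self.source_grid.to_geojson(), fh)
        for name, series in (("entry_ratio", self.entry_ratio),
                             ("occupancy", self.occupancy),
                             ("retention", self.retention)):
            if series is not None:
                series.to_csv(out / f"{name}.csv", header=True)
        if self.stranding is not None:
            self.stranding.to_csv(out / "stranding_shares.csv")
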