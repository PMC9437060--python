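"""Connectivity metrics against forced examples and brute-force recounts."""

import numpy as np
import pytest

from medusadrift.metrics import (compute_nsi, entry_ratio_series,
                                 mean_strait_residence, occupancy_series,
                                 retention_ratio_series, stranding_shares,
                                 travel_time_map)
from medusadrift.tracker import TrajectorySet

DAY = 86_400.0


def _mini_traj(source, release_time, entered_age=None, status=None,
               status_time=None, strand_seg=None, duration=10 * DAY,
               in_strait=None):
    """Assemble a small TrajectorySet from per-particle scalars."""
    n = len(source)
    source = np.asarray(source, dtype=float)
    release_time = np.asarray(release_time, dtype=float)
    first_entry = np.full(n, np.nan)
    if entered_age is not None:
        for i, age in enumerate(entered_age):
            if age is not None:
                first_entry[i] = release_time[i] + age
    st = np.zeros(n, dtype=np.int8) if status is None else \
        np.asarray(status, dtype=np.int8)
    stt = np.full(n, np.nan) if status_time is None else \
        np.asarray(status_time, dtype=float)
    seg = np.full(n, None, dtype=object)
    if strand_seg is not None:
        for i, s in enumerate(strand_seg):
            seg[i] = s
    out_times = np.arange(0.0, duration + 1, 3_600.0)
    ins = (np.zeros((len(out_times), n), dtype=bool) if in_strait is None
           else in_strait)
    return TrajectorySet(
        release_time=release_time, source_position=source, status=st,
        status_time=stt, first_entry_time=first_entry,
        stranding_segment=seg, final_position=source.copy(),
        output_times=out_times, in_strait=ins, positions=None,
        duration=duration)


class TestComputeNSI:
    def test_single_cohort_forced_values(self):
        """(10/10, 5/10, 0/10) entering ratios normalize to (1, 0.5, 0)."""
        src = ([[500, 500]] * 10 + [[2_500, 500]] * 10 + [[4_500, 500]] * 10)
        ages = [0.0] * 10 + [0.0] * 5 + [None] * 5 + [None] * 10
        traj = _mini_traj(src, [0.0] * 30, entered_age=ages)
        grid = compute_nsi(traj, bin_size=2_000.0)
        assert grid.nsi_defined
        row = grid.nsi[0]
        assert np.allclose(row[:3], [1.0, 0.5, 0.0])

    def test_identical_ratios_all_one(self):
        src = [[500, 500]] * 4 + [[2_500, 500]] * 4
        ages = [0.0, 0.0, None, None] * 2
        traj = _mini_traj(src, [0.0] * 8, entered_age=ages)
        grid = compute_nsi(traj, bin_size=2_000.0)
        assert np.allclose(grid.nsi[0, :2], 1.0)

    def test_cohort_averaging(self):
        """Cohort ratios 0.2 and 0.6 average to 0.4; against 0.8 -> NSI 0.5."""
        src, rel, ages = [], [], []
        # cell A: cohort 1 ratio 0.2 (1/5), cohort 2 ratio 0.6 (3/5)
        for cohort, (rt, k) in enumerate([(0.0, 1), (DAY, 3)]):
            for i in range(5):
                src.append([500, 500])
                rel.append(rt)
                ages.append(0.0 if i < k else None)
        # cell B: constant ratio 0.8 (4/5) in both cohorts
        for rt in (0.0, DAY):
            for i in range(5):
                src.append([2_500, 500])
                rel.append(rt)
                ages.append(0.0 if i < 4 else None)
        traj = _mini_traj(src, rel, entered_age=ages)
        grid = compute_nsi(traj, bin_size=2_000.0)
        assert np.isclose(grid.ratio[0, 0], 0.4)
        assert np.isclose(grid.ratio[0, 1], 0.8)
        assert np.isclose(grid.nsi[0, 0], 0.5)
        assert np.isclose(grid.nsi[0, 1], 1.0)

    def test_no_entrants_flagged_undefined(self):
        traj = _mini_traj([[500, 500]] * 5, [0.0] * 5)
        grid = compute_nsi(traj, bin_size=2_000.0)
        assert not grid.nsi_defined
        assert np.all(np.isnan(grid.nsi))

    def test_max_defined_nsi_is_one(self, exp1_run):
        grid = exp1_run.connectivity.source_grid
        assert grid.nsi_defined
        assert np.isclose(np.nanmax(grid.nsi), 1.0)


class TestTravelTimeMap:
    def test_mean_of_two_entrants(self):
        src = [[500, 500]] * 2
        ages = [10 * DAY, 30 * DAY]
        traj = _mini_traj(src, [0.0, 0.0], entered_age=ages, duration=40 * DAY)
        grid = compute_nsi(traj, bin_size=2_000.0)
        tt = travel_time_map(traj, grid, nsi_threshold=0.6)
        assert np.isclose(tt[0, 0], 20 * DAY)

    def test_below_threshold_undefined(self):
        # cell A enters 1/2 (NSI 0.5), cell B 2/2 (NSI 1.0)
        src = [[500, 500]] * 2 + [[2_500, 500]] * 2
        ages = [5 * DAY, None, 5 * DAY, 5 * DAY]
        traj = _mini_traj(src, [0.0] * 4, entered_age=ages, duration=40 * DAY)
        grid = compute_nsi(traj, bin_size=2_000.0)
        tt = travel_time_map(traj, grid, nsi_threshold=0.6)
        assert np.isnan(tt[0, 0])
        assert np.isfinite(tt[0, 1])


class TestEntryRatio:
    def test_nobody_enters_zero(self):
        traj = _mini_traj([[0, 0]] * 10, [0.0] * 10)
        series = entry_ratio_series(traj)
        assert np.allclose(series.values, 0.0)

    def test_step_at_entry_day(self):
        traj = _mini_traj([[0, 0]] * 4, [0.0] * 4,
                          entered_age=[4.5 * DAY] * 4)
        series = entry_ratio_series(traj)
        assert np.allclose(series.loc[:4], 0.0)
        assert np.allclose(series.loc[5:], 1.0)

    def test_left_domain_removed_from_denominator(self):
        """100 released, 20 left, 40 entered -> 40/80 = 0.5."""
        n = 100
        status = np.zeros(n, dtype=np.int8)
        status[:20] = 4  # left_domain
        status_time = np.full(n, np.nan)
        status_time[:20] = 2 * DAY
        ages = [None] * 20 + [3 * DAY] * 40 + [None] * 40
        traj = _mini_traj([[0, 0]] * n, [0.0] * n, entered_age=ages,
                          status=status, status_time=status_time)
        series = entry_ratio_series(traj)
        assert np.isclose(series.iloc[-1], 0.5)


class TestOccupancyAndRetention:
    def test_occupancy_all_zero(self):
        traj = _mini_traj([[0, 0]] * 3, [0.0] * 3, duration=2 * DAY)
        assert np.allclose(occupancy_series(traj).values, 0.0)

    def test_occupancy_half_day(self):
        """A particle inside for 12 of 24 hourly snapshots scores 0.5."""
        traj = _mini_traj([[0, 0]], [0.0], duration=1 * DAY)
        ins = np.zeros((len(traj.output_times), 1), dtype=bool)
        ins[:12, 0] = True
        traj.in_strait = ins
        series = occupancy_series(traj)
        assert np.isclose(series.loc[1], 12 / 24)

    def test_retention_forced_counts(self):
        """10 entered, 4 north, 3 south -> retention ratio 0.4."""
        n = 10
        status = np.zeros(n, dtype=np.int8)
        status[:4] = 2
        status[4:7] = 3
        status_time = np.full(n, np.nan)
        status_time[:7] = 2 * DAY
        traj = _mini_traj([[0, 0]] * n, [0.0] * n,
                          entered_age=[DAY] * n, status=status,
                          status_time=status_time)
        series = retention_ratio_series(traj)
        assert np.isclose(series.iloc[-1], 0.4)

    def test_retention_none_leave(self):
        traj = _mini_traj([[0, 0]] * 5, [0.0] * 5, entered_age=[DAY] * 5)
        assert np.isclose(retention_ratio_series(traj).iloc[-1], 0.0)


class TestStrandingShares:
    def test_all_in_one_segment(self, toy_segments):
        shares = stranding_shares(["Sic1", "Sic1", "Sic1"], toy_segments)
        tab = shares.table.set_index("segment_id")
        assert np.isclose(tab.loc["Sic1", "share_pct"], 100.0)
        assert np.isclose(tab["share_pct"].sum(), 100.0)

    def test_equal_coasts_ratio_one(self, toy_segments):
        shares = stranding_shares(["Sic1", "Cal1"] * 10, toy_segments)
        assert np.isclose(shares.coast_ratio, 1.0)

    def test_53_47_split(self, toy_segments):
        ids = ["Cal1"] * 53 + ["Sic1"] * 47
        shares = stranding_shares(ids, toy_segments)
        tab = shares.table.set_index("segment_id")
        assert np.isclose(tab.loc["Cal1", "share_pct"], 53.0)
        assert np.isclose(tab.loc["Sic1", "share_pct"], 47.0)
        assert np.isclose(shares.coast_ratio, 53 / 47)

    def test_no_strandings_ratio_undefined(self, toy_segments):
        shares = stranding_shares([], toy_segments)
        assert np.isnan(shares.coast_ratio)
        assert np.allclose(shares.table["share_pct"], 0.0)


# ---------------------------------------------------------------------------
# brute-force recount oracles on the 50-particle hand fixture


def _brute_nsi(traj, bin_size):
    xs = traj.source_position[:, 0]
    ys = traj.source_position[:, 1]
    x0 = np.floor(xs.min() / bin_size) * bin_size
    y0 = np.floor(ys.min() / bin_size) * bin_size
    cells = {}
    for i in range(traj.n_particles):
        key = (int((xs[i] - x0) // bin_size), int((ys[i] - y0) // bin_size),
               traj.release_time[i])
        cells.setdefault(key, []).append(i)
    ratio = {}
    for (cx, cy, rt), idx in cells.items():
        ent = sum(1 for i in idx if np.isfinite(traj.first_entry_time[i]))
        ratio.setdefault((cx, cy), []).append(ent / len(idx))
    mean_ratio = {k: float(np.mean(v)) for k, v in ratio.items()}
    mx = max(mean_ratio.values())
    return {k: v / mx for k, v in mean_ratio.items()}, (x0, y0)


class TestBruteForceRecounts:
    """Each metric reproduces a plain-Python recount exactly."""

    def test_nsi(self, toy_trajectories):
        bin_size = 2_000.0
        oracle, (x0, y0) = _brute_nsi(toy_trajectories, bin_size)
        grid = compute_nsi(toy_trajectories, bin_size=bin_size)
        for (cx, cy), val in oracle.items():
            ix = int(round((x0 + cx * bin_size - grid.x_edges[0]) / bin_size))
            iy = int(round((y0 + cy * bin_size - grid.y_edges[0]) / bin_size))
            assert abs(grid.nsi[iy, ix] - val) < 1e-12

    def test_entry_ratio(self, toy_trajectories):
        traj = toy_trajectories
        series = entry_ratio_series(traj)
        for day in series.index:
            end = day * DAY
            rel = sum(1 for t in traj.release_time if t <= end)
            left = sum(1 for i in range(traj.n_particles)
                       if traj.status[i] == 4 and traj.status_time[i] <= end)
            ent = sum(1 for t in traj.first_entry_time
                      if np.isfinite(t) and t <= end)
            denom = rel - left
            expected = np.nan if denom == 0 else ent / denom
            got = series.loc[day]
            assert (np.isnan(expected) and np.isnan(got)) \
                or abs(got - expected) < 1e-12

    def test_occupancy(self, toy_trajectories):
        traj = toy_trajectories
        series = occupancy_series(traj)
        for day in series.index:
            hours = [k for k, t in enumerate(traj.output_times)
                     if int(t // DAY) + 1 == day]
            counts = [int(traj.in_strait[k].sum()) for k in hours]
            assert abs(series.loc[day] - np.mean(counts)) < 1e-12

    def test_retention(self, toy_trajectories):
        traj = toy_trajectories
        series = retention_ratio_series(traj)
        for day in series.index:
            end = day * DAY
            ent = sum(1 for t in traj.first_entry_time
                      if np.isfinite(t) and t <= end)
            ex = sum(1 for i in range(traj.n_particles)
                     if traj.status[i] == 2 and traj.status_time[i] <= end)
            expected = np.nan if ent == 0 else ex / ent
            got = series.loc[day]
            assert (np.isnan(expected) and np.isnan(got)) \
                or abs(got - expected) < 1e-12

    def test_stranding_shares(self, toy_trajectories, toy_segments):
        traj = toy_trajectories
        shares = stranding_shares(traj, toy_segments)
        ids = [s for s in traj.stranding_segment if s is not None]
        total = len(ids)
        tab = shares.table.set_index("segment_id")
        for seg in toy_segments:
            expected = 100.0 * ids.count(seg.id) / total
            assert abs(tab.loc[seg.id, "share_pct"] - expected) < 1e-12
        cal = sum(1 for s in ids if s.startswith("Cal"))
        sic = sum(1 for s in ids if s.startswith("Sic"))
        assert abs(shares.coast_ratio - cal / sic) < 1e-12

    def test_mean_residence(self, toy_trajectories):
        traj = toy_trajectories
        expected = np.mean([traj.in_strait[:, i].sum() * 3_600.0
                            for i in range(traj.n_particles)])
        assert abs(mean_strait_residence(traj) - expected) < 1e-9


class TestInvariants:
    def test_entrant_monotonicity(self, exp1_run):
        traj = exp1_run.trajectories
        days = np.arange(1, int(traj.duration // DAY) + 1)
        ent_t = np.sort(traj.first_entry_time[
            np.isfinite(traj.first_entry_time)])
        cum = np.searchsorted(ent_t, days * DAY, side="right")
        assert np.all(np.diff(cum) >= 0)

    def test_shares_sum_to_100(self, exp3_run):
        shares = exp3_run.connectivity.stranding
        assert abs(shares.table["share_pct"].sum() - 100.0) < 0.1
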