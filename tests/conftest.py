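"""Shared fixtures: idealized domain, forcing fields, desk-scale runs.

The experiment runs are session-scoped because they are the expensive part
of the suite; every test that needs a realistic trajectory set shares them.
"""

import numpy as np
import pytest

from medusadrift.config import FlowConfig, TrackerConfig
from medusadrift.synthetic import make_idealized_domain, make_strait_field
from medusadrift.tracker import TrajectorySet
from medusadrift.workflow import RunConfig, run_exp1, run_exp2, run_exp3


@pytest.fixture(scope="session")
def flow_config():
    return FlowConfig()


@pytest.fixture(scope="session")
def domain(flow_config):
    dom, _ = make_idealized_domain(flow_config)
    return dom


@pytest.fixture(scope="session")
def grid_axes_fixture(flow_config):
    from medusadrift.synthetic import grid_axes
    return grid_axes(flow_config)


@pytest.fixture(scope="session")
def strait_field(flow_config, domain):
    """Ten tidal periods of the default strait forcing."""
    return make_strait_field(flow_config, domain,
                             duration=10 * flow_config.tidal_period)


@pytest.fixture(scope="session")
def exp1_run():
    """Desk-scale connectivity experiment (basin releases, days 25-155)."""
    return run_exp1(RunConfig(experiment="exp1", master_seed=7))


@pytest.fixture(scope="session")
def exp2_run():
    """Desk-scale retention experiment (year-round strait releases)."""
    return run_exp2(RunConfig(experiment="exp2", master_seed=7))


@pytest.fixture(scope="session")
def exp3_run():
    """Desk-scale summer stranding experiment."""
    return run_exp3(RunConfig(experiment="exp3", master_seed=7))


@pytest.fixture(scope="session")
def exp2_regime_pair():
    """Same-seed retention runs: tidal+residual vs tidal-only (120 days)."""
    kwargs = dict(experiment="exp2", master_seed=11, window_days=(1, 110),
                  duration_days=120)
    full = run_exp2(RunConfig(**kwargs))
    tidal_only = run_exp2(RunConfig(**kwargs, include_residual=False,
                                    include_eddy=False))
    return full, tidal_only


@pytest.fixture(scope="session")
def exp3_symmetric_run():
    """Stranding run with mirror-symmetric forcing (no wind, no eddy)."""
    return run_exp3(RunConfig(experiment="exp3", master_seed=13,
                              wind=False, include_eddy=False))


def _toy_segments():
    """Two tiny coasts of 3 + 2 straight segments for hand-checked metrics."""
    from medusadrift.geometry import segment_coastline
    sic = segment_coastline(np.array([[0.0, 0.0], [15_000.0, 0.0]]),
                            5_000.0, coast="sicily_side", id_prefix="Sic")
    cal = segment_coastline(np.array([[0.0, 9_000.0], [10_000.0, 9_000.0]]),
                            5_000.0, coast="calabria_side", id_prefix="Cal")
    return sic + cal


@pytest.fixture(scope="session")
def toy_segments():
    return _toy_segments()


@pytest.fixture(scope="session")
def toy_trajectories(toy_segments):
    """A 50-particle trajectory set with known, recountable structure.

    Two release cohorts; source positions on a 2x2 km grid; a mix of
    entrants, Tyrrhenian/Ionian exits, strandings on both toy coasts, and
    open-boundary losses; hourly strait membership over five days.
    """
    rng = np.random.default_rng(1234)
    n = 50
    release_time = np.where(np.arange(n) < 30, 0.0, 86_400.0)
    source = np.column_stack([rng.uniform(0, 8_000, n),
                              rng.uniform(0, 6_000, n)])
    out_times = np.arange(0.0, 5 * 86_400.0 + 1, 3_600.0)
    m = len(out_times)

    status = np.zeros(n, dtype=np.int8)
    status_time = np.full(n, np.nan)
    first_entry = np.full(n, np.nan)
    seg_ids = [s.id for s in toy_segments]
    strand_seg = np.full(n, None, dtype=object)

    in_strait = np.zeros((m, n), dtype=bool)
    for i in range(n):
        r = rng.random()
        rel = release_time[i]
        if r < 0.5:  # enters the strait at some hour, may exit or stay
            t_ent = rel + rng.integers(1, 48) * 3_600.0
            first_entry[i] = t_ent
            t_leave = t_ent + int(rng.integers(5, 40)) * 3_600.0
            h0 = int(t_ent // 3_600)
            h1 = min(int(t_leave // 3_600), m - 1)
            in_strait[h0:h1 + 1, i] = True
            r2 = rng.random()
            if r2 < 0.4:
                status[i] = 2  # exited_tyrrhenian
                status_time[i] = t_leave + 3_600.0
                in_strait[h1 + 1:, i] = False
            elif r2 < 0.7:
                status[i] = 3  # exited_ionian
                status_time[i] = t_leave + 3_600.0
        elif r < 0.75:  # strands without entering
            status[i] = 1
            status_time[i] = rel + float(rng.integers(3, 90)) * 3_600.0
            strand_seg[i] = seg_ids[int(rng.integers(0, len(seg_ids)))]
        elif r < 0.85:  # leaves the domain
            status[i] = 4
            status_time[i] = rel + float(rng.integers(3, 90)) * 3_600.0
        # else: stays active in open water
    # membership before release is impossible
    for i in range(n):
        before = out_times < release_time[i]
        in_strait[before, i] = False

    return TrajectorySet(
        release_time=release_time, source_position=source, status=status,
        status_time=status_time, first_entry_time=first_entry,
        stranding_segment=strand_seg,
        final_position=np.zeros((n, 2)), output_times=out_times,
        in_strait=in_strait, positions=None, duration=5 * 86_400.0)
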