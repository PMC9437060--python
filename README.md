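# medusadrift

Lagrangian connectivity, retention and stranding analysis for jellyfish
(*Pelagia noctiluca*) transported between an island spawning basin and a
narrow tidal strait, together with the beach-survey analytics used to
compare model output with field observations.

## The problem

Holoplanktonic jellyfish spawned around a volcanic archipelago drift with
the surface circulation into a strait dominated by semi-diurnal tidal
currents (peaks above 2 m s⁻¹) with a weaker residual through-flow
(0.2–0.3 m s⁻¹) and an anticyclonic recirculation cell north of the sill.
The package answers three questions with a particle-tracking pipeline:

1. **Connectivity** — which source waters feed the strait, and how long
   does the journey take?
2. **Retention** — how efficiently does the strait's circulation trap
   what arrives?
3. **Stranding** — where along the two facing coasts do drifting animals
   beach, and in what proportions?

Because the original hydrodynamic hindcast is not distributed, a
synthetic-forcing module generates an idealized basin-plus-strait seascape
that reproduces the regime's magnitudes, so the whole pipeline runs from
scratch with no external data.

## The model

Particles are passive surface drifters advected by

dx/dt = **u**(x, t) + α **w**(t),  α = 0.004 (leeway, 4‰ of wind speed)

integrated with RK4 (Δt = 300 s default) on bilinearly interpolated
velocities, plus an uncorrelated random walk with per-axis increments of
standard deviation √(2 K Δt), K = 5 m² s⁻¹ by default.  Transport is
purely horizontal.  Terminal events are geometric coastline contact
(stranding, binned into 5-km coastal segments), exit through one of the
two gates bounding the strait, or crossing the outer open boundary.

The central connectivity statistic is the **Normalized Source Index**:
for source cell *i*,

NSI_i = ⟨ n_entered / n_released ⟩_cohorts / max_j ⟨ · ⟩_j ∈ [0, 1],

the cohort-averaged fraction of particles from that cell reaching the
strait, normalized by the best-connected cell.  Companion metrics: mean
particle age at first strait entry (travel time), the daily cumulative
entry ratio, daily strait occupancy, the cumulative Tyrrhenian-exit
(retention) ratio, and per-segment stranding shares with the
Calabria:Sicily coast ratio.

The survey module implements the field-observation computations: the
local allometric biomass law **W = 0.0002 · D^2.8786** (W in g, D = bell
diameter in mm), eye-count abundance classes (0; 1 = 1–10; 2 = 10–100;
3 = >100; explicit "large aggregation"), seasonal size-class and biomass
tables, the observed-vs-modeled stranding-ratio comparison, current-speed
statistics against the 5 cm s⁻¹ swimming threshold, and upwelling depth
from the 28.5 σt density-anomaly criterion.

## Worked example

```python
import numpy as np
from medusadrift import RunConfig, run_exp1, biomass

result = run_exp1(RunConfig(experiment="exp1", master_seed=1))
traj = result.trajectories
entered = np.isfinite(traj.first_entry_time)
print("released:", traj.n_particles)
print("entered strait:", int(entered.sum()))
print("final entry ratio:",
      round(result.connectivity.entry_ratio.dropna().iloc[-1], 3))
print("mean travel time (d):",
      round(np.nanmean(traj.first_entry_age[entered]) / 86400, 1))
print("one 50 mm medusa weighs (g):", round(biomass(50.0), 2))
```

prints, for this desk-scale run (2 016 particles released semi-diurnally
over the day 25–155 spawning window):

```
released: 2016
entered strait: 876
final entry ratio: 0.435
mean travel time (d): 5.3
one 50 mm medusa weighs (g): 15.55
```

i.e. 43.5 % of particles still in the domain reached the strait, taking
about five days on average from the synthetic spawning grounds, and the
allometric law gives 15.55 g wet weight for a 50-mm bell.  The NSI map is
in `result.connectivity.source_grid` (cells nearest the channel mouth
approach 1.0; far-basin and island-shadowed cells fall toward 0).

A command-line interface wraps the same pipeline:

```
medusadrift run-exp1 --seed 1 --outdir runs/exp1
medusadrift run-exp3 --seed 1 --outdir runs/exp3
medusadrift survey-stats --survey surveys.csv --out tables/
```

## Layout

- `src/medusadrift/synthetic.py` — idealized domain, strait/basin forcing,
  wind generator, analytic oracle fields
- `src/medusadrift/geometry.py` — regions, coastal segmentation, stranding
  and exit classification (GeoJSON I/O)
- `src/medusadrift/tracker.py` — the advection–diffusion particle tracker
- `src/medusadrift/metrics.py` — NSI, travel time, entry/occupancy/
  retention series, stranding shares
- `src/medusadrift/survey.py` — biomass, abundance classes, size/biomass
  tables, habitat statistics
- `src/medusadrift/workflow.py`, `cli.py` — experiment runners and CLI
- `docs/methods.md` — model description, parameter choices, limitations
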