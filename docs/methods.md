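# Methods

## Scope and design

The package is a biophysical transport pipeline for a jellyfish
population spawned in an island basin and advected into a tidal strait.
It has five working parts: a synthetic forcing generator, a planar
geometry layer, a Lagrangian particle tracker, connectivity/retention/
stranding metrics, and beach-survey analytics.  Everything runs on a
local Cartesian plane in metres: the idealized domain is of order 100 km,
small enough that a geographic projection would add nothing but
bookkeeping.  Ingested real fields are expected to be projected before
use.

## The idealized seascape

The domain is an 80 × 60 km rectangle.  Two mainland blocks occupy the
south-east; their facing walls, 4 km apart, form a north–south channel
connecting the northern open water to the southern boundary.  The strait
proper is the stretch of channel between two cross-channel gates
(y = 6 and 34 km); the sill sits midway (y = 20 km).  The western basin
holds four circular islands and a 30 × 20 km spawning rectangle around
them.  Each coast is cut into consecutive 5-km segments (all full length
except the final remainder), numbered in polyline order; the two mainland
coasts carry the `Sic*` / `Cal*` ids used for stranding shares, and each
island ring is segmented under its own name.

The current field is the sum of three components:

* **Basin drift** (default 8 cm s⁻¹, within the observed 5–10 cm s⁻¹
  range): a constant-magnitude drift toward a focus just north of the
  channel mouth.  Near the mainland top wall the drift's onshore
  component is suppressed and a small offshore lift is added, emulating a
  coastal boundary current whose *mean* flow does not run aground —
  coastal losses there are produced by wind and diffusion fluctuations.
  The drift field is kinematic, not divergence-free; for particle
  statistics at these speeds the distinction is immaterial, and no
  streamfunction machinery is warranted.
* **Residual through-flow** (default 0.25 m s⁻¹, observed 0.2–0.3):
  southward along the channel, weighted by a channel-proximity function
  that is exactly zero outside the channel walls (so along-wall flow
  rounds the mouth corners) and ramps up 1 km inside them.  An
  anticyclonic (clockwise) eddy with a Lamb–Oseen-style tangential
  profile sits just north of the sill.  Its peak tangential speed
  defaults to half the residual speed so that the time-mean speed on the
  eddy rim — through-flow plus eddy — stays near the configured residual
  value.
* **Semi-diurnal tide**: an along-channel oscillation
  A(x, y)·cos(2πt/T) with T = 44 712 s (the M2 period; the regime is
  described only as semi-diurnal, so T is configurable).  The amplitude
  peaks at 2.2 m s⁻¹ over the sill and decays along-channel with a 5-km
  Gaussian scale, mimicking the observed concentration of extreme
  currents at the sill.  This localisation also keeps the tidal excursion
  (~12 km) inside the gate span, which is what makes a tidal-only regime
  retentive rather than simply flushing.

Because the field is (residual) + (amplitude)·cos(ωt), it is stored as a
`HarmonicFlowField` and sampled analytically in time; materialising a
year of hourly snapshots (~3 GB at 500-m resolution) is never necessary.
`to_gridded()` produces the CF-style (time, y, x) snapshot stack for
interchange, written as NetCDF3 via the scipy backend.  Velocities on
land cells are identically zero; for interpolation, land cells are
pre-filled with the nearest water value so bilinear stencils touching the
coast do not drag particle speeds down artificially.

**Wind** is spatially uniform and piecewise constant over 3-h intervals.
Direction is a categorical draw over eight compass sectors from a monthly
prevalence table anchored to the observed regime — north-westerlies about
half the year overall, 95 % in May, 80 % in June, 8 % in October — with
the remainder spread evenly over the other sectors.  No wind-speed
magnitudes are reported for the region, so speeds are a modelling choice:
Rayleigh-distributed with scale 4.5 m s⁻¹ (mean ≈ 5.6 m s⁻¹), a typical
coastal Mediterranean distribution.  A "from" bearing convention is used:
a NW wind moves particles toward the south-east.

## The tracker

Particles obey dx/dt = **u** + α·**w** with leeway α = 0.004 (4‰ of wind
speed), integrated with RK4 by default (Euler and RK2 available) at
Δt = 300 s, plus Euler–Maruyama diffusion with per-axis increments of
std √(2KΔt).  K is not constrained by observation; the default 5 m² s⁻¹
is a conventional sub-grid horizontal eddy diffusivity at ~500 m
resolution, and K = 0 is fully supported for oracle tests.  Horizontal-
only transport reflects the surface-trapped behaviour of the early life
stages; no vertical dimension exists in the data model.

Stranding is geometric: a displacement segment crossing a land-polygon
boundary terminates the particle at the first crossing point, assigned to
the nearest coastal segment of that coast.  (Whether the original
GIS post-processing used geometric contact or land-cell entry is not
documented; geometric contact was chosen because it is independent of the
forcing grid resolution.)  A cheap prefilter — a land mask dilated by
three cells — selects candidates for the exact shapely test, so the
per-step cost stays vectorised.  Exit-gate crossings (checked every step
for particles that have entered the strait) and open-boundary crossings
are coordinate half-plane tests.  Strait *entries* are detected at the
output cadence (hourly), consistent with an hourly-positions analysis;
the minimum tidal transit of the strait is ~3 h, so hourly detection does
not miss entrants.

Releases are pulses of uniformly seeded positions (rejection sampling on
region ∩ water) at semi-diurnal cadence, snapped to the nearest time
step.  One master seed drives seeding, diffusion and wind through
separate spawned generators, so runs are bit-reproducible.

## Metrics

* **NSI**: release positions are binned on a regular 2-km source grid
  (the mesh-element granularity of the original computation has no
  analogue here, and the index is mesh-agnostic).  The entered/released
  ratio is computed per release cohort, cohort ratios are averaged, and
  cells are normalized by the maximum.  Averaging over cohorts (rather
  than over time or sub-elements) was an open interpretation; it weights
  release pulses equally regardless of size.  Cells with no releases are
  undefined (NaN), never zero; if nothing entered anywhere the whole map
  is flagged undefined rather than normalized by zero.
* **Travel time**: mean particle age at first strait entry, reported only
  for cells with NSI > 0.6 and at least one entrant.  A particle counts
  as an entrant once, at first entry.
* **Entry ratio**: daily cumulative entrants over (cumulative released −
  cumulative open-boundary losses); multi-year runs can be averaged by
  day-of-year.
* **Occupancy**: daily mean over the day's hourly snapshots of the count
  inside the strait (a daily mean was chosen over a fixed daily sampling
  time, which the source description leaves open).
* **Retention**: cumulative Tyrrhenian exits over cumulative entrants.
* **Stranding shares**: percentage of stranding events per 5-km segment;
  the coast ratio is the Calabria total over the Sicily total.

## Experiments and problem sizes

Three protocols are encoded in `workflow.py`, on an abstract 365-day year
(the spawning window "late January to early June" becomes days 25–155;
summer seeding is days 152–244):

| run  | seeding | cadence | desk size | duration |
|------|---------|---------|-----------|----------|
| exp1 | spawning region, days 25–155 | semi-diurnal | 2 016 particles | 210 d |
| exp2 | strait, all year | semi-diurnal | 4 224 | 365 d |
| exp3 | strait, days 152–244 | semi-diurnal | 3 560 | 274 d |

The desk sizes are deliberate scale-downs of the reference protocols
(~10⁴ particles for the connectivity and retention runs, ~8 × 10⁶ for
stranding); share- and ratio-type metrics are scale-invariant up to
binomial noise, which the tests verify by doubling the count.  A
`--scale` factor multiplies particles per release for larger machines.

## Numerical choices and degenerate inputs

Regions are closed sets (boundary points are inside).  Zero-width
channels, islands outside the basin, non-summing wind prevalence rows,
negative speeds or diffusivities, non-multiple output intervals and
empty seeding regions all raise configuration errors.  The cosine tide
averages exactly to the residual over whole periods (the tests check
1 ppm at field points).  Segment ids and numbering origin follow the
constructed polylines; the convention is configuration, not hard-coded.
Biomass rejects non-positive diameters; abundance boundary counts (10,
100) resolve to the lower class; size-class bins are half-open [lo, hi)
with out-of-range diameters reported in an explicit "other" column; a
reference diameter for damaged specimens must be supplied explicitly per
record or imputation refuses to run.

## What the synthetic generator does and does not show

The generator reproduces magnitudes and topology — tidal peak, residual
and basin speeds, the eddy's sense and position, NW wind seasonality,
island obstacles, a gated strait — but not the real bathymetry, the
baroclinic dynamics, internal waves, vertical shear, or the observed
seasonal modulation of the residual circulation.  Consequently the
pipeline's quantitative outputs (entry ratios, travel times, coast
ratios) characterise the idealized seascape, not the real strait; what
carries over is the definitions of the metrics and the qualitative
structure the tests assert: near-channel sources outrank far ones in NSI,
a tidal-only regime retains longer than tidal+residual, symmetric forcing
strands symmetrically, and conservation of particles holds everywhere.
Travel times here (~5 days on average) are shorter than in the real
region (up to ~30 days) because the idealized basin is more compact and
its drift field funnels directly toward the mouth.

Known limitations: the basin drift is not divergence-free; wind speeds
are an assumed distribution; strait entries are sampled hourly; stranding
uses geometric contact with no surf-zone buffer; the exit gates make
leaving the strait terminal, so a particle oscillating across a gate is
counted as exited even if the next flood would have returned it.
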