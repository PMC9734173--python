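# Methods

`reefdrift` models interannual variability in reef-fish larval connectivity
driven by the El Niño–Southern Oscillation (ENSO). It couples a synthetic,
climate-index-forced shelf ocean to a Lagrangian larval-transport model and
aggregates the results into annual region×region connectivity matrices whose
directional structure is regressed on the Southern Oscillation Index (SOI).
This note records the model, its assumptions, the defaults and why they were
chosen, and what the synthetic setting can and cannot show.

## The idealized shelf

The domain is a local Cartesian grid in km (default spacing 10 km), with `y`
increasing northward. The setting is Southern-Hemisphere-like, so *poleward*
means southward (decreasing `y`) and *equatorward* northward. A land strip
occupies the western 20 km; the shelf extends 140 km east of the coast and
1020 km along-shelf. Reef habitat is organized as:

- 15 latitudinal **rows**, 60 km apart, split into three **sectors**
  (northern / central / southern, five rows each);
- two cross-shelf **bands** per row — inshore (centered 45 km offshore) and
  offshore (centered 105 km) — each band a **region**; the southernmost
  offshore slot is dropped, giving 29 regions;
- 141 **reefs** (square polygons, 6 km across, seeded-jitter placement),
  4–5 per region, each occupying its own grid cell, which is also the
  particle seed cell.

Regions carry a strict north→south `latitude_rank` (inshore before offshore
within a row), which fixes the matrix ordering everywhere downstream.

## The synthetic ocean

Hourly horizontal currents on three behavioural depth layers (1, 3, 6 m)
over a 123-day window (Oct 1–Jan 31). For a season with yearly-mean index
value `I`:

```
v(x)        = (γ·I + v0) · shape(x) · s(x)            along-shelf jet
u(x, y)     = −c·|I| · w(y) · s(x)                    shoreward intrusion
            + tide + eddies                           oscillatory/stochastic
```

- `γ = 0.0045 m s⁻¹` per SOI unit and `v0 = −0.04 m s⁻¹`: the jet is weakly
  poleward in neutral years (the East-Australian-Current-dominated mean
  state) and reverses equatorward at `I ≈ +9`, i.e. only under very strong
  La Niña — which reproduces the observed transition from predominantly
  poleward dispersal to equatorward dispersal at high SOI. The amplitudes
  are set so that the strongest El Niño season transports larvae roughly
  250–300 km in one pelagic larval duration — far enough to span several
  regions yet remain on the model shelf — while neutral-year drift stays
  below one region spacing. (The real system shows connections up to
  ~600 km over an ~2000-km shelf; amplitudes here are scaled to the 1020-km
  model domain.)
- `shape(x)` ramps 0.7→1.3 toward the shelf edge (faster outer-shelf flow);
  `s(x)` is a smoothstep taper to zero at the coastline, so velocities
  vanish on land and particles stall rather than beach.
- The shoreward intrusion grows with |I| (Coral-Sea intrusion activity peaks
  at both ENSO extremes) and is confined to latitudinal corridors
  `w(y) = clip(cos 2πy/λ, 0, 1)²` with `λ = 340 km`. Corridors matter:
  a shelf-wide intrusion would displace the entire population shoreward in
  extreme years and convert along-shelf transport into across-shelf
  transport wholesale; localized intrusions instead divert only part of the
  population, which is both more realistic and what preserves the observed
  coexistence of strong along-shelf and across-shelf responses.
- Tide: semidiurnal (12.42 h) cross-shelf oscillation of 0.10 m s⁻¹
  amplitude (0.3 of it along-shelf), giving particles the sub-daily
  excursions that make zone encounters position- rather than phase-locked.
- Eddies: a divergence-free field from a 24-mode random streamfunction,
  AR(1) in time (2-day decorrelation), 60-km spatial scale, scaled to
  0.05 m s⁻¹ rms. This is the only stochastic term; with eddies and tide
  disabled the field is time-constant and seed-independent.
- Depth shear multiplies each layer by (1.15, 1.00, 0.85) — surface
  amplified — so the behavioural depth schedule has dynamical consequences.

The SOI forcing is the Bureau of Meteorology monthly series for the
October–January dispersal seasons 2010–2017 (packaged as CSV), averaged per
season; a seeded AR(1) surrogate generator provides arbitrary-length series
in the same range for experiments.

## Larval transport and biology

- **Release:** 100 particles per seed cell per day (desk-scale runs reduce
  this; connectivity is a probability, so its expectation is rate-invariant)
  over 92 daily releases (Oct 1–Dec 31).
- **Advection:** classical RK4 with a 0.5-h step (resolving the tide against
  hourly snapshots), velocities interpolated bilinearly in space and
  linearly in time. A step ending on a land cell is rejected (the particle
  waits); any integration stage leaving the grid hull marks the particle
  *lost*, and lost particles are excluded downstream. Optional horizontal
  diffusion adds a seeded Gaussian random walk of std `√(2K dt)` per axis;
  the default is pure advection (`K = 0`) since no diffusivity is published
  for the reference configuration.
- **Depth schedule:** day 1 at 1 m, days 2–20 at 3 m, days 21–25 at 6 m,
  switched at the first step after each age threshold.
- **Mortality:** 18 % per day while pelagic, applied as a deterministic
  per-particle weight `0.82^age` (continuous exponent) rather than
  stochastic removal — identical in expectation with far lower Monte-Carlo
  variance; a seeded Bernoulli-thinning mode exists and is tested for
  equivalence.
- **Settlement:** 4-km sensory zones buffered around each reef polygon.
  A larva settles at its **first** zone contact at age ≥
  `competency_start_days`, paying 13 % settlement-predation mortality;
  survival is evaluated at the contact age, not at day 25. No contact by
  the 25-day pelagic larval duration → excluded. Overlapping zones resolve
  to the reef with the nearest polygon boundary, ties to the lower reef id.
  The study default `competency_start_days = 20` places competency at the
  final (6-m) depth stage, consistent with late-stage competency in
  snappers; a default of 0 would let every larva settle into its natal zone
  at release, eliminating dispersal altogether. The function-level default
  of `evaluate_settlement` remains 0 so the rule itself is unbiased; the
  study configuration supplies the biological value.
- The bulk tracker detects zone contact on a 1-km rasterization of the
  zones (exact vector queries at every half-hour step for ~65 k particles
  are prohibitive); the raster applies the same nearest-boundary/lowest-id
  rule, and its boundary error is bounded by half a cell diagonal (~0.7 km
  against a 4-km buffer). The vector path (`evaluate_settlement`) is exact
  and is what the unit tests check the raster against.

## Connectivity statistics

`C[i, j]` = summed settled weights from region *i* to region *j* divided by
the number of particles **released** in *i* (so mortality depresses
probabilities; with the default rates row sums are ≤ 0.87·0.82^20). The
diagonal is retention. Over the eight annual matrices the package computes
the elementwise mean, the per-cell coefficient of variation (sample
standard deviation with n−1, undefined and masked where the mean is zero),
and per-year signed anomalies about the mean (anomalies at float-epsilon
scale classify as zero).

Directional analysis classifies each ordered region pair: retention;
offshore→inshore = across-shelf; inshore→offshore (reported separately);
otherwise poleward/equatorward by latitude rank within a band. Annual
directional means average `C[i, j]` (zeros included) over pairs whose
source is in the central or southern sector, minus the two southernmost
regions (their dispersal directionality differs, as in the reference
system). The poleward share counts realized (> 0) poleward cells as a
percentage of realized along-shelf cells. Poleward and equatorward means
are regressed linearly on the yearly SOI mean (two-sided slope t-test);
across-shelf, with its U-shaped response, quadratically (F-test). The
mean-vs-CV relation is fitted as `mean = a·exp(−b·CV)` by nonlinear least
squares, initialized from the log-linear fit, with r² reported on the
original scale.

## Numerical and design choices

- One master seed; per-year, per-stage substreams derived via
  `SeedSequence(master, spawn_key=(year, stage))`, so years are independent
  and any stage is reproducible in isolation.
- Velocity fields are float32 (a season is ~58 MB per component);
  integration is float64. Closed-form transport checks are therefore exact
  only to single precision (~1e-7 relative), which is what the tests
  assert.
- The eddy field is scaled to its target rms over ocean cells after
  generation, making the noise level exact rather than approximate.
- netCDF I/O uses xarray's scipy backend (NetCDF3) so no compiled netCDF
  library is needed; domain geometry travels as GeoJSON plus a JSON
  descriptor; user-supplied real geometry can be read through the same
  interface.
- Desk-scale defaults used by the tests and the acceptance script:
  5 particles per cell per day (518 880 particles over 8 years), everything
  else at study defaults. An 8-year run takes roughly five minutes on one
  core.

## What the synthetic study does and does not show

The generator reproduces the statistical *structure* the analysis assumes —
index-proportional along-shelf flow with reversal inside the observed SOI
range, |index|-driven shoreward intrusion, stochastic interannual
variability — not the hydrodynamics of any real shelf. Passing the
parameter-recovery tests therefore demonstrates that the pipeline
(transport → settlement → matrices → regressions) correctly extracts a
known forcing signal from noisy Lagrangian data at realistic sample sizes;
it does not validate the oceanography of the reference system, whose
reanalysis currents and reef geometry are not packaged. Reported r² values
from the synthetic study characterize this artificial system only.

Known limitations: retention is under-represented (the jet has no
reef-scale recirculation or flow shadows, so weak-drift years are the only
source of self-settlement); there is no vertical advection (depth is purely
behavioural); larvae do not swim beyond the sensory-zone rule; mortality is
age-only (no temperature dependence or growth); and the open boundary
simply discards emigrants, consistent with excluding non-settlers.
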