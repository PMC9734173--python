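# reefdrift

Biophysical modelling of reef-fish larval dispersal and inter-reef
connectivity over an idealized, climate-index-forced shelf sea — for marine
ecologists and modellers studying how the El Niño–Southern Oscillation
(ENSO) restructures larval connectivity from year to year.

## The problem

Reef-fish populations are connected by pelagic larvae drifting on shelf
currents for a few weeks before settling. On shelves bordering the Coral
Sea, the interannual state of those currents tracks ENSO: weak or negative
Southern Oscillation Index (SOI, El Niño) favors poleward along-shelf flow,
while very strong positive SOI (extreme La Niña) reverses it equatorward.
`reefdrift` provides a full, tested pipeline to quantify that linkage:

1. **Synthetic ocean** — an idealized shelf (29 latitude-ordered regions in
   inshore/offshore bands, 141 reef seed cells) with hourly currents whose
   along-shelf jet is linear in the yearly SOI mean, plus |SOI|-driven
   shoreward intrusions, a semidiurnal tide and stochastic eddies.
2. **Particle tracking** — 100 larvae per reef cell per day released
   October–December, advected by fourth-order Runge–Kutta at a 0.5-h step
   through an age-dependent depth schedule (1 m day 1, 3 m days 2–20, 6 m
   days 21–25) for a 25-day pelagic larval duration (PLD).
3. **Larval biology** — 18 % daily pelagic mortality as survival weights
   `(1−m)^age`; settlement at first contact with a 4-km sensory zone around
   any reef at competent age, with 13 % settlement predation mortality;
   larvae that never reach a zone are excluded.
4. **Connectivity** — annual matrices `C_ij = P(spawned in i → settles in j)`
   with retention on the diagonal; across years the elementwise mean, the
   coefficient of variation `CV = σ/μ` (sample σ, undefined where μ = 0)
   and signed anomaly matrices `C_ij(t) − C̄_ij`.
5. **ENSO analysis** — each ordered region pair is classified poleward /
   equatorward (along-shelf, by latitude rank within a band), across-shelf
   (offshore→inshore) or retention; annual directional means over central
   and southern source regions are regressed on the yearly SOI mean
   (ordinary least squares, linear for along-shelf, quadratic for the
   U-shaped across-shelf response), and the strength–variability relation
   is fitted as an exponential decay `μ = a·exp(−b·CV)`.

See `docs/methods.md` for model equations, defaults and limitations.

## Worked example

A three-year study on the default domain at reduced release rate:

```python
from reefdrift import StudyConfig, run_study

config = StudyConfig(rate=2, seed=7, years=[2010, 2014, 2015])
report = run_study(config)

for s in report.summaries:
    soi = report.yearly_index[s.year]
    print(f"{s.year}  SOI {soi:+6.2f}  "
          f"poleward {s.mean_poleward:.2e}  equatorward {s.mean_equatorward:.2e}  "
          f"poleward share {s.poleward_fraction_pct:.0f}%")

r = report.regressions["poleward_vs_index"]
print(f"poleward vs SOI: slope {r.coefficients[1]:.2e}, r2 = {r.r2:.2f}")
```

prints

```
2010  SOI +20.43  poleward 0.00e+00  equatorward 4.87e-04  poleward share 0%
2014  SOI  -7.83  poleward 1.39e-03  equatorward 0.00e+00  poleward share 100%
2015  SOI -13.57  poleward 1.21e-03  equatorward 0.00e+00  poleward share 100%
poleward vs SOI: slope -4.00e-05, r2 = 0.93
```

Reading this: during the very strong 2010 La Niña (yearly SOI mean +20.43)
along-shelf transport in the central/southern shelf ran equatorward — every
realized along-shelf connection pointed north and mean equatorward
connectivity (the average settlement probability over all equatorward
region pairs) was ~5×10⁻⁴. In the two El Niño seasons the flow reversed:
all along-shelf connections poleward, with mean probabilities ~10⁻³. The
fitted OLS slope of mean poleward connectivity on the SOI is negative
(poleward transport weakens as the SOI rises), explaining 93 % of the
interannual variance in this three-year example.

`run_study` with `outdir` set also writes per-year matrices (CSV), the
year×source×sink netCDF cube, CV/anomaly matrices, directional summaries
and regression results, plus the exact config and seed needed to regenerate
them. The same stages are scriptable from the shell:

```sh
reefdrift full-run --seed 7 --rate 2 --outdir study_out
reefdrift simulate-ocean --outdir stages --years 2015   # netCDF + GeoJSON
reefdrift track --outdir stages --year 2015             # settlement CSV
reefdrift connect --outdir stages --year 2015           # connectivity CSV
reefdrift analyze --outdir stages                       # summary JSON
```

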