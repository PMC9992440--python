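# sargasso

Where does the *Sargassum* stranding on a Caribbean beach come from — and
does its species/morphotype make-up betray the route it travelled?

`sargasso` is a Python package for analysts of pelagic *Sargassum* influxes
(and, more generally, of drifting material with a measurable composition).
It links the seasonal composition of beach strandings — the displacement
volumes of the three morphotypes *S. natans* I, *S. natans* VIII and
*S. fluitans* III per collected clump — to oceanic sub-origins inferred by
backward Lagrangian particle tracking, and tests whether composition and
environmental conditions differ between transport pathways.

## The method

1. **Backtracking.** From each collection date, an ensemble of 100 particles
   is tracked backward 365 days through a year-day surface-current
   climatology (as gridded from drifter fixes) with 0.5% windage and a
   Lagrangian stochastic turbulence model applied per step to each current
   component:

       u′ = u + 0.1 · s · P(1),   s = √(u² + v²),

   with P(1) a standard normal draw.  The ensemble's centre of mass is the
   most probable origin.
2. **Sub-origins.** Each simulation is reduced to (mean distance travelled,
   mean origin latitude) ± 95% CI; K-means (k = 2, z-scored) partitions the
   simulations, and the longer-distance / lower-latitude cluster is pathway
   A (the equatorial meandering route), the other pathway B (the direct
   northern route).
3. **Composition test.** Clump volumes become three-part compositions,
   mapped to bivariate isometric log-ratio coordinates; a PERMANOVA with a
   *date-nested* permutation scheme (whole dates are reassigned between
   pathways; clumps travel with their date) tests composition against
   pathway, with a betadisper-style dispersion-homogeneity check.
4. **Environment test.** SST and chlorophyll-a are box-averaged (≈93,500
   km²) at each origin (365 d back) and trajectory midpoint (183 d back); a
   sequential two-factor PERMANOVA on (SST, √chl) tests period, sub-origin
   and their interaction.

A first-class synthetic module generates every input — a two-regime current
field with a planted seasonal pathway structure, drifter fixes, Dirichlet
compositions whose mean differs by regime, and smooth SST/chl fields — so
the full pipeline runs and is validated without any downloads.  See
`docs/methods.md` for models, parameters and limitations.

## Worked example

```python
from sargasso import StudyConfig, run_study

report = run_study(StudyConfig(seed=1))

print(report.regime_recovery)
print(report.metrics[["simulation", "mean_distance_km", "mean_origin_lat"]].head(3))
print(report.composition_permanova.pseudo_f, report.composition_permanova.p_value)
print(report.sst_pooled_mean)
```

prints

```
1.0
   simulation  mean_distance_km  mean_origin_lat
0  2021-01-10       2577.759465        13.279740
1  2021-01-24       2578.155223        13.283043
2  2021-02-10       2576.169929        13.276208
62.68510381149961 0.0001
{'A': 28.197277915695423, 'B': 25.577238376217036}
```

Reading: every collection date's inferred pathway matched the regime the
synthetic calendar planted for it (`regime_recovery = 1.0`); January
simulations took the short (~2580 km) northern route from ~13.3° N;
morphotype composition differs strongly between pathways (pseudo-F ≈ 62.7,
nested-permutation p = 1/10 000, the smallest value 9999 permutations can
resolve); and origins of pathway A are ~2.6 °C warmer, matching the planted
equatorward SST gradient.

The same study is scriptable: `sargasso run --seed 1 --out study/` writes
the grids, sample table, per-date metrics and the JSON report;
`sargasso synth ...` and `sargasso track ...` expose the generators and the
tracker individually.

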