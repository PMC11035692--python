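# cropfuse

Fusing heterogeneous gridded crop-area datasets into harmonized global
per-crop maps of harvested area (HA) and physical crop area (CA), with
statistical gap filling and adjustment to national reference totals.

## The problem

Published gridded crop maps disagree: they report different variables
(harvested area in ha, physical area in ha, cover fraction *f*, or binary
presence *w*), sit on different grids (0.0000833°–0.0833°), refer to
different years, and carry very different levels of validation.  National
statistics (FAOSTAT-style tables) are authoritative in total but have no
spatial detail; subnational statistical-office (NSO) tables sit in between.
`cropfuse` implements a reproducible construction workflow that turns this
mess into one consistent per-crop product on a common 0.05° grid:

1. **Harmonize** every input to (HA, CA) in hectares on the common grid
   (pixel counting of *w*, CA = *f*·GA, CA imputation for HA-only layers,
   seasonal max/sum rules, mass-conserving regridding, a 100 m² lower
   bound, and the diagnostics CA ≤ HA, CA ≤ LA ≤ GA, CI = HA/CA ≤ 3).
2. **Score** each dataset on seven endogenous indicators in [0, 1]
   (synchrony Q_y, scope Q_a, source Q_s, validation Q_v, resolution Q_r,
   maturity Q_m, dispatch Q_d) and two exogenous ones per crop × country:
   agreement with a cropland consensus map (Q_CAM) and with the national
   reference table (Q_FAO).
3. **Select** the best dataset per crop × country by the combined score

       Q = (Q_y+Q_a+Q_s+Q_v+Q_r+Q_m+Q_d)/21 + Q_CAM/3 + Q_FAO/3

   (the legacy baseline dataset is excluded from the ranking) and mosaic
   the winners, carrying per-cell quality and provenance layers.
4. **Gap-fill** pairs covered only by the legacy dataset by spreading NSO
   subnational totals over the cropland-agreement percentile maps,

       HA(g) = NSO · CAM_p(g) / Σ CAM_p(g),

   iterating p through {2.5, 5, 10, 25, 50} until the 100 m² bound fires.
5. **Adjust** each crop × country to the reference national total with a
   uniform factor under per-cell bounds (100 m² lower, ΣCA ≤ LA upper),
   redistributing excess uniformly, preserving per-cell CI, for at most 60
   iterations or until the country total is within 0.5% of the reference.
6. **Validate** (efficiency-style R², NRMSE, percent error, cropland-bounds
   coverage) and quantify ranking robustness by Monte-Carlo perturbation of
   the nine indicator weights (Gaussian mean 1, sd 0.1, truncated to
   [0.7, 1.3], 10,000 draws).

A first-class synthetic-world generator (`cropfuse.synthetic`) builds
admin masks, land and cropland-percentile layers, degraded datasets in all
four variable conventions, and statistics tables consistent with a retained
ground truth, so the whole pipeline is testable end-to-end without any
downloads.

## Worked example

```python
from cropfuse import gen_world
from cropfuse.pipeline import run_pipeline

world = gen_world()                      # synthetic world, seed 0
result = run_pipeline(world, adjust=True)
print(result.mosaic.table)
```

prints the per-pair selection

```
      crop  country    status acronym         Q
0    maize        1  selected    GOLD  0.987190
1    maize        2  selected    GOLD  0.987190
2    maize        3   gapfill     NSO  0.547619
...
```

meaning the noise-free candidate (`GOLD`, combined score 0.987) wins every
country it covers, while country 3 — covered only by the legacy layer — is
gap-filled from subnational statistics (quality 0.548, computed without the
Q_CAM term because the agreement map itself did the spatialization).
`result.validation` then shows exact national recovery of the withheld
truth (R² = 1.0, NRMSE ≈ 4e-15 for each crop), and
`result.cam_report` shows 100% of cropped cells within the 5th–95th
percentile cropland bounds.

More narrated examples are in `examples/` (one script per capability), and
a thin CLI mirrors the stages:

```
cropfuse make-fixtures --seed 2 --out fx/
cropfuse run --fixtures fx/ --out out/
cropfuse score --fixtures fx/ --out scores/
```

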