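# Methods

This note documents the models, conventions and design choices behind
`cropfuse`, in the order the pipeline runs them.

## Grid and cell geometry

All layers live on a rectilinear WGS-84 latitude/longitude grid with square
cells (default 0.05°, ≈5.6 km at the equator), bounded by ±180° longitude
and ±90° latitude, north-up (row 0 is the northernmost band; cell centres
at `lat = lat_max − (i+0.5)·res`).  Cell areas use the authalic sphere
R = 6,371,007.2 m, so the 0.05° equatorial cell is ≈3,091 ha and the
global sum is exactly 4πR².  The land available for cropping, LA, is
GA·(1 − e) with e the per-cell fraction under water, wetland, urban,
snow/ice and barren cover; LA is accepted as a precomputed exclusion
layer (a helper maps categorical land-cover rasters to 0/1 exclusions),
decoupling the pipeline from any specific land-cover product.  Ocean and
undefined cells carry a single integer no-data code (−1) in admin masks
and a declared fill value in NetCDF files; arithmetic treats no-data as
absent, never as zero.  Files are written in classic NetCDF through
xarray's scipy backend, with variables `harvarea`, `croparea`, `qual`,
`set` and descending-latitude coordinates.

## Harmonization

Variable conventions are unified in a fixed rule order: binary presence at
fine resolution is pixel-counted into cover fractions (fine pixels assigned
by centre when grids do not nest); CA = f·GA with HA imputed equal to CA;
HA-only layers impute CA = HA for permanent crops and
CA = min{HA, LA, CAM95} for temporary crops; CA layers with a
cropping-intensity map use HA = CA·CI; multi-season layers take the
cell-wise max for annual CA and the sum for HA.  Regridding of area
(extensive) layers uses exact fractional-overlap weights on the
(sin φ, λ) measure rather than interpolate-then-rescale: conservation is
then exact by construction (the contract the workflow actually needs),
and it handles non-nesting ratios such as 0.0833°→0.05° without special
cases.  After conversion, HA is floored at CA (CI ≥ 1 where a crop is
present), CA is capped at LA with HA scaled by the same ratio (preserving
CI) so the diagnostics hold for arbitrarily noisy inputs, and cells with
CA < 0.01 ha (100 m²) have both layers zeroed.  The diagnostics
CA ≤ HA, CA ≤ LA ≤ GA and CI ≤ 3 are checked per crop and reported
per cell; the pipeline treats a non-empty report as a hard error.

## Quality indicators and selection

The seven endogenous indicators are closed-form functions of dataset
metadata (piecewise-linear synchrony around the 2020 reference year;
categorical lookups for scope, source, validation, maturity, dispatch;
linear resolution score between 0.0000833° and 0.0833°).  The shipped
registry of 28 published datasets stores the indicator *values* as
authoritative overrides because several published entries are not exactly
reproduced by the formulas; the formulas serve new datasets.  The
exogenous indicators are computed per dataset × crop × country:
Q_CAM is the fraction of the dataset's cropped cells (CA > 0) that are
also cropland in the agreement map, binarized at the most inclusive
(95th-percentile) level so dataset support is not penalized for consensus
conservatism; a crop absent from a dataset in a country scores 0.
Q_FAO = 1 − min{1, |HA − HA_ref|/HA_ref}; pairs missing from the
reference table score 0, and a zero reference with zero dataset area is
treated as a perfect match.

The combined score weighs the endogenous block, Q_CAM and Q_FAO one third
each.  The legacy baseline dataset is excluded from the ranking: a pair
with only the legacy candidate is routed to gap filling, and a single
non-legacy candidate wins automatically.  Ties break on higher synchrony
score, then lexicographically smaller acronym — the rule is arbitrary but
must be deterministic for reproducibility.  The mosaic paints the winner's
combined score uniformly over the country's cells (the score is defined
per crop × country) and records an integer provenance code per cell.

## Gap filling

Subnational totals are spread over each unit proportionally to the
cropland-agreement map at percentile p.  The percentile iterates upward
through {2.5, 5, 10, 25, 50}; it stops at the first p at which some
positive-weight cell falls below 0.01 ha, and those cells are clamped to
the bound (if no percentile triggers, the median map is used).  Clamping
is not re-balanced — the unit total may exceed the tabulated value by the
clamp surplus, which the national adjustment later absorbs.  Finalization
caps CA = min{HA, LA, CAM95} and sets HA = CA (CI = 1 for gap-filled
cells).  Units without statistics fall back to the legacy layer unchanged.
The quality of gap-filled layers drops the Q_CAM term (the agreement map
itself did the spatialization) with the remaining weights unchanged, so it
ranges over [0, 2/3]; the literal dropped-term form is used without
renormalization.

## National adjustment

Each iteration, in fixed order (sorted crop ids, for determinism): scale
every targeted crop by one factor bringing its national HA to the
reference value, CA scaled identically so per-cell CI is preserved;
enforce the upper bound — in cells where the all-crop ΣCA exceeds LA the
excess is attributed to crops proportionally to their CA share (scale-free
and order-independent) and returned to each crop's other occupied,
non-violating cells in equal per-cell increments capped by cell headroom
(receiving HA uses the receiving cell's own CI; cells where the crop is
absent are ineligible); enforce the lower bound — cells with
0 < HA < 0.01 ha are raised to the bound and the added area removed in
equal per-cell decrements from the crop's other occupied cells without
driving any below the bound.  Unallocatable amounts are reported as
residuals, never silently dropped.  Iteration stops at 60 rounds, when the
country's summed HA is within 0.5% of the summed reference, or when it
changes by less than 0.01% in a round.  Crops and countries absent from
the reference table are untouched.

## Validation and uncertainty

R² is the Nash–Sutcliffe efficiency form (may be negative; no flooring);
NRMSE divides RMSE by the reference range; records missing on either side
are dropped pairwise and counted.  The cropland coverage check classifies
cells with total CA > 0 as below / within / above the 5th–95th percentile
cropland bounds; the three fractions partition the cropped set.  The
Monte-Carlo analysis draws the nine indicator weights i.i.d. from
N(1, 0.1²) truncated to [0.7, 1.3] by resampling (clipping would put
probability atoms on the bounds) and counts how often the weighted argmax
differs from the unit-weight winner, only for pairs with at least two
non-legacy candidates; one shared weight matrix serves all pairs.

## Synthetic worlds

The default world is a 40 × 80-cell window of the real 0.05° grid
(40–42° N, 0–4° E; cell areas ≈2,300 ha) with a 2-cell ocean frame, three
countries as column strips, each split into two subnational units; three
crops (wheat and maize temporary, oil palm permanent) as smoothed random
fields thinned to leave crop-free cells, jointly capped at 50% of LA so
the adjustment stage has slack; truth CI varies smoothly in [1, 1.5].
The cropland-agreement stack is built from truth total CA with percentile
multipliers 0.6–1.3 and support that thins at low percentiles, so the
truth lies within the 5th–95th bounds everywhere it is cropped.  Reference
tables are exact zonal sums of truth (optionally perturbed).  Degraded
datasets apply multiplicative lognormal noise (σ = 0.2 by default) to area
content — the same factor on HA and CA, as measurement error scales both —
Bernoulli flips (5%) to binary pixels, block-sum coarsening, and
deterministic sub-pixel fill patterns for binary refinement (so pixel
counting recovers fractions up to 1/k² quantization).  The standard suite
has a coarse legacy dataset covering all countries, a noise-free
full-convention dataset and two noisy rivals covering a subset, leaving
one country legacy-only: both selection branches are always exercised.

What passing tests on these worlds do *not* show: real landscapes have
spatial autocorrelation, systematic (not multiplicative-independent)
sensor error, inconsistent crop naming, and admin boundaries that do not
follow grid lines; the synthetic generator emulates none of these beyond a
smoothing kernel, so end-to-end exactness here demonstrates algorithmic
correctness, not real-world accuracy.  Problem sizes (40 × 80 cells,
3 crops, 10,000 Monte-Carlo draws) were chosen so the full suite and the
acceptance script each run in seconds while every code path is exercised;
the production-scale grid (3600 × 7200) differs only in array size.

## Known limitations

- The end-to-end parameter-recovery limit holds at the national level:
  gap filling sets CI = 1, which changes subnational HA totals before the
  national adjustment rescales them, so subnational recovery in gap-filled
  countries is approximate by design.
- The upper/lower-bound redistributions are uniform per cell, not
  suitability-weighted; heavily constrained countries converge to the
  iteration cap with reported residuals rather than an optimal layout.
- Cropland-bounds coverage of the final product varies with the seed
  (gap-filled countries follow the agreement map, not the truth pattern),
  which is the realistic behaviour of the statistic, not a defect of the
  check.
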