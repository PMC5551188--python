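# Methods

## The synthetic city and its truth process

The generator builds a planar 20 × 20 km metro area (local metric CRS, y
north) on a 50 m land-cover lattice: a high-intensity core with a secondary
node, medium-density development, park-like developed open space
interspersed through the urban envelope, peripheral tree canopy
(deciduous/evergreen/mixed sub-layers that extraction sums into a single
"trees" category), shrub/grassland/pasture/crop patches, two freeway
corridors (AADT 150 000 and 65 000), arterial and local road grids, one
rail line, three point emitters (900/650/520 tons NOₓ/yr, mirroring a
metro area with three large permitted sources), housing, elevation, and
1 km population blocks allocated dasymetrically to cells.

Two structural choices matter for identifiability and were made
deliberately:

- **Fine-scale texture.** Each areal field is modulated by sub-100 m
  multiplicative texture. Real 30 m land-cover products are patchy well
  below the buffer radii; without texture, the 12 buffer sums of a category
  correlate above 0.97 with one another and buffer-size selection is
  unidentifiable in principle.
- **Corridor zoning.** Housing is damped within ~400 m of freeways
  (industrial/commercial corridor zoning), so the population living in the
  narrow high-exposure freeway corridor is small — the demographic feature
  that makes traffic scenarios matter much less for area-wide incidence
  than canopy scenarios.

The truth process is additive per category:
`m_season · [background + Σ s_c·K_c(x)]`, floored at 0.5 ppb. Line classes
use `exp(−d/L)` of the distance to the nearest segment (the freeway kernel
additionally scales with the nearest segment's AADT); emitters sum
`(tons/500)·exp(−d/500 m)` over sources; areal categories use the mean
cover fraction within a fixed density radius (housing: units/ha against a
20 units/ha reference). Defaults: background 8.5 ppb; strengths +6
(freeway at reference AADT), +2/+1.2/+1/+0.8 (primary/secondary/local/rail),
+0.8 (emitters), +3.5/+1.5/+0.8 (high/medium development, housing),
−3/−1.2/−0.8 (trees, open development, shrub); decay lengths 150–500 m;
seasonal multipliers 1.0 (summer) and 1.2 (winter); observation noise
σ = 1 ppb, truncated at 0.5 ppb as passive samplers report positive
concentrations. Additivity makes every category's ground-truth attribution
exactly `m_season · s_c · K_c`, which the recovery tests exploit.

Calibration: with these defaults the summer truth surface spans ~7–21 ppb
and seasonal site means land at ~10.5 (summer) and ~12.3 (winter) ppb,
inside the ±2 ppb bands around the 11/13 ppb field-campaign summaries the
generator emulates. Site sampling over-weights freeway/arterial corridors
and vegetation gradients, as monitoring campaigns of this type do.

What the generator does **not** emulate: meteorology and wind-driven
anisotropy, atmospheric chemistry (NO/NO₂/O₃ cycling), temporal variation
within a season, terrain channelling, and spatially correlated measurement
error. Passing recovery tests therefore shows the *statistical machinery*
is sound — not that a forest recovers causal effects in a real atmosphere.

## Buffer features

~200 predictors per location: 16 categories × 12 radii (100–1200 m) plus
x, y, elevation. Areal buffers count a cell's `area × fraction` when its
center lies in the disc (clipped at the study extent, no renormalisation);
line lengths use closed-form segment–disc chord clipping; freeway VMT is
Σ AADT × miles-in-buffer; emissions and housing are sums of
points/counts in the disc. Units follow field conventions (ha, km,
vehicle-miles/day, tons/yr). All features are non-decreasing in radius by
construction, and the brute-force cell-scan oracle in the tests agrees to
float precision.

## Forest engine and importance

The forest is a transparent CART/bagging implementation with a fixed,
documented randomness protocol (per tree: bootstrap draw, then depth-first
left-first growth with an `mtry`-subset draw per splittable node), enabling
an exact-match brute-force oracle in the tests. Minimum node size is 5, no
depth limit, squared-error loss throughout; predictions are means over
trees and are additionally clipped to the training response range.

Conditional permutation importance permutes a predictor within strata
defined by the split points that each tree uses for covariates correlated
with it above |r| = 0.2. Two implementation details:

- a tree that never splits on a variable contributes an exact zero and is
  skipped (large speedup, no approximation);
- the conditioning set is capped at the 20 most-correlated covariates.
  With ~200 mutually correlated predictors the full conditioning grid
  collapses every stratum to a single observation and all importances
  vanish; the cap keeps the correction effective (duplicated-predictor
  importance is properly deflated in the tests) while preserving signal.

## Two-phase selection, sweep, and the LUR baseline

Phase 1 fits one forest (default 300 trees, mtry = p/3) on all buffer
columns and keeps the radius with the highest conditional importance per
category (all-zero categories are flagged degenerate and get the smallest
radius). Phase 2 sweeps ntree × mtry over seeds — the full grid
(500–5000 × 1–8) is the function default; desk-scale runs use reduced grids
— and selects the lowest mean OOB RMSE, ties toward smaller ntree then
mtry, refit with the first seed ("robust model" rule; the choice of rule is
ours, made for reproducibility).

The LUR baseline prunes |r| > 0.7 pairs (keeping the earlier column),
searches bidirectionally by AIC, retains up to four candidates under a VIF
ceiling of 5, and picks by 6-fold CV RMSE. Stepwise direction, thresholds
and the ceiling are configurable since standard practice varies.

## Surfaces, attribution, scenarios, health

Predictions are made at cell centers of a regular grid (200 m convention;
the shipped configs use 400 m to keep desk-scale runtimes in minutes) and
averaged cellwise across seasons. Attribution zeroes all radii of one
category (or a group — freeway length and VMT are also attributed jointly,
since the generative freeway kernel is traffic-weighted and the two
predictor families split credit) with **no rebalancing**; the modification
engine, by contrast, changes areal cover by percentage points of the buffer
disc area at every radius, proportionally rebalances the other areal
categories so the areal total is preserved where possible, clamps to
[0, 100] %, and treats VMT deltas as global multiplicative scalings with no
rebalancing. The two procedures are deliberately distinct operators.

Health impacts use Δy = y₀·(1 − e^{−β·ΔC})·Pop per cell with ΔC > 0
meaning added NO₂. The shipped endpoint registry (asthma exacerbation in
4–12-year-olds, cough in 7–14-year-olds, asthma ER visits 75+, respiratory
admissions 65+) is a synthetic stand-in: the β/y₀ pairs are plausible-scale
configuration values, clearly labelled, because the real coefficients for
such analyses live in tool databases that are not printed in journal text.
Age-band populations are fixed fractions of the total (4–12: 11 %, 7–14:
10 %, 65+: 16 %, 75+: 7 %). Population reaches the grid by areal-weighted
polygon allocation (conserving totals); the worst-NO₂-quintile scope masks
cells at or above the 80th percentile of the annual surface.

## Numerical choices and degenerate inputs

Ties in split search break toward the earlier feature in the drawn subset,
then the smaller threshold, with strict improvement required; a split whose
float midpoint fails to separate the node becomes a leaf. Constant
responses yield single-leaf trees with a warning. Metrics require strictly
positive observations (relative errors are undefined otherwise) and flag
R² as undefined for constant series. A constant surface makes the worst
quintile the whole area, with a warning. All stage seeds derive from one
global seed by fixed offsets; truth-term summation iterates categories in
sorted order so float results are identical across processes.

## Known limitations

- Buffer-radius recovery for exponential line kernels is information-
  limited: neighbouring radii correlate > 0.99, so Phase-1 selection
  scatters over ~2–4× the kernel scale rather than pinning it to ±100 m.
- Random-forest counterfactuals attenuate toward zero (zeroed inputs sit at
  the edge of the training support), so attribution magnitudes
  underestimate generative truth by roughly a third to a half; correlated
  predictor families (housing vs development vs road density) additionally
  split credit.
- Cellwise responses to opposite-signed scenarios are not antisymmetric —
  a forest responds as a step function — although study-area mean responses
  are.
- The synthetic health coefficients make incidence *levels* meaningless;
  only signs, spatial patterns, and relative magnitudes between scenarios
  are interpretable.
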