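# Methods

This note documents the statistical model behind `telefire`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not demonstrate.

## Data model

All stages operate on monthly data: a burned-area (or 95th-percentile fire
radiative power) cube `(time, lat, lon)`, one cube per mediator, a scalar
series per teleconnection index, and a boolean burnable mask.  Masked
cells carry NaN at every time step.  Time axes must be consecutive
calendar months; misalignment is an error, never silently reindexed.

## Preprocessing

**Fire season.** Per cell, the 12-month climatology of summed burned area
is scanned with circular 3-month windows; the window with the highest
accumulated total is the fire-season peak.  Circularity matters for
Southern-Hemisphere (DJF-type) seasons.  Ties break to the earliest
calendar start month — deterministic and order-independent.  Cells with no
burned area at all have no fire season and are excluded downstream.

**Trend and seasonality.** Teleconnection indices are detrended by OLS on
the time index over the full record.  Mediators and burned area need both
the trend and the monthly climatology removed.  These two projections do
not commute: one pass of detrend-then-subtract-month-means leaves a
residual trend of order 1e-4 for typical inputs, because the month-mean
projection of a trend is not flat.  The pipeline therefore removes them
*jointly* — one least-squares projection onto {12 month indicators,
centered time} — which is the limit of alternating the two single steps
and leaves residuals with exactly zero per-month means and zero OLS slope.
The standalone `detrend` and `monthly_anomaly` functions keep their
single-step definitions.

**Sample frame.** The regression response is the burned-area anomaly at
the three fire-season months of each year (three samples per year, not a
seasonal aggregate; a `season_aggregate` switch collapses each season to
its mean for one sample per year).  Lagged predictors shift only backward
in time — a predictor always coincides with or precedes the fire month.
Years whose worst-case lag (24 months) would reach before the record start
are dropped for *every* lag, so all 25 lags share an identical sample
size and their R² values are comparable; a 22-year record with max lag 24
yields 3 × 20 = 60 samples.  Cells with fewer than 10 samples are flagged
insufficient and excluded.

## PLSR predictability

The per-cell design is the 25 lagged copies of one index (75 columns for
the combined three-index model).  Columns are centered and scaled to unit
variance — lagged copies of one index share scale, but scaling keeps the
multi-index model well-posed across modes with different variances.  The
PLS1 (univariate-response NIPALS) recursion is implemented in-package; its
components are nested, so one fit per cross-validation fold yields
predictions for every candidate component count k.  This is what keeps the
thousand-cell calibration runs cheap.  scikit-learn's independently coded
`PLSRegression` serves as the oracle in the test suite (agreement to
1e-8 relative on random designs); with one predictor the fit collapses to
simple OLS exactly, and with k equal to the design rank to multiple OLS.

**Protocol.** k is selected on the 70 % training split by 10-fold
cross-validation minimizing mean squared prediction error over k = 1..10
(ties to the smallest k).  The 70/30 split is stratified by year (each
year contributes one of its three season samples to the test set), which
avoids whole-season leakage imbalance.  Predictability is the coefficient
of determination between predicted and observed burned area on the
held-out 30 %.

**Significance.** PLS components are response-supervised: the first
component is built from X'y, so the classical F-test of the response on
the k component scores (numerator df = k) is strongly anticonservative
under the null — measured rejection near 0.9 at nominal 0.05 for a
60 × 25 null design.  The package therefore evaluates model significance
on the held-out split: the F-test (equivalently the two-sided correlation
test) of observed against predicted test-set values, which is exactly
calibrated because the predictions are independent of the test responses.
Measured null rejection is 0.04–0.05 over a thousand cells.  The
training-data variant remains available as `p_value_mode="train"` for
comparison; it is not the default precisely because of its null behavior.
No multiple-testing correction is applied across cells (an FDR switch
would sit naturally on top; per-cell 0.05 gating is the baseline
behavior).

## Hot spots (Getis-Ord Gi*)

The clustered field is the per-cell *maximum test R² over all indices*,
without the significance gate.  Significance defines "predictable" for
the area-fraction summaries; the Gi* field itself must stay continuous —
replacing non-significant cells by zero produces a spike-at-zero mixture
that breaks the normal approximation and manufactures hot spots out of
chance-adjacent significant cells (measured: ~25–30 % of null worlds grew
a spurious region under the gated field, ~0 % under the continuous one).

Gi* uses binary queen-contiguity weights including the focal cell (the
closest well-defined analogue of a fixed-distance band on a regular grid;
the scheme is configurable), global mean and population standard deviation
over all finite burnable cells, and the classic variance term
`(n·Σw − (Σw)²)/(n−1)`.  Neighborhoods wrap across the longitude seam so
regions straddling ±180° are contiguous.  p-values come from the normal
approximation, as in the standard GIS implementation, with an optional
permutation mode (random relabeling over valid cells) as a calibration
check.  Classification tiers are two-sided at 0.10/0.05/0.01; hot-spot
regions are rook-connected components of hot-99 cells with at least
`min_cells` (default 5) members, with area fractions relative to the
burnable mask.

## Lag profiles

Per hot spot and index: Pearson correlation between the fire-season
response and each lagged copy, two-sided p, correlations gated to zero at
p > 0.05.  The per-lag mean of absolute gated correlations divides by the
count of *all* region cells (cells contribute zeros where not
significant); a `denominator="significant"` mode divides by the count of
significant cells instead, since the two conventions appear
interchangeably in practice.  Profiles are normalized by their maximum to
the 0–1 scale (all-zero profiles stay zero rather than erroring).
Positive/negative fractions split the absolute-correlation mass by sign at
each lag and sum to one wherever any mass exists.  Plain Pearson p-values
are used; no autocorrelation-adjusted effective sample size.

## Mediation pathways

For each (cell, index, mediator) and each lag pair (i, j) with
i + j ≤ 24 — 325 pairs — three univariate OLS regressions on the shared
sample frame: burned area on the index at lag i + j; the mediator at lag j
on the same index; burned area on the mediator at lag j.  The mediator
enters as its anomaly sampled j months before each fire-season response
month, on the same frame as the response, so the three regressions are
comparable.  Regressions 2 and 3 run only when regression 1 is significant;
the contribution is R₁²·R₂² when all three p-values are below 0.05 and
zero otherwise.  R₃² is recorded for diagnostics but never enters the
score — only its p-value gates.  The bulk path evaluates the 325 pairs
from three correlation tables (R₁²/p₁ depend only on i + j, R₃²/p₃ only
on j, R₂²/p₂ on the pair), which the tests verify against the explicit
per-pair regressions.

Contributions are summed over lag pairs and cells per (hot spot, index,
mediator); mediator fractions divide by the total over mediators (rows
with zero total are flagged undefined rather than divided).  Group
comparisons use both the sum and the maximum over the weather
{Tmax, ET0, VPD, Wind} and fuel {NDVI, EVI, FPAR, SM} groups, at hot-spot
level (including an all-index aggregate) and per cell.  Sums are reported
raw; they scale with region size, so cross-region comparisons should use
the per-cell frames.  By default the stage runs over extracted hot-spot
cells; `pathways_scope="global"` runs it everywhere.

## Synthetic worlds

The generator emulates the statistical structure the pipeline assumes, not
any specific climate: indices are stationary unit-variance AR(1) processes
(default lag-1 coefficient 0.5); mediators are seasonal cycle (sinusoid
with per-variable phase, default amplitude 0.5) plus linear trend (default
0.002 units/month) plus unit Gaussian noise, with the planted region
adding `sign · strength · TCM(t − i)`; burned-area anomalies add the
standardized mediator anomaly (signal plus mediator noise — a genuinely
noisy two-link chain) at lag j, scaled by `strength`; the burned-area
climatology has three dominant consecutive months so the fire-season
detector's target is part of ground truth.  With unit noise, `strength s`
gives a true per-link R² of s²/(s²+1) — 0.5 at s = 1, the "moderate
noise" setting used by the recovery studies.  Defaults mirror a 22-year
record with all 11 indices and all 8 mediators.  Reproducibility: one
root seed, split per variable by fixed spawn keys, so adding a mediator
never perturbs the index or burned-area draws.

What the generator does *not* emulate: skewed/zero-inflated burned-area
marginals (an exponential link is available but the default is
anomaly-scale Gaussian), spatially correlated noise, observational
artifacts, or cross-correlated indices.  Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the model's
own assumptions, not performance on satellite archives.

## Problem sizes in the verification runs

The acceptance script and test suite choose sizes that make the Monte
Carlo bands tight while keeping a laptop run short: 100 random 60 × 25
designs for the PLS oracle, 50 random 20 × 20 grids for the Gi* oracle, a
32 × 32 null world (1,024 cells) for type-I calibration, 20 null worlds
(12 × 12, two indices) for the end-to-end null, and 50 seeded worlds each
for lag recovery (3 × 3 region, i = 4, j = 6, strength 1) and mediation
recovery (2 × 2 region, soil-moisture pathway, strength 1).

## Known limitations

- The three-step contribution score is correlational; it cannot separate
  a genuine mediated chain from a direct effect plus a mediator that
  shares the driver (no product-of-coefficients or counterfactual
  mediation machinery, by design).
- Pearson p-values ignore serial dependence within the three monthly
  samples of one fire season; with strongly autocorrelated responses the
  lag-gating rate will run slightly liberal.
- The Gi* normal approximation is exact only for moderately sized
  neighborhoods relative to the field; the permutation mode exists for
  checking doubtful configurations.
- Regions are extracted from the hot tail only; cold spots are classified
  but not componentized.
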