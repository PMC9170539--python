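# Methods

This note documents the models and procedures `camsdm` implements, the
defaults that matter, the numerical conventions, and what the synthetic
test system does and does not establish about real data.

## Raster model and conventions

All stages share one raster convention: WGS84 lon/lat grids with square
cells, north-west origin, and half-open cells `[edge, edge + cell_size)`
— a point exactly on a shared edge belongs to the cell to its
south/east. Every point→cell mapping (thinning, extraction,
pseudo-absence placement) uses `floor((coord − origin)/cell_size)`, so
there is a single unambiguous convention across the package. Nodata is
carried as NaN and handled by masking, never by sentinel arithmetic;
any operation with a nodata operand yields nodata. Inputs in other
coordinate systems are rejected rather than silently reprojected.

Resampling is bilinear for continuous fields and nearest-neighbour for
categorical ones, via regular-grid interpolation on cell centers;
bilinear output can never leave the `[min, max]` of the source values,
and resampling onto the source grid is the identity. The collinearity
screen reports pairwise Pearson r over cells valid in all layers and
flags `|r| ≥ threshold` (default 0.7, configurable — a conventional
screening level, not a derived constant); it never drops layers itself,
because predictor choice is a modelling decision.

GeoTIFF I/O is implemented directly over TIFF with the standard
georeferencing tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA);
ESRI ASCII grids are supported as a plain-text raster format, and
monthly series travel as NetCDF3 (`time, lat, lon`) or a `YYYY-MM`
GeoTIFF directory. Values are written at full float64 precision so
write→read round-trips are bit-exact.

## Climate predictability indices

Annual totals use a strict per-cell completeness rule: a calendar year
contributes only where all 12 months are valid, and incomplete years
are dropped per cell rather than globally so coverage is preserved at
the edges of the record. The Hellmann–Eberle quotient
`Q = max_year / min_year` needs at least two complete years; a driest
year of exactly 0 mm is masked to nodata rather than mapped to
infinity — a ratio map must stay finite for downstream learners, and a
truly rain-free year is indistinguishable from a data gap at this
scale. `Q ≥ 1` wherever defined, equals 1 iff all totals are equal, and
is invariant to rescaling all years by a positive constant.

The Ellenberg map flags cells where mean annual precipitation (over
complete years) is below 500 mm *and* `Q > 5` — dry and erratic, the
combination under which stem succulents are absent. Both thresholds are
parameters. The aridity index `P/PET` and R-index `AET/PET` consume
published evapotranspiration rasters as inputs; non-positive PET masks
to nodata, and AET > PET warns but passes through unclamped.

## Occurrences

The validity filter is a deliberately reduced subset of full
archive-cleaning protocols: non-finite or out-of-range coordinates, the
exact (0, 0) placeholder, and exact coordinate duplicates beyond a cap
(kept lowest record-id first, deterministically). Thinning retains at
most 5 records per 1°×1° cell on a lattice anchored at integer degrees
(the natural reading of a 1° graticule); selection inside over-full
cells is uniform random under a per-cell derived seed rather than
first-n, which would encode source ordering bias. Thinning is
idempotent and never invents records. Extraction reads the containing
cell's value with no interpolation and drops (counting) points on
nodata or outside the grid.

## Envelope and pseudo-absences

The surface range envelope takes per-predictor `[q, 1−q]` empirical
quantile bounds of presence values, with linear interpolation between
order statistics (the estimator must be pinned for reproducibility;
default `q = 0.025`, roughly a 95% tolerance interval). Membership is
inclusive at the bounds, so the `q = 0` envelope contains every
training presence, and the envelope shrinks monotonically as `q` grows.
The envelope is fit on all thinned presences before splitting
(configurable); pseudo-absences are drawn uniformly without replacement
from cells outside the envelope that have valid data and hold no
presence (preventing label contradiction at a cell), one independent
seeded draw per realization, points at cell centers. Uniform-over-cells
is the default; latitude-area weighting is not applied because the
envelope exclusion rule names areas, not cell masses, and desk-scale
grids span few degrees.

## Learners, splits, ensembles

Tree induction is delegated to scikit-learn: gradient boosting
(`n_estimators=250, learning_rate=0.1, max_depth=3`) and random forests
(`n_estimators=500`), both seeded; these are documented package
defaults in the spirit of using an established implementation's
standard settings. Each run's 60/40 split is stratified by label to
preserve the engineered 1:1 presence:pseudo-absence balance, and each
repeat gets a fresh split seed and learner seed — that is what makes
repeats informative. All skill scores come from the held-out 40% only.

Ensemble weights are proportional to held-out TSS (negative TSS clamped
to 0; ROC weighting selectable), with members excluded unless ROC AUC
strictly exceeds 0.5; if all included scores clamp to zero the included
members share uniform weights. The ensemble map is the per-cell
weighted mean (a convex combination, so it stays inside the member
envelope); uncertainty is the per-cell coefficient of variation,
100·sd/mean with unweighted sample (n−1) sd, masked where the mean is
zero. Ensemble-level scores use pooled-held-out evaluation: the full
ensemble predicts each member's own test rows, and the pooled pairs are
scored once. This choice (rather than averaging member scores) is
documented because either reading is defensible.

## Evaluation conventions

`TSS = sensitivity + specificity − 1` exactly; ROC AUC is the
Mann–Whitney probability with ties counted ½. A prediction exactly at a
cutoff counts as positive, everywhere in the package (evaluation and
map binarisation share the rule). The optimal cutoff maximises TSS over
data-adaptive candidates — midpoints between adjacent distinct
prediction values plus {0, 1} — which is exact and cheap; ties resolve
to the smallest cutoff. Scores are kept at full precision internally
and rounded to 3 decimal places only in report CSVs.

## Variable importance

For each predictor, its column in the reference table is permuted
(seeded), the ensemble re-predicts, and Pearson r is computed against
the reference predictions. Raw importance is the mean of
`max(0, 1 − r)` over shuffles: 0 means the predictor has no influence,
larger means more. The lower side is clamped at 0 (an anticorrelated
shuffle still indicates influence); values above 1 pass through. Raw
importances are standardized proportionally to percentages summing
to 100. Importance is computed on the pooled reference table (presences
plus all pseudo-absence realizations). The reference shuffle count is
10; importance percentages are Monte-Carlo estimates and stabilise as
the count grows.

## Area accounting

Cell areas use the spherical band formula
`R² · Δλ · (sin φ_top − sin φ_bottom)` with R = 6371 km; at the
3-significant-figure precision of continental totals an ellipsoidal
Earth changes nothing. Suitable area sums cell areas over cells flagged
1 (optionally within a user-supplied region mask — masks are inputs,
never built in) and reports million km². Deviation maps are signed
continuous differences (scenario − baseline, positive = more suitable);
a gain/loss/stable binary variant is also provided.

## Scenario design and seeding

Scenario 1 is the four bioclim-style predictors (mean diurnal range,
minimum temperature of the coldest month, annual precipitation,
precipitation seasonality); scenarios 2–5 add exactly one of the
Hellmann–Eberle quotient, aridity index, cloud cover, or R-index. The
full design is 2 algorithms × 5 realizations × 10 repeats = 100 models
per scenario ensemble, 500 across scenarios. A single master seed fans
out to every randomised stage through
`blake2b(master:stage:indices) mod 2³¹`, so stages are independent yet
the whole run is reproducible from one integer, with no unseeded
randomness anywhere.

## The synthetic system

The generator emulates the *assumed structure* of the real inputs, not
their full statistics: climate fields are low-pass-filtered Gaussian
noise with a common-factor cross-correlation (restricted to
non-negative pairwise correlation, since equal pairwise negative
correlation is infeasible for more than two fields); annual rainfall
totals are lognormal (non-negative, right-skewed, with closed-form
variability control), parameterised with median = `mean_annual` so the
quotient is unaffected by the location choice, and spread over months
by a fixed sinusoidal profile; the true niche is a product of logistic
/ Gaussian response curves; presences are sampled ∝ suitability ×
observer bias and jittered within cells so the cell conventions are
exercised off centers.

The default desk-scale system is a 64×64 quarter-degree grid, seven
fields with field-realistic means/sds and 0.3 cross-correlation, a
58-year monthly record at log-sd 0.4, a niche with logistic midpoint
10 °C on minimum temperature (dominant) and Gaussian center 520 mm on
annual precipitation (secondary), and 500 biased presences. Tests run
the pipeline on it at a scaled 2 × 2 × 2 design; the bookkeeping logic
is identical at the full 2 × 5 × 10 size, which is verified
arithmetically.

Passing the niche-recovery checks on this system shows the pipeline's
plumbing and statistics are sound — it does **not** show that any real
species' niche is recoverable: real occurrence data carry taxonomic
error, non-climate constraints (competition, dispersal, land use),
and bias structures richer than a smooth effort field, and real
predictors are not Gaussian fields.

## Known limitations

- Presence-only design: "absences" are pseudo-absences by construction,
  so suitability is relative, not a detection probability.
- Only the two tree-ensemble algorithms are provided; no GLM/GAM/MaxEnt,
  hyperparameter tuning, or spatial cross-validation.
- No reprojection; lon/lat WGS84 in, lon/lat WGS84 out.
- Permutation importance measures direct single-variable influence and
  is blind to interactions; correlated predictors share credit
  unpredictably.
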