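# Methods

This note documents the models and procedures `sdmrisk` implements, the
choices made where the design was genuinely open, and what validation on
the simulator does and does not establish.

## Spatial model

All data live on one WGS84 lon/lat lattice: north-up, row 0 the
northernmost row, cells half-open `[edge, edge + cell_size)` on both
axes, 0-based indices.  The occurrence-thinning grid defaults to
0.0833333° (≈10 km at subtropical latitudes); the package never
reprojects — inputs must share the grid.  Cell areas are spherical,
`A = R²·Δλ·(sin φ_top − sin φ_bottom)` with R = 6371.0088 km, constant
per row; synthetic tests may switch to unit cell areas
(`area_mode="unit"`) to reason in cell counts.  Rasters are plain-text
ESRI ASCII grids — an axis-aligned, square-cell dialect that matches this
lattice exactly and keeps every fixture human-readable; rotated or
sheared geotransforms are unrepresentable in it and out of scope.

## Data preparation

**Spatial filtering** keeps the first point encountered per occupied
cell; the operation is idempotent and the output count is the number of
distinct occupied cells.

**Collinearity pruning** is a greedy scan in a user-supplied priority
order (default: stack order): a variable is kept iff its Pearson |r|
with every already-kept variable is ≤ the threshold (default 0.8).  The
priority list externalises the expert judgment of which of two collinear
variables is "more relevant and easier to interpret" — that judgment is
not an algorithm, so it is configuration.  Correlations are computed on
a seeded random sample of at most 10⁴ cells (scale-free, deterministic
under seed), pairwise over cells valid in both layers; fewer than 3
shared valid cells for any pair is an error.  Categorical layers pass
through untested.

**Pseudo-absences** are sampled uniformly *without replacement* at cell
level (duplicates would add no information) from cells where the
presence SRE envelope is 0, excluding presence cells and cells with any
missing predictor.  The default count equals the presence count
(balanced classes by construction) with a per-species override, since
reasonable designs range from balance to a few hundred or thousand
fixed background points.  Three replicate background draws are the
default, each seeded deterministically from the base seed.

## Learners

Only two algorithms are native; everything else joins through
`register_adapter`, which runs a contract suite (scores in [0, 1],
bit-identical predictions under a fixed seed, column-order invariance)
and refuses violators at registration time.  The ensemble arithmetic is
agnostic to the member roster, so the canonical nine-algorithm roster is
a configuration, not a code path.

* **SRE** (surface range envelope): per-variable empirical `q`/`1−q`
  quantile bounds (linear-interpolation quantile) of the presence
  values; a row scores 1 iff every continuous variable lies inside its
  interval, bounds inclusive (deterministic tie behaviour at quantile
  edges).  Default `q = 0.025` per side — the conventional envelope
  default in this modelling tradition — and configurable.  The envelope
  doubles as the pseudo-absence exclusion zone.
* **GLM**: logistic regression via iteratively reweighted least squares
  (statsmodels, Binomial family, tol 1e-8, ≤100 iterations), quadratic
  terms for continuous variables by default (`degree=2`; a Gaussian
  niche is a quadratic on the logit scale), categorical variables
  one-hot encoded against the first observed level.  Perfect separation
  or IRLS failure falls back to a ridge penalty of 1e-6 with a warning.
  Unseen category levels at prediction time map to the reference level.

## Evaluation design

Each pseudo-absence replicate is split into 70 % calibration / 30 %
evaluation, five times.  The five repeats are *independent stratified
random splits*, not a partitioning 5-fold: the 70/30 statement is taken
as operational (a 70/30 split is incompatible with 5-fold partitioning's
80/20), and stratification guarantees both classes on both sides even
for small species datasets.  A true stratified K-fold is available via
`method="kfold"`.  Scores: AUC in the rank (Mann–Whitney) formulation
with ties counted ½, and TSS at the threshold maximising TSS.  The
max-TSS threshold search enumerates the distinct score values under the
rule `score ≥ t → presence` and returns the smallest optimum
(deterministic tie-break).  Reported per-algorithm summaries are
per-split means; whether refit-on-all values would be preferable is
undecidable from the protocol alone, and per-split means are the honest
out-of-sample quantity.

## Ensemble, projection, binarization

Every algorithm × pseudo-absence replicate whose mean TSS across the
five splits exceeds 0.7 is refit on its full replicate training set
(standard ensemble-platform behaviour: the final map should use all the
information) and weighted by that mean TSS, normalised at predict time.
Members failing the cut are dropped — envelope models typically fall
here, since a 0/1 response caps their TSS.  Member scores are averaged
as *continuous* values; thresholding before averaging (committee
averaging) is a different estimator and out of scope.  The binarization
threshold is the max-TSS threshold of the ensemble scores against the
pooled rows of all replicates, fixed once from the current scenario and
reused for every future scenario — gain/loss accounting is meaningless
if the decision rule changes between periods.

## Range change and protected-area risk

Under full dispersal, cells classify as loss (1→0), stable (1→1) and
gain (0→1); by construction `loss + stable = current` and
`stable + gain = future` exactly, and the net change is
`round(100·(gain − loss)/current)`, half away from zero, reported as a
signed integer (matching the "+15"-style convention of published range
tables).  Overlap statements such as "stable exceeds 95 % of current"
use stable/current as the denominator.  Protected areas are rasterised
by cell-center containment (deterministic and resolution-consistent;
fractional-cell weighting is out of scope), and "overlap" in the threat
rule means ≥1 suitable cell whose center lies inside the polygon — cell
granularity is the map's native resolution.  A reserve is threatened by
a species under a scenario iff current overlap is empty and future
overlap is not; summary counts deduplicate protected plant species and
ecosystems across reserves.

## The virtual-species simulator

The generator emulates the structure of a real study's inputs: a
bioclimatic stack (linear gradient + smoothed Gaussian noise per layer,
optional quantile-binned categorical layers), future stacks that re-use
the *same* noise fields and differ only by stated additive deltas (the
climate signal is the only change to detect), presence-only points
accepted by Bernoulli(suitability × detection bias) and placed uniformly
within their cell, and disjoint rectangular reserves with attributes
from fixed vocabularies.  The product-Gaussian niche makes the true
range (suitability ≥ threshold, default 0.3) an analytically tractable
region and the true net change computable by the same accounting as the
pipeline's.

Default study conditions: a 60×60 landscape of 1/6° cells (lon 100–110°,
lat 20–30°); `tmin` cooling northward at 0.8 °C/° lat, `precip` rising
eastward at 30 mm/° lon, a 4-class soil layer; niche tmin ~ N(20.8, 1.0)
and precip ~ N(650, 100); 300 presences; warming deltas +1.6 °C and
+2.4 °C (within the 2–3.7 °C mid-century projection band for the kind of
region emulated).  These place the species' thermal band fully interior
under the current climate and push it partly out of the northern extent
under warming, so the true net change is negative.  This is deliberate:
a *gain* signal produced by niche truncation at the warm edge would live
in environmental space never sampled under the current climate, which no
presence-only model can learn — it would test the simulator, not the
pipeline.  The poleward-exit signal is geometric and visible to both.

What passing the recovery checks shows: the chain of envelope exclusion,
split evaluation, TSS weighting, max-TSS binarization and range
accounting correctly recovers a known range and the direction of a known
climate-driven shift under clean conditions.  What it does not show:
robustness to geocoding error, strong detection bias, spatial
autocorrelation of residuals, niche truncation at data edges, dispersal
limits or land-use constraints — real-data features the simulator
deliberately omits (some are quantifiable by raising `detection_bias`
asymmetries or noise levels, none are defaults).  Presences are drawn in
proportion to suitability and therefore occasionally fall outside the
thresholded "true range"; the recovery TSS consequently saturates below
1 even for a perfect model.

## Numerical choices

* Missing data is NaN everywhere in memory; −9999 on disk.
* The max-TSS search and the greedy prune are exactly reproducible; all
  stochastic stages derive from one global seed via
  `SeedSequence([seed, stage])` with fixed stage indices (0 correlation
  sample, 1 pseudo-absences, 2 splits, 3 refits), so any stage can be
  replayed in isolation from the run manifest.
* Degenerate inputs: constant presence variables collapse the envelope
  to a point (warning, not an error); zero-area reserve polygons
  rasterise empty with a warning; a class missing from either side of a
  split, a suitability field that is identically zero, and an ensemble
  with no retained member are hard errors naming the cause.
* Problem sizes in the shipped tests and the acceptance script (60×60
  cells, 300 presences, 10 recovery seeds, 100 metric-oracle instances)
  were chosen so a full validation runs in seconds while keeping every
  statistical check at ≥3-standard-error resolution.

## Known limitations

The package models climate suitability only: no dispersal kernels,
biotic interactions or land-use masks.  One grid, one projection;
fractional cell coverage is ignored at reserve boundaries.  The GLM is
the only smooth native learner; richer learners (boosting, random
forests, Maxent) must come in as adapters with their own defaults.
Geocoding of place-name-only records is out of scope — occurrence input
must carry coordinates.
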