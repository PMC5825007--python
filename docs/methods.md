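# Methods

`floraplan` re-implements, at desk scale, a national gap-analysis workflow
for plant conservation: model many species' ranges jointly from survey
points, binarize them with a data-driven threshold, evaluate how well an
elevation-biased protected-area (PA) estate represents them, and propose
area-capped complementary reserve networks with a simulated-annealing
selector. Because the national survey, climate rasters and PA polygons that
the original assessment consumed are not redistributable, a synthetic-data
module generates worlds with the statistical structure the analysis assumes;
everything downstream operates identically on real gridded inputs.

## The synthetic study system

**Landscape** (`synthgeo.make_landscape`). A rectangular grid of square
cells (default 120 x 120 cells of 0.1 km^2 — a 1,440 km^2 "country"
standing in for a 95,219 km^2 mainland). Elevation is a sum of
deterministic ridge functions (a major coastal range plus a secondary
inland range) and seeded, spatially smoothed noise, clipped at sea level;
roughly 70 % of cells end up in hill or mountain terrain. Climate is a
*deterministic function of elevation and position*: annual mean temperature
follows a lapse-rate model (default 6.5 °C/km) with a south-north gradient;
seasonality, warmest/coldest-quarter temperatures and the three
precipitation layers are smooth functions of the same variables. This makes
temperature and elevation strongly collinear by construction, so the
distribution models face the same predictor redundancy a real mountain
flora produces. Slope and aspect come from finite differences; northness is
sin(aspect). Flat cells take aspect 0 (northness 0) by convention, logged.

**Virtual species** (`synthgeo.simulate_species`, default 60). Suitability
is a product of Gaussian kernels over selected predictors (default annual
mean temperature, annual precipitation, northness), rescaled to a landscape
maximum of 1; the *true range* is suitability >= 0.5. Niche centres are
anchored at cells whose elevations span the 2nd-98th landscape percentiles,
and niche widths (as multiples of each predictor's landscape SD) are spread
geometrically over [0.05, 2.5], so every world contains lowland and
high-mountain specialists and true range areas spanning at least three
orders of magnitude. Species are independently flagged endangered (15 %),
endemic (20 %) and biological-resource (25 %).

**Survey** (`synthgeo.sample_occurrences`). The landscape is tiled into
15 transect blocks; 40 cells per block are drawn with probability
proportional to (elevation rank)^bias (bias 1 by default), emulating
mountain-path transects. A species is recorded at a surveyed cell inside
its true range with probability `detection_prob * u_s`, where u_s ~ U(0, 1)
is a fixed per-species detectability; outside its range it is never
recorded. Heterogeneous detectability reproduces a key feature of large
floristic surveys — some species with very few records are widespread but
inconspicuous — and yields a right-skewed records-per-species distribution
(median ~19, mean ~40 on the default world). Species with fewer than two
records are dropped with a warning, matching the emulated survey's observed
minimum of two. Setting the heterogeneity exponent to 0 recovers a uniform
survey in which `detection_prob = 1` records every in-range cell.

**Existing PAs** (`synthgeo.make_existing_pas`). Contiguous patches are
grown from seed cells, with both seeding and frontier growth weighted by
exp(bias x normalized elevation rank); the default bias of 6 concentrates
the estate on mountains, and the mask covers exactly the requested fraction
of cells (default 5.7 %). With bias 0 the mask is an unbiased contiguous
sample. `default_world` checks at generation time that at least one
species' true range is missed entirely by the mask — the "lowland gap" the
analysis is designed to expose.

## Species distribution models

The survey data are presence-only; sites where other species were recorded
but a focal species was not are treated as *inventory pseudo-absences*,
giving a shared site-by-species 0/1 matrix. The model is multi-response
MARS: a single expansion of mirrored hinge functions
h(x; k, s) = max(0, s(x − k)), products of at most two hinges, fitted by
least squares to all species at once. The forward pass greedily adds the
(parent basis, variable, knot) pair that most reduces the residual sum of
squares summed over all response columns (knots are observed values where
the parent is active, thinned to at most 50 quantiles); the backward pass
deletes one function at a time while the multi-response GCV

    GCV = (RSS_total / (n S)) / (1 − C(M)/n)^2,  C(M) = M + d (M − 1)/2

keeps falling (default penalty d = 3, maximum 21 basis functions). Each
species keeps its own coefficient vector over the shared basis. Predictions
are clamped to [0, 1]; responses are fitted on the raw 0/1 scale (no
logistic link), the classical multi-response MARS formulation, with the
clamp supplying the probability contract. Species pools larger than 300 are
partitioned into random near-equal groups before fitting (all groups of
size floor(S/n), the last absorbing the remainder), since very large
concurrent batches are numerically fragile.

Model fit is scored by AUC computed on the fitting data (presences vs all
pseudo-absences in the group matrix, Mann-Whitney formulation with
midranks). There is no hold-out: many species have too few records to
split, which is also why fit AUC — not independent AUC — is reported.

## Range maps

The default threshold for species s is mean(p_occ) − SD(p_occ) over the
model probabilities at s's own occurrence points (sample SD, floored at
0.001 to stop clamped-zero models from producing all-landscape ranges); the
alternative max-SSS rule maximizes sensitivity + specificity against the
pseudo-absences, ties resolved toward the lowest threshold. Binarization
uses p >= theta, which guarantees every occurrence point whose probability
reaches the threshold lies inside the range. The mean − 1 SD reading of the
"one standard deviation" rule is the one consistent with its source
methodology; the centre is configurable for users who prefer the SD alone.

## Reserve selection

Fine-grid ranges are aggregated onto square planning units (PUs) of f x f
fine cells (default f = 6, i.e. 3.6 km^2 PUs at the 0.1 km^2 resolution —
the nearest square aggregation to the 4 km^2 PUs of the original analysis,
since 40 fine cells is not a perfect square). Amounts are stored as integer
fine-cell counts so per-species totals are conserved exactly. PU cost
equals PU area (no cost surface); a PU is locked in when at least half its
cells fall in the PA mask (configurable). Problems round-trip through
tab-delimited Marxan 2.43 planning files (pu.dat, spec.dat, puvspr.dat
sorted by PU, bound.dat with rook-adjacency edges and landscape-edge
self-pairs).

The objective of a reserve set R is the documented Marxan 2.43 form

    score(R) = sum cost(u) + BLM * boundary(R)
             + sum_s SPF_s * max(0, (target_s − held_s) / target_s),

with proportional (unit-free) shortfall. Optimization is simulated
annealing over single-PU flips: initial temperature = SD of the score
change over 100 random probe flips, geometric cooling (x0.95 every n_PU
iterations), default 10^4 x n_PU iterations per run, and a final greedy
improvement sweep. Per-run seeds derive from the master seed through
`numpy.random.SeedSequence`, so repeat runs are independent and replayable.
The flip loop maintains the score incrementally (numba-compiled); the
pure-Python `objective_value` recomputes it from scratch and is used to
audit the bookkeeping (agreement is ~1e-14 relative over >5x10^5 accepted
flips). One hundred repeat runs give a summed solution (selection
frequency 0-100), the usual irreplaceability surrogate.

Scenarios cap the network by extent, not cost: PUs are ranked by summed
score (locked-in PUs first; ties by ascending id) and accumulated until the
total area is nearest the target, never exceeding it when the adjacent
prefixes are equidistant. Presets cover an equal-area alternative (free
statuses, extent = existing estate), additional PAs with the estate locked
in (extents: double the estate, or 17 % of land — the Aichi Target 11
level), and the same extents without lock-in; uniform representation
targets run on the 10-30 % grid in 5 % steps, with tiered presets
(endangered 50/55 %, endemic and biological-resource 30/35 %, others
10/15 %) available.

## Gap reporting

Representation of a species is the percentage of its modelled range area
inside the network; group means are unweighted. Stratified comparisons use
ten equal-width classes of range size or mean range elevation (boundary
values to the lower class, the global maximum to the top class; quantile
classing available by flag) and the Wilcoxon rank-sum test: exact
permutation p for pooled n <= 12, otherwise a tie-corrected,
continuity-corrected normal approximation (which matches
`scipy.stats.mannwhitneyu(method="asymptotic")`). Significance is starred
at 0.05 and 0.01. Network geometry is summarized by the perimeter/area
ratio (exterior edges only) and elevation mean/SD pooled over fine cells.

## Numerical choices and problem sizes

- Annealing runs in the desk-scale pipeline use 10^3 x n_PU iterations
  (400-PU default world), a size at which best-of-100 runs reproduces
  exhaustive optima exactly on every audited instance; the library default
  remains 10^4 x n_PU.
- The exhaustive-search oracle enumerates subsets up to ~20 PUs and is
  test-only.
- Forward-pass candidate evaluation residualizes both signed hinges against
  the current basis through a QR factor and solves the exact 2x2 Gram
  system per knot; near-singular pairs fall back to the better single
  column, and numerically dependent columns are dropped with a log entry.
- GCV with C(M) >= n is treated as infinite, so an extreme penalty prunes
  to the intercept-only model.
- The default study runs in well under a minute on one CPU: world
  generation (~1 s), one 40-60-species MARS group (~2 s), prediction and
  thresholding (~1 s), and two 100-run scenarios (~5 s).

## What the synthetic worlds do and do not show

Passing tests demonstrate that the pipeline's machinery is correct (oracle
agreement, conservation identities, format round trips) and that the
headline *directions* of the emulated assessment emerge under the assumed
structure: a high-elevation PA estate over-represents high-elevation
species; freeing the selection narrows the elevation gap and lowers the
network's mean elevation. They do not certify behaviour on real data:
synthetic climate is noiseless and fully elevation-determined, survey noise
contains no misidentification or positional error, and species' niches are
low-dimensional Gaussians.

One documented divergence: in these worlds, fit AUC is governed by
prevalence (widespread species cannot separate presences from
pseudo-absences drawn largely from their own suitable area; r ≈ −0.95),
and record count has no independent effect once prevalence is controlled.
The positive record-count/AUC relationship reported for the real survey —
where detection is abundance-driven and models are fitted in 153-species
batches — is therefore not reproduced, and the suite tests the
prevalence-driven property instead.

Known limitations: no dispersal constraints, land-cover clipping or
range-patch filtering; no spatial cross-validation or ensemble SDMs; no
cost surfaces or integer-programming solver; no real geography (CRS,
coastlines, islands).
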