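# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
landscapes do and do not establish.

## Friction and travel time

A friction surface assigns each grid cell one traversal speed (km/h) for a
transport mode. Roads strictly override the underlying landcover speed in
any cell they cross (no averaging): this is the simplest testable merge
rule and matches the conventions of raster cost-distance tools. Road
rasterization uses a supercover line traversal, which marks *every* cell a
segment passes through; ordinary Bresenham rasterization can leave diagonal
gaps through which 8-connected movement would "jump" the road. Within a
cell, primary beats secondary beats tertiary.

The shipped default speed tables are, per mode (walk / bicycle / drive, in
km/h): primary road 6/12/100, secondary 6/12/50, tertiary 6/12/30, forests
2/2/2, shrublands 2/2/2, grassland 5/5/5, cropland 4/4/4, regularly flooded
areas 0/0/0, sparse vegetation 3/3/3, bare areas 5/12/5, built-up areas
5/12/5, open water 0/0/0. Zero-speed classes are impassable. Note that the
tables make bicycling and driving at least as fast as walking in every
class, but *not* driving at least as fast as bicycling (bare and built-up
areas are 12 km/h by bicycle, 5 km/h by car): the coverage ordering
walk ≤ bicycle ≤ drive is therefore an empirical property of road-bearing
landscapes, checked per run, not a cellwise theorem.

Protected-area polygons are barriers: their cells are impassable unless the
cell carries a *major* road, interpreted as primary or secondary (a config
switch, `barrier_exempt_roads`). Tertiary tracks do not open a barrier.

A scenario's multiplier scales every speed (default runs at 0.8, 1.0, 1.2).
Scaling is exact, so all travel times divide by the multiplier exactly; the
suite asserts this to 1e−9.

Travel time is the exact multi-source Dijkstra solution on the 8-connected
grid graph. The edge cost between adjacent cells is time to cross half of
each cell at that cell's own speed, `t = (d/2)/v_a + (d/2)/v_b`, `d` being
the cell size (orthogonal) or cell size × √2 (diagonal). This rule is
symmetric (t(a→b) = t(b→a)); the test-suite oracle — an independent
fixed-point relaxation of the shortest-path equations, plus literal
simple-path enumeration on tiny grids — uses the same rule. Facilities that
fall on impassable cells snap to the nearest passable cell within 3 cells
(configurable) and error beyond that. A slope-dependent speed adjustment is
deliberately *not* applied: the speed tables are flat per class, and no
terrain model is generated.

Minutes are stored as floats with +∞ for unreachable cells; files encode
+∞ as the declared NODATA value.

## Coverage

Coverage is the population-weighted share of cells with travel time within
the threshold, read as *inclusive* (≤ 60 minutes); the denominator is the
whole population raster, including people on unreachable cells, matching
country-total denominators. The central table value uses multiplier 1.0 and
the parenthesized interval the min/max over the 0.8/1.2 runs.

## Hotspots

Parish values are unweighted means of finite cell minutes (the access
raster is aggregated by zone with no population weighting). Zones with no
finite cell are excluded with a warning.

Gi\* includes the focal zone (w_ii = 1) with binary weights:
`z_i = (Σ_j w_ij x_j − x̄ W_i) / (s · sqrt[(n W_i − W_i²)/(n−1)])`, with x̄
and s the global mean and population standard deviation. If a zone's
cumulative neighborhood covers every zone the denominator vanishes and the
statistic is undefined; such zones return NaN and drop out of inference.

Queen contiguity at order k is *cumulative*: all zones within k adjacency
steps (an exclusive-order variant would be a trivial set difference and is
not the default). Significance uses conditional permutation — the focal
value held fixed, the remaining values reassigned among the other zones —
with `p = (1 + #{|z*| ≥ |z|}) / (1 + n_perm)`. The default is 9,999
permutations with an explicit seed, because p ≤ 0.001 is not resolvable at
999. A consequence of conditioning worth knowing: a *single* isolated
extreme zone is not significant (its own value is fixed under the null);
clusters are neighborhood phenomena.

The multi-order rule labels a zone at order k only if p ≤ α at order k and
|z(k)| > |z(j)| for all j < k, applied to |z| so cold spots (fast access)
are treated symmetrically with hot spots (long travel times). The reported
order is the highest k satisfying the rule. Under spatially random values
the labeled fraction at α = 0.001 stays below 0.005 (checked over 200
simulations); a planted contiguous block larger than the order-3
neighborhood is labeled at order 3, because |z| keeps growing while the
widening window stays inside the block.

## Covariate modeling

Random points are drawn uniformly over the study mask; points landing on
no-data (unreachable) cells are resampled with a note. Fifteen layers are
extracted: population density (persons/km²), poverty, sub-region id, walking
minutes for the six tiers, and bicycle minutes-saved for the six tiers.

Collinearity screening is the standard iterative VIF rule
(VIF_j = 1/(1 − R²_j), drop the worst offender until all ≤ 10). The split
is 85/15 (4,250/750 at n = 5,000).

**Forests.** One regressor per response, tuned over mtry ∈ {1,2,3} (and an
ntree grid, default 500 trees) by out-of-bag MAE; the winner is evaluated
on the held-out test set. Variable importance is out-of-bag permutation
mean decrease in accuracy — for each tree, the MAE increase on that tree's
OOB samples when one predictor column is permuted — averaged over trees and
over repeated permutation iterations (default 20). Measuring on OOB rather
than training rows is essential: trees memorize training noise, which
otherwise inflates the apparent importance of uninformative predictors.
Partial dependence averages predictions over a grid of the target variable
with the other predictors at their observed joint values; the grid is
trimmed to the boxplot fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR] of the training
values. The sub-region enters the forest as a categorical code.

**Mixed models.** Poverty and density are normalized by Tukey's ladder of
powers — λ from a grid (−2…2, step 0.025) maximizing the Shapiro–Wilk W on
a subsample capped at 5,000; transform x^λ (λ>0), log x (λ=0), −x^λ (λ<0),
with a positive shift first if needed — then centered; the interaction is
the product of the transformed, centered predictors. Five candidate
fixed-effect sets are fit per response — null, poverty, density,
poverty+density, and both mains plus interaction (the interaction never
enters without both mains) — each with a sub-region random intercept, by
maximum likelihood so BIC (−2·llf + k·log n, k counting fixed effects plus
the two variance parameters) is comparable across candidates; lowest BIC
wins. The null model doubles as the grouping-variable check via a
boundary-halved likelihood-ratio test against pooled OLS. Reported:
estimates with SE/CI/t/p, σ², τ₀₀, ICC = τ₀₀/(τ₀₀+σ²), and test-set MAE,
RMSE and predictive R² = 1 − SS_res/SS_tot (which may be negative; chosen
over squared correlation so forests and mixed models are directly
comparable). Test-set prediction adds each group's estimated random
intercept (BLUP) to the fixed-effect prediction.

Model comparison reports forest-minus-mixed deltas in MAE, RMSE and R² for
the matched 12 (level × scenario) responses.

## The synthetic-data generator

The generator emulates the joint structure national accessibility studies
rely on, with one integer seed driving all randomness:

- **Population**: a mixture of Gaussian settlement clusters (log-normal
  cluster weights, default 12 clusters) over a small rural background,
  multiplied by smooth log-normal texture and scaled to the target total
  (default 1,000,000). Density is heavy-tailed and spatially clustered.
- **Poverty**: logistic(a + g·(−c·u + e)) with u the standardized log
  density and e smooth noise; c is calibrated by a short deterministic
  iteration so the realized Pearson correlation with log(1+density) hits
  the target (default −0.5; the generated value must land in [−0.7,−0.3]).
  Mean poverty defaults to 0.35. The coupling strength is a design
  parameter, not an estimate from any dataset.
- **Landcover**: a smooth random field classified by quantiles into the
  vegetation mosaic, with water (2%) and flood zones (1.5%) from an
  independent field and the densest 2% of cells read as built-up.
- **Roads**: a minimum spanning tree over cluster centers (primary),
  density-weighted towns tied to their nearest center (secondary), and
  local fill segments (tertiary).
- **Barriers**: random circular blobs accumulated to the target area
  fraction (default 5%).
- **Facilities**: per tier, cells sampled without replacement with weight
  density^γ · exp(−β·poverty), with γ rising from 1.0 (HC II analog) to 2.5
  (national-referral analog) and β = 5 by default. The γ gradient encodes
  the urban bias of higher tiers; the β term makes access genuinely worse
  in poor areas *conditional on density* — without it, poverty would carry
  no signal once density is controlled and coefficient-sign recovery would
  be meaningless. Tiers are distinct point sets; hierarchy unioning happens
  in the eligibility step.
- **Admin zones**: a Voronoi partition of the study rectangle into parishes
  (polygons and a consistent nearest-seed label raster), each parish nested
  in exactly one sub-region (default 11). Voronoi partitions of a convex
  region have connected contiguity graphs.

Scales used in the shipped fixtures and the acceptance pipeline: a 130×130
grid of 800 m cells (104 km box) with facility counts 64/32/12/6/3/1 and
4,000 sample points for parameter recovery; a 60×60/1 km scene for the fast
structural tests. These sizes were chosen so the generated effects are
statistically identifiable: with substantially fewer lowest-tier facilities
the facility-distance field is too coarse and the sign of the conditional
poverty effect becomes seed-dependent.

**What passing recovery tests show — and don't.** On these scenes the
models recover the built-in structure: density ranks first in importance
for the dense-network tiers, partial dependence of walking time rises with
poverty, and the mixed-model poverty coefficient is positive at the densest
tier. Each scene is a single spatial realization, and smooth spatial
confounding (the poverty residual field is spatially correlated at scales
the sub-region intercept only partly absorbs) can flip the conditional
poverty effect in a minority of realizations — so the recovery suite
asserts these properties as a majority vote over five independent scene
replicates, and the acceptance script reports the positive-sign fraction
over replicates rather than treating one scene as definitive. Tiers with
very few facilities (the GH/RRH/NRH analogs) are dominated by broad
geography, so sub-region out-ranks density there — the same pattern real
national analyses show for capital-only tiers. None of this validates
conclusions about any real country: the generator has no terrain, no
seasonality, planar geometry, stylized roads, and a poverty surface
constructed (not observed) to anti-correlate with density.

## Numerical conventions and edge cases

- All grids are planar (meters); no CRS or geodesy anywhere in the core.
  Real-data adapters should reproject upstream and resample all layers to
  one shared grid.
- Rasters are numpy arrays; files are ESRI ASCII grids and GeoJSON, all
  plain text.
- Degenerate inputs error loudly: zero total population, constant values
  into Gi\* or the Tukey ladder, empty facility tiers, barrier fractions
  ≥ 1, unknown landcover or road classes (named in the error), facilities
  with no passable cell within the snap radius.
- Ties in road priority resolve to the higher class; ties in the Tukey grid
  resolve to the first-scanned λ; importance ranks break ties by column
  order.
- Seeds: every public stochastic function takes an explicit seed or rng;
  nothing touches global random state.
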