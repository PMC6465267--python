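# Methods

`fullcycle` implements a full-annual-cycle spatial prioritization pipeline
for migratory species on synthetic data: weekly relative-abundance
surfaces are estimated from checklist-style observations, partitioned into
regional abundance clusters, and fed into exact minimum-set-cover reserve
selection under eight planning scenarios, with land-cover accounting of
the solutions.  This note documents the models, the defaults and why they
were chosen, the numerical decisions, and what the synthetic experiments
do and do not demonstrate.

## The optimization model

Reserve selection is the minimum set cover integer program

```
minimize    c·x          subject to   A x ≥ b,   x ∈ {0,1}^n
```

where `x_j` selects planning unit j, `c_j` is its cost, `A_ij = r_ij` the
relative abundance of conservation feature i in unit j, and
`b_i = p · Σ_j r_ij` the feature's representation target at proportion
`p` (default 0.30; configurable — the 30% level is an illustrative
intermediate between common 17% and 50% policy targets).  Features are:

* **weekly, single population** — one feature per species in each weekly
  problem (52 independent problems; their solutions are summed into a
  0–52 selection-frequency map, and areas are summed across weeks);
* **yearly, single population** — one feature per species-week in a
  single problem (binary map);
* **clustered** variants — each species-week's occupied cells are first
  partitioned into k regional clusters and each cluster becomes its own
  feature, stratifying the target across the species' range.

Costs are uniform 1 (shared-use planning: the objective is area) or a
human-footprint-style index in (0, 50) (intact-habitat planning: the
objective penalizes human-dominated cells).  Areas are always reported in
km² separately from the objective; a weekly scenario reports both the
summed area (per-week areas added, repeat selections counted each time)
and the union area.

### Solver and gap policy

Problems are solved with HiGHS branch-and-cut (`scipy.optimize.milp`).
Constraint rows are scaled to `A_ij / b_i ≥ 1` before the solve — an
identical problem with far better conditioning when representation levels
span orders of magnitude.  Zero-cost units are floored at 1e-6 so "free"
cells cannot bloat solutions invisibly.

Proving optimality (gap 0) is cheap for the weekly single-population
problems and for small instances, and those are always solved exactly.
The clustered and footprint-cost problems at desk scale carry an
integrality gap of a few percent that branch-and-bound closes only very
slowly, so scenario runs solve them with a 5% relative MIP gap and a
per-solve wall cap (30 s), in line with the default gap tolerances of
standard exact conservation-planning toolchains.  Every solution is
re-verified independently of the solver (attainment `Ax`, shortfall
`max(0, b − Ax)`, objective `c·x`), and gap-solved objectives enter
cross-problem comparisons only through their solver bounds: an incumbent
objective is an upper bound on the optimum, and `objective × (1 − gap)` a
lower bound.  The nesting inequalities asserted by the tests (weekly ≤
yearly, yearly ≤ union of weekly ≤ sum of weekly, single ≤ clustered,
monotonicity in the target) are stated so that each follows from the
corresponding inequality between true optima regardless of gaps.

An exhaustive subset-enumeration oracle (instances up to 20 units,
lexicographic tie-break) provides the independent correctness check for
the exact solver.

## The abundance estimator

Weekly relative abundance is estimated by a spatiotemporal ensemble of
block-local two-step models.  The study extent × year is tiled by 100
randomly offset partitions of spatiotemporal blocks: squares of 10° north
of 12° latitude and 20° south of it (block sizes follow data density),
crossed with 30 continuous days.  In each block holding at least 50
checklists with at least 10 detections of the species, two submodels are
fitted: a classifier for detection/occupancy and a regressor for the
count conditional on detection; blocks failing the data rule contribute
no model.  The estimate at a (cell, week) is the average of
`P(occupied) × E[count | occupied]` over all base models containing that
location and date, evaluated at a standardized search (1 km, 1 h starting
07:00, one observer); estimates supported by fewer than 50 base models
are withheld.  Predictors fall into three classes: spatial (latitude,
longitude, elevation, optional landscape composition/configuration
metrics), temporal (day of year, year, start time), and effort (duration,
distance, party size).

A 366-day year is not a multiple of 30, so each partition owns the year
through 13 day-bins — twelve of 30 days and the 6-day wrap remainder.
The bins give every (location, day) exactly one block per partition
(prediction side); every block is *trained* on the full 30 continuous
days starting at its bin, wrapping modulo 366 (fitting side).  This keeps
both desired properties: fixed-length local training windows and a
gap-free, overlap-free ownership tiling.

Default base learners are gradient-boosted trees with bag fraction 0.80,
shrinkage 0.05, 1000 trees, and depth 5 (occupancy) / 10 (abundance).
The fitting interface accepts any classifier/regressor pair; the fast
deterministic pair used in tests and the desk-scale experiments is a
single CART per submodel with the same depths and a minimum leaf size of
5, which keeps a 100-partition, 20,000-checklist experiment at roughly a
minute on one core.  A uniform random 10% of checklists is withheld
before fitting and used only for validation reporting, never for early
stopping.

### Landscape metrics

For each location, PLAND, LPI, PD and ED are computed per land-cover
class in a 2.8 × 2.8 km window of fine cells centered on the location
(clipped at raster edges): PLAND is the class's percent of the window,
LPI the percent covered by its largest 4-connected patch, PD the number
of 4-connected patches in the window, and ED the edge length per km²,
counting class/non-class adjacencies plus the window border along class
cells.  PLAND sums to 100% over classes by construction; LPI ≤ PLAND.

## Regional abundance clustering

Each species-week surface is clustered independently on its occupied
cells.  Points are (latitude, longitude, abundance); each axis is min-max
scaled to [0, 1] and the abundance axis is multiplied by 1/3 so geography
dominates the partition — with min-max scaling the weight reads directly
as a fraction of the geographic range, but note this standardization
choice is a divergence risk against any convention that scales by
standard deviations or log-transforms abundance first.  Dissimilarity is
Euclidean in the scaled space; a degenerate axis contributes zero.

PAM (k-medoids) runs BUILD initialization followed by steepest-descent
SWAP; because SWAP descent can stall in a local optimum, four additional
descents from seeded random medoid sets are run and the best kept — on
instances small enough to enumerate, this matches exhaustive medoid
search.  CLARA extends PAM to larger point sets: PAM on 5 random
subsamples of size min(n, 40 + 2k) (the classical rule), all points
assigned to the nearest candidate medoids (scaling always computed on the
full point set), best medoid set kept; when the subsample is the whole
set CLARA is exactly PAM.  Ties in assignment go to the lowest medoid
index, and clusters are relabelled in medoid cell-id order, which makes
the partition invariant to point order.

Equal abundance across clusters is *not* enforced — k-medoids cannot
guarantee it — and the per-cluster abundance share is always reported
instead.  An optional greedy boundary-reassignment pass that nudges
shares toward 1/k exists but is off by default.  Weeks with fewer
occupied cells than k fall back to a single cluster with a warning.
Clusters are re-drawn each week; no cross-week cluster identity is
implied.

## The synthetic landscape

The generators produce inputs with the statistical structure the analysis
assumes, so every stage is testable without external data.  All
generators are pure functions of parameters and a seed.

* **Grid** — square cells (default 8.4 km), row-major 0-based ids,
  half-open extents, locally flat geometry (km offsets converted to
  degrees at 111.32 km/°; latitude matters only for the estimator's
  block-size rule).
* **Species** — an isotropic Gaussian kernel in km-space follows a
  52-week route between a breeding and a non-breeding centre (cosine-
  smoothed transits, stationary phases).  Kernel values below 1e-4 of the
  weekly maximum are set to exact zero — outside its weekly range a
  species is absent, not astronomically rare — and the surface is
  rescaled so every weekly total equals the population size exactly.
* **Checklists** — zero-inflated counts: detection is Bernoulli with a
  logistic probability in log abundance density (party size enters
  detection only); the count given detection is Poisson with mean
  `detection_scale × density × duration × √(1 + distance)`.  The closed
  form of the expected count backs the Monte-Carlo generator checks and
  serves as the estimand for recovery experiments.  Checklist placement
  is uniform by default; an effort-density surface parameter exposes
  spatially biased effort without committing to a specific density law.
* **Costs** — uniform 1, or a smoothed Gaussian random field squashed
  logistically into (0, 50).  The squash (rather than a hard clip) was
  chosen because a *mean* footprint over an 8.4 km cell is rarely exactly
  0 or 50, and clip plateaus create large sets of exactly tied costs that
  are degenerate for branch-and-bound.
* **Land cover** — a smoothed field rank-transformed to uniform and cut
  at cumulative class proportions: exact class mix up to rounding, with
  spatial clumping.
* **Elevation** — a smooth synthetic surface standing in for a terrain
  covariate.

### Study conditions

The scenario experiments run on a 20 × 20 grid with 5 species, k = 3
clusters, and 8 weeks sampling the annual cycle (two per season: weeks 1,
8, 15, 22, 29, 36, 43, 50); these sizes keep a full eight-scenario run
around a minute while leaving every formulation non-trivial (40–120
features over 400 binary variables).  The estimator-recovery experiment
uses a 16 × 16 grid, one representative migrant (population 10,000,
kernel spread 15% of the grid extent, south-to-north migration), 100
partitions and 20,000 checklists, against 2,000 for the
data-volume contrast.

## What the synthetic experiments show — and what they do not

Passing tests demonstrate internal correctness and the qualitative
behavior of the method chain: the exact solver agrees with enumeration;
yearly planning needs far less summed area than weekly planning (the
nesting is a theorem; the observed ~70–75% reduction at 8 weeks is
specific to these synthetic conditions); stratifying over clusters costs
area; all targets are attained in all scenarios; the estimator's
abundance ranking converges toward truth with data volume.  They do not
calibrate any real-world quantity: the synthetic landscape has no ocean
mask or projection, effort is spatially unbiased by default, detection
does not vary with habitat or observer, species dynamics are a single
smooth kernel with conserved weekly totals, and the cost field is
statistically, not empirically, footprint-like.  Absolute areas,
percentages and correlation levels therefore transfer to real data only
in direction, not in magnitude.

## Known limitations

* The clustered/footprint integer programs are solved to a 5% gap at
  desk scale; strict optimality there would need a stronger MIP solver.
* PAM's global-optimality is verified only on enumerable instance sizes;
  on larger instances restarts reduce, but cannot eliminate, local
  optima.
* The estimator's within-block stationarity assumption smears fast
  migration: recovery is weakest in transit weeks for species whose
  weekly displacement is large relative to the block's 30-day window.
* Weekly problems are fully independent; no locked-in-area constraint
  couples consecutive weeks.
* The land-cover availability criterion ("cells where at least one
  species is present at some point in the year") exposes the species
  threshold as a parameter; area accounting uses pure containment
  warping, which is exact only because planning cells are integer
  multiples of fine cells.
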