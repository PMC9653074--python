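# Methods

This note documents the models, conventions and numerical choices behind
`tobaccoscape`, and what its synthetic-data validation does and does not
establish about real data.

## Kernel density estimation of retail exposure

Outlet locations (projected planar coordinates, metres) are smoothed into a
continuous density. The default kernel is the quartic (biweight) kernel used
by ArcGIS Kernel Density,

K(d) = 3/(π r²) · (1 − d²/r²)²,  d < r,

with the search radius r entered in metres and densities reported in
outlets/km² (so one isolated outlet contributes 3/(π·0.64) ≈ 1.492
outlets/km² at distance 0 with r = 800 m). Each outlet integrates to one, so
the surface integral recovers the outlet count when the raster extent pads
the point cloud by at least one bandwidth; the single-point 100 m grid
integral is within 1% of unity. A truncated-Gaussian kernel (σ = r/3,
renormalised over the disk d < r) is available for sensitivity analysis.

Defaults follow common practice in retail-exposure studies: r = 800 m (a
plausible 10-minute walking distance) and a 100 × 100 m raster. Points at
exactly d = r contribute nothing (strict inequality). No edge correction is
applied at the study boundary, matching the GIS default behaviour such
studies rely on.

Two evaluation paths exist and must agree *bit-for-bit*: a transparent
O(n·m) double loop (`kde_at_points_naive`) and a spatially indexed
implementation (`kde_at_points`, uniform binning at bandwidth pitch). The
indexed path gathers candidate neighbours sorted in ascending point order
and applies the identical per-pair arithmetic, so summation order matches
the naive loop exactly; the test suite asserts zero difference on
1000 × 1000-point instances. Rasterisation scatter-adds each outlet's kernel
patch onto cell centres, which computes the same cell-centre values.

Availability at subcommunity centroids is evaluated *exactly* (not by
raster lookup) to avoid a 100 m discretisation artifact; a bilinear raster
lookup is provided for grid-extraction workflows and agrees with exact
evaluation within 5% where kernels overlap densely (≈30 outlets/km²,
an urban-core regime). In sparse suburbs the relative discrepancy near
kernel support edges is larger — a property of relative error at
near-zero densities, not of the estimator.

## Population-weighted availability

Community availability is the population-weighted mean of centroid
densities, TRAᵢ = Σⱼ KDEⱼ popⱼ / Σⱼ popⱼ. Zero-population subcommunities
contribute nothing; a community whose subcommunities sum to zero population
is an error (the denominator is undefined) rather than silently dropped.
Pooled-type availability is computed as the sum of the per-type TRAs, which
by linearity of the kernel estimator equals the availability of the pooled
point set and makes type-additivity exact in floating point. Invariants
enforced by tests: weighted-mean bounds (min KDEⱼ ≤ TRA ≤ max KDEⱼ),
invariance under rescaling all populations, and exact type-additivity.

## Deprivation index

Four deprivation-increasing census rates — unemployment, low-skilled
workers, low educational attainment, non-home ownership — are standardized
to Z-scores and summed with equal weights (the Carstairs/Townsend
tradition). Conventions that the source literature leaves open are fixed
here and tested:

* **Sample SD (ddof = 1)** for Z-scores. At thousands of communities the
  difference from the population SD is negligible, but the choice is fixed
  so results are exactly reproducible.
* **City-wide quintiles**, not stratum-wise: rank r of n maps to quintile
  ⌈5r/n⌉, with tied scores receiving their mean rank so a tie block is never
  split across quintiles. Quintile assignment is verified against a
  brute-force sort-and-slice oracle on 1000 random vectors with and without
  ties.
* Zero-variance indicators and missing values are hard errors naming the
  indicator / communities, since they would silently break standardisation.

## Rank-based group comparison

Kruskal–Wallis H uses mid-ranks and the standard tie correction
1 − Σ(t³−t)/(N³−N); p-values come from the χ²(k−1) approximation. The
implementation delegates to `scipy.stats.kruskal` behind the package
interface and is cross-checked against an independent first-principles rank
implementation to 1e-10 on 1000 random tied and untied datasets. All values
identical is an error (the tie correction degenerates). Monte-Carlo
calibration: with 5 groups × 100 observations the null rejection rate at
α = .05 over 10 000 simulations lies in [0.04, 0.06].

Effect size is epsilon squared, ε² = H/(n−1), in [0, 1]; this closed form
reproduces published effect-size tables from their printed H statistics and
community counts, which is the package's exact-arithmetic acceptance check.

Distributions of availability are strongly right-skewed, so groups are
summarized by medians with percentile-bootstrap 95% CIs (default 1000
resamples, explicitly seeded, hence reproducible). The CI method for
published medians is generally unstated in the literature; the percentile
bootstrap is this package's documented choice and is configurable. Skewness
is the biased moment ratio m₃/m₂^1.5 and kurtosis the non-excess Pearson
ratio m₄/m₂² (Gaussian = 3), matching how such descriptives are usually
printed. No multiple-testing adjustment is applied to the stratified table
(mirroring standard practice of reporting unadjusted p-values).

The analysis surface is a model/results pair: `TobaccoRetailAnalysis`
(communities + exposure tables) whose `fit(seed=…)` returns
`TobaccoRetailAnalysisResults` with distribution and quintile tables,
`summary()` and plotting. Any empty stratum × quintile cell is an error
naming the cell — an empty cell means the quintile design does not support
the stratified comparison.

## Synthetic city generator

The generator emulates the study design of socio-spatial retail analyses in
a large monocentric city, with every parameter planted and recoverable:

* **Geometry.** Communities on a jittered lattice over a square extent
  (default 20 km side, 500 communities); urbanity assigned by radial
  distance — urban_center within 4 km, urban_area within 9 km, suburb
  beyond — emulating ring-road classifications without digitised roads.
  Each community has 1–5 subcommunities (uniform), centroids jittered near
  the community centroid, populations uniform on 500–5000.
* **Census indicators.** Rates in (0,1) via inverse-logit of a Gaussian:
  expit(intercept + slope·dnorm + N(0, σ)), with dnorm the distance from
  centre normalized to [0,1]. Default slopes (0.8–1.2) make the suburbs more
  deprived; the default noise σ = 1.5 deliberately dominates the trend at
  the indicator level so every urbanity zone spans all five city-wide
  quintiles, as observed in real cross-tabulations.
* **Retailers.** Each type follows an inhomogeneous Poisson process,
  simulated by exact thinning of a homogeneous process at the maximum
  intensity. The intensity is piecewise constant over nearest-centroid
  community territories: baseline(type, zone) × effect(type, zone)^((q−1)/4),
  where q is the community's deprivation quintile computed *inside the
  generator* with the same standardisation and ranking rules the index stage
  applies — so the plant is exactly recoverable downstream — and `effect` is
  the planted Q5:Q1 intensity ratio. Piecewise constancy makes
  `planted_truth` an exact read-through of the configuration. Default
  baselines (e.g. convenience stores 11 / 5.7 / 1.2 outlets/km² across
  centre/area/suburb) emulate the magnitudes reported for East-Asian
  megacity retail environments, with availability rising with deprivation in
  the centre and falling elsewhere.

All randomness flows through a single `numpy` generator seeded from the
config; identical configs are byte-identical on disk. Poisson count
calibration (mean over 200 seeds within 3√(λA) of λA) is tested.

**What the generator does not emulate:** road-network geometry and network
distances, realistic parcel/boundary shapes, population heterogeneity
beyond uniform draws, point clustering beyond the planted intensity
(e.g. retail strips), and temporal mismatch between census and outlet data.
Passing recovery tests therefore show the *pipeline* is correct and
well-calibrated, not that any particular real city follows the planted
model.

## Recovery experiments

Two canonical experiments (`tobaccoscape.experiments`) validate the whole
pipeline end to end on a reduced city — 16 km extent, 350 communities,
enlarged 5 km centre ring — sized so that 100-seed replication runs in
seconds while all zone × quintile cells stay populated:

* **Urbanity ordering.** Plant 6:4:1 centre:area:suburb intensity with no
  deprivation effect; recovery = median TRA strictly ordered
  centre > area > suburb. Required in ≥95 of 100 seeds.
* **Deprivation divergence.** Same zone baselines plus a centre-confined
  planted deprivation effect (Q5:Q1 = 6, chosen as a strong but realistic
  monotone plant); recovery = monotone increasing Q1→Q5 urban-centre median
  profile while the city-wide profile is not monotone increasing — the
  divergence signature of a centre-specific gradient. KDE smoothing blurs
  neighbouring communities' planted intensities, which is why a clearly
  separated plant is used.

## Cleaning ledger

Retail point-of-interest data require multi-step validation (deduplication,
verification, record matching). `CleaningLedger` enforces
records_out = records_in − records_removed and step-to-step chaining, and
reports exclusion percentages (2 dp) against a declared per-step baseline.
It deliberately cannot represent internally inconsistent count chains;
published chains that do not add up must be resolved to a consistent one
before they can be recorded.

## Numerical and degenerate-input conventions

* Strict d < r kernel support; ε² domain requires n ≥ 2 and H ≥ 0.
* Quintiles need n ≥ 5; standardisation needs n ≥ 2 and nonzero variance
  (constant columns detected via zero range, robust to floating-point
  means).
* Shape descriptives of a constant sample are NaN (undefined), while its
  bootstrap CI collapses to the constant.
* CSV interchange uses round-trip float parsing in the CLI so staged runs
  are byte-identical to `run-all` output.

## Problem sizes

Default test/validation scales: 1000 × 1000-point KDE oracle instances;
10 000 null simulations for test calibration; 100 seeds × 350-community
cities for ordering recovery; 200 seeds for Poisson calibration. These sizes
give comfortable statistical margins (e.g. binomial 3σ on calibration rates)
at desk-scale runtimes.

## Known limitations

* No edge correction means densities are biased low within one bandwidth of
  the study boundary; the synthetic extent pads rings so this mainly affects
  the outermost suburb.
* The χ² approximation for Kruskal–Wallis is slightly conservative at small
  group sizes; group sizes here (≥ tens) are comfortably large.
* Euclidean distance stands in for walking distance; network KDE is out of
  scope.
* The bilinear raster lookup degrades in sparse-density areas (see above);
  exact centroid evaluation is the default for this reason.
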