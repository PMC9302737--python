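# Methods

## The problem

Top-down gridded population datasets spread census counts from areal units
(enumeration areas, districts) across small grid cells using a statistical
model and spatial covariates. Users apply them at the cell or neighbourhood
scale, but producers can only validate them at the areal-unit scale — the
finest scale at which real counts exist. This package measures cell-level
accuracy by *simulation*: it builds a synthetic region in which every
household's location, size and construction year are known, degrades that
truth into realistic census inputs, runs the standard unconstrained
Random-Forest dasymetric workflow, and scores the output against the truth.

## The synthetic world

**Geography.** A 360 × 360 grid of 100 m cells (1 cell = 1 ha), row 0 at
the top, cells half-open (`[x0+cs, x0+(c+1)s) × (y0−(r+1)s, y0−rs]`), so a
point on a shared edge belongs to exactly one cell. A circular urban mask
covers ~5% of the grid (a dense city in empty hinterland); a configurable
number of circular slum patches (default 3, radius 12 cells) sit inside it.
Everything outside the mask is rural.

**Households.** Default counts per stratum (urban-slum 35,001,
urban-non-slum 57,843, rural 4,823) are placed by weighted sampling without
replacement over cell "slots", with at most 60 households per cell. Urban
weights decay with distance from the patch interior (e-folding 6 cells in
slums, 30 in non-slum areas), so slum cells are several times denser than
non-slum cells; rural households scatter uniformly and sparsely — over 80%
of the grid stays unsettled. Household size is a lognormal with mean 4.0
and log-scale σ = 0.5, rounded to the nearest integer and truncated to
[1, 15]. The distribution is an assumption, not an observed fact; the exact
integer pmf is exposed (`household_size_pmf`) so tests can check the sample
mean against its enumeration.

**Growth history.** Construction years are assigned per stratum so that
filtering to `build_year ≤ Y` reproduces configured historical counts
exactly (defaults follow census-report-anchored trajectories; four
reference years 2001/2006/2011/2016). Households deep inside the settled
footprint (by distance transform) receive the oldest years, plus a small
random jitter, emulating outward growth. The year counts must be
non-decreasing; the default rural trajectory is clamped accordingly (real
regions can lose rural buildings; that is out of scope).

**Covariates.** Each layer is
`informativeness · block_mean(log(1+density)) + noise`, with both signal
and noise constant on `native_factor × native_factor` blocks. This
reproduces the two properties of real covariate stacks that matter here:
coarse native resolution (the 9-block layers emulate ~900 m sources such as
night-time lights, and are the mechanism behind the "halo" of estimates
around settlements) and imperfect correlation with within-settlement
density. The default stack is one fine, weakly informative
distance-to-feature-like layer plus three coarse layers of decreasing
informativeness; `SimulationConfig.coarse_only()` drops the fine layer.

**Zones.** Settled cells are ordered along a Morton (Z-order) curve and cut
into `n_small` consecutive runs of near-equal household counts (defaults
922 small / 10 large); every unsettled cell joins the zone of its nearest
settled cell, so zones partition the grid, and large zones group
consecutive small zones so nesting is exact. The construction is
deterministic and balanced (max/min household ratio well under 5); zone
shapes are compact but not guaranteed simply-connected, which does not
affect any statistic computed here.

**What the generator does not emulate.** Real building footprints, road
networks and terrain; survey-derived household typologies; within-city
correlation structure beyond the monotone density link; rural village
clustering; building demolition. A green test therefore establishes that
the *machinery* behaves as specified and that the qualitative error
phenomena (slum under-estimation, halo misallocation) emerge from the
stated mechanisms — not that error magnitudes match any real region.

## Census degradation

Outdatedness keeps households with `build_year ≤` the reference year.
Undercount removes households per stratum uniformly at random, retaining
exactly `floor((1−r)·N)` — the count is deterministic, only the selection
depends on the seed, and removal has no spatial pattern by construction.
Default rates: low (slum 10%, others 2%), medium (30%, 5%), high (60%,
10%). Strata are removed independently by default; a config flag pools
non-slum and rural households before the floor, matching an alternative
rounding arithmetic seen in pooled tabulations. Each of the 16
year × undercount populations is aggregated to both zone levels, giving 32
census inputs; both aggregations of a pair share one degraded table.

## The disaggregation model

Phase A: per zone, covariate means, density = population / total cell count
(hinterland included — the "unconstrained" behaviour under study), and
log density. Zones with zero population are excluded before the log
transform. A `RandomForestRegressor` (default 500 trees, ⌈p/3⌉ candidate
covariates per split, unlimited depth, bootstrap resampling) fits
covariate means → log density.

Phase B: per cell, predicted density = `exp(mean over trees of predicted
log density)`; strictly positive everywhere, including unsettled cells — no
settlement mask is applied, deliberately, since misallocation into
unsettled cells is a quantity of interest. No smearing correction is
applied to the back-transform: the within-zone normalisation cancels any
zone-constant factor, so a correction would not change the estimates.

Phase C: cell estimate = zone population × cell density / Σ zone densities.
Conservation is exact to floating point (tested at 1e−9 relative). A zone
with positive population but zero predicted density falls back to uniform
disaggregation with a warning (the default model cannot produce this case;
it guards user-supplied density rasters). Normalisation happens on the
natural scale — the only scale on which the pycnophylactic property can
hold.

## Evaluation

Estimates and truth are aggregated by summing k × k blocks (ragged edges
dropped; the default grid is divisible by every asserted k). The inclusion
rule — estimate ≥ 1 person — is applied *after* aggregation, at the
evaluated scale. Each aggregated cell takes the stratum holding the
plurality of its true population; blocks with no true population take the
plurality of cell labels instead, so urban "halo" cells are evaluated as
urban; ties break slum > non-slum > rural (slum error is the focus).
Misallocated percentage uses every cell, no threshold. Metric values that
are undefined for a subgroup (zero mean truth under the mask, zero
estimated mass) are reported as NaN rather than raised, so one degenerate
subgroup cannot abort a 32-scenario report; the kernels themselves raise on
degenerate input when called directly.

## Reproducibility and numerics

One master seed; every operation derives an independent substream keyed by
operation name (and scenario labels), so any single scenario is
reproducible in isolation and the no-undercount scenario is byte-identical
across aggregation levels. Reruns with the same config and seed produce
bit-identical rasters (manifest checksums verify this). Rasters are written
as single-band float64 TIFF, nodata −1, with the grid geometry serialised
in the image description tag.

## Known limitations

- With a single, perfectly informative native-resolution covariate and
  small-zone input, the included-cell population-adjusted RMSE at 100 m
  plateaus just above 0.1 (≈ 0.09–0.11 across seeds) rather than below it.
  The floor is intrinsic to the workflow replicated here: training
  covariates are zonal means diluted by each zone's unsettled share while
  prediction uses cell values (the ecological-fallacy mechanism), and a
  small fraction of each rural zone's population leaks into its unsettled
  cells because excluded-zero-zone training keeps predicted density
  positive everywhere. Per-stratum decomposition: ≈3% of mean in slum
  cells, ≈11% in non-slum, ≈47% in (sparse, low-count) rural cells.
- Forest-size reductions (tests and the acceptance script use 50–100 trees
  instead of 500) change none of the structural properties asserted —
  conservation, cardinality, monotonicity, sign patterns — only the
  variance of individual estimates.
- Scale labels in metric tables assume 100 m cells (`scale_m = 100·k`).
- The misallocation-monotonicity property holds exactly only on grids whose
  dimensions every asserted k divides (otherwise ragged-edge mass is
  dropped); the default 360-cell grid satisfies this for k ∈
  {1,…,6,8,9,10}.
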