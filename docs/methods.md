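# Methods

This note documents the models, conventions, and numerical choices behind
`pfdisturb`, and what the synthetic test suite does and does not establish
about real data.

## Data model and geometry

All computation happens on one planar, square-celled grid assumed to be in
an equal-area projection: area is cell count × `cell_size²` (0.09 ha per
cell at 30 m). Reprojection is out of scope; the CLI warns if the declared
CRS tag looks geographic. Cells are indexed `(row, col)` from the top-left
(north-west) corner.

Rasters carry self-describing sentinels: year 0 = undisturbed, negative
severity = nodata. Disturbance years are valid in `[year_min, year_max]`
(default 1986–2020); severity is only defined for disturbance years up to
`severity_year_max` (default 2016), so severity summaries use a shorter
window than area summaries.

**Rasterization rule.** A polygon owns a cell iff it contains the cell
center under a lower-left half-open rule: a center exactly on the polygon
boundary counts as inside on the polygon's west/south edges and outside on
the east/north edges (implemented by nudging the test point by
`1e-9 · cell_size` toward the upper right). This makes rasterization
deterministic and makes area exactly additive across edge-sharing polygons —
no boundary center is counted twice or dropped.

## Patches and the minimum mapping unit

Patches are maximal rook-connected (4-neighbor) components of cells sharing
one disturbance year; cells of different years never share a patch, because
the source product is annual and severity is aggregated per year. Forest
patches are components of the mask. The MMU is expressed in cells
(default 2, the hectare figure following from the grid) and removes sub-MMU
patches from the disturbance layer and the forest mask alike; the boundary
is inclusive (a 2-cell patch is retained). MMU filtering is idempotent and
the pre-MMU patches partition the disturbed cells — both are property-tested
against an independent BFS flood-fill oracle.

## Attribution and indicators

For a documented dataset with mapping year *M*, PRE = `[year_min, M]`
(inclusive of the mapping year) and POST = `[M+1, year_max]`; a dataset
mapped in the final year has an empty POST window, reported as null rather
than a division by zero. Potential datasets use the FULL window.

Numerators count disturbed cells that lie inside the polygon **and** the
MMU-filtered forest mask, because the denominators are mask-based forest
areas; mixing mask-filtered denominators with unfiltered numerators would
inflate proportions. Where documented and potential polygons overlap, the
cell goes to the documented layer and is clipped from the potential one;
polygons of the same status are assumed non-overlapping, and each polygon
carries exactly one country/bioregion/EU attribute (geometries spanning two
strata must be split upstream).

At every aggregation level (country, biogeographical region — with the
Alpine region split into Alpine and Alpine–Scandinavian — EU, Europe), areas
are summed over member polygons and the ratios recomputed from the pooled
values. With mixed mapping years the rate pools area-time exposure:

    r = 100 · Σ_d A_disturbed,d / Σ_d (A_forest,d · n_years,d)   [%/yr]

which reduces to `100·A_d/(A_f·n)` for a single dataset and makes the rate
invariant to splitting a stratum into sub-polygons. Values are rounded only
at presentation time.

**Severity.** A patch's severity is the arithmetic mean over all of its
cells; patches containing nodata severity are flagged and excluded from
summaries. Stratum severity is the *unweighted* mean of patch means (a
2-cell patch counts as much as a 100-cell one), matching a patch-level view
of disturbance events. Patch membership in a polygon uses the any-cell rule:
one shared cell assigns the patch to the stratum, its mean still computed
over all its cells, and a patch is counted once per stratum even if it
touches several member polygons. Majority-cell membership was the plausible
alternative; any-cell was chosen because clipping severity to the polygon
would redefine the patch mean.

## Resampling inference

The exchangeable resampling unit is the **patch** (with its area and
severity); intervals are percentile intervals at 95% over 10,000 iterations
by default, reproducible under a seed and independent of input order (each
stratum derives its own substream from the global seed and its key).

**Count model.** For totals (disturbed area, and rates, which are scaled
totals) the bootstrap draws an independent Poisson(1) multiplicity per
patch instead of fixed-n index resampling. Disturbed area is a point-process
total — the number of patches is itself random — with
`Var(T) = E[N]·E[A²]`; a fixed-n patch bootstrap reproduces only the
`E[N]·Var(A)` part and understates the variance by the count term, giving
undercovering CIs and an anticonservative rate test. The Poisson
multiplicity scheme matches the full variance while keeping the patch as
the unit. For means (severity) the sample size is ancillary and the
classical fixed-n bootstrap is used. `count_model="fixed"` and a cell-level
resampling unit remain available for comparison; cell-level intervals are
narrower because they ignore the clustering of disturbance into patches.

**Rate-difference test.** Statistic Δ = r_post − r_pre; patches are
resampled independently within each period and the two-sided p-value is
`2·min(P(Δ* ≤ 0), P(Δ* ≥ 0))`, clipped to `[2/n_iter, 1]`. A period with no
patches yields the point Δ with a null p-value. Calibration on 500 null
strata (equal hazards) gives rejection rates near nominal; the test runs
slightly hot (≈6–7% at the 5% level) when the post window holds only a few
dozen patches, a consequence of bootstrap-Δ skewness at small counts.

**Severity test.** Mann–Whitney U with midranks; groups above the cap
(default 1000 patches, a guard against spatial autocorrelation inflating
the effective sample size) are first reduced by seeded uniform subsampling
without replacement. The p-value is exact when `n1·n2 ≤ 400` and the data
are tie-free, otherwise the tie-corrected normal approximation. Stars:
`*` p < 0.10, `**` p < 0.05; no multiple-testing correction is applied
across strata.

**Sensitivity analysis.** Every documented mapping year is shifted by each
of −3…+3 years (clamped to the window) and attribution and rates are
recomputed from the cached cell-level overlay; shift 0 re-runs the identical
code path and reproduces the baseline byte-for-byte.

## Synthetic landscapes

The generator emulates the statistical structure the assessment assumes,
with known ground truth:

* **Forest mask**: a Gaussian-smoothed noise field thresholded at the target
  cover fraction (default 0.6) — spatially clumped, like real masks.
* **Polygons**: non-overlapping rectangles snapped to cell edges, one per
  tile slot, assigned to datasets with country/bioregion/EU attributes and
  mapping years (defaults average ≈2015, area-weighted, echoing the
  continental databases).
* **Disturbance**: each year, eligible cells (forest, never disturbed — the
  one-disturbance-per-cell rule mirrors the annual source product) seed a
  patch; patches grow by stochastic rook accretion to a target size of
  `2 + Geometric(1−g)` cells (default mean 3 cells = 0.27 ha; every patch
  meets the MMU by construction). The hazard is `hazard_pre` (default
  0.0008/yr) up to the owning dataset's mapping year and `hazard_post`
  (default 0.0015/yr) after; background and potential-polygon cells keep
  the pre hazard. Two design properties keep the nominal hazard exactly
  equal to the marginal per-forest-cell annual disturbance probability:
  growth is confined to cells sharing the seed's hazard regime (events are
  stand-level and do not straddle regime boundaries, which would otherwise
  asymmetrically leak post-period area into the background), and the seed
  probability is conditioned on the per-regime eligible pool
  (`p = h/m · N_forest/N_eligible`), compensating the depletion that the
  one-disturbance rule accumulates over the window. The expected rates in
  the truth record are therefore `100·h` exactly.
* **Severity**: one Beta(α, β) draw per patch (default Beta(4, 2),
  mean ≈ 0.67) plus clipped Gaussian cell jitter (sd 0.05), only for years
  within the severity window.
* **Selection-bias mode**: an extra labeled "anthropogenic" hazard stream
  runs before the mapping year, and candidate documented polygons it touches
  are excluded — reproducing how primary-forest maps omit stands visibly
  disturbed by people before the survey, so the measured PRE rate
  underestimates the combined natural + anthropogenic hazard.

**What passing tests show — and don't.** On these landscapes the pipeline
recovers known hazards within bootstrap CIs, both tests hold their nominal
size, and the sensitivity analysis localizes a simulated hazard changepoint.
Real landscapes add features the generator omits: spatial autocorrelation of
hazard (weather, topography), multi-year disturbance episodes, non-geometric
patch-size tails, mapping-year error, polygon digitization error, and
non-random placement of primary forests. Passing here validates the
*machinery*, not the attribution assumption that all pre-mapping
disturbances were natural.

## Problem sizes and defaults

The recovery and calibration suites use 256×256 grids (≈39k forest cells),
100 seeds, and 1000 bootstrap iterations — sizes chosen so the full suite
runs in about a minute while leaving the Monte-Carlo error of each check
well inside its acceptance margin; production runs default to 10,000
iterations. The changepoint-localization scenario uses a sharp 0.0008 →
0.015 /yr jump at mapping year 2010, chosen from a power calculation so the
argmax test has negligible noise. The tiny 64×64 fixture bundle raises
hazards to 0.004/0.010 so every code path (both periods, both statuses,
severity window) is exercised despite the small grid; it is pinned by
checksum.

## Known limitations

* Attribution of individual post-mapping disturbances to natural versus
  anthropogenic causes is out of scope by construction.
* Percentile CIs (not BCa); for strata with very few patches the intervals
  are ragged and the rate test slightly anticonservative.
* The minimum-centroid-distance thinning variant of the severity subsample
  is not implemented; subsampling is uniform.
* The country comparison does not harmonize forest definitions between the
  mask and reported statistics; its output carries that caveat.
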