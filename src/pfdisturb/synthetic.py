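"""Synthetic landscape generator with known ground truth.

Emulates the statistical structure the assessment assumes, standing in for
the (large, proprietary-adjacent) European inputs: a Landsat-style annual
disturbance-year raster on a 30-m equal-area grid, a [0, 1] severity raster
valid through 2016, a smoothed binary forest mask, and polygon datasets of
documented / potential primary forests stratified by country and
biogeographical region, each documented dataset carrying a mapping year.

The disturbance process: each year, eligible cells (forest, never disturbed
before - first year wins) initiate a patch with probability
``hazard / E[patch size]``, where the hazard is ``hazard_pre`` up to and
including the owning dataset's mapping year and ``hazard_post`` after (cells
outside documented polygons keep ``hazard_pre`` throughout).  Patches grow by
seeded stochastic rook-neighbor accretion to a target size of
``2 + Geometric`` cells (geometric stopping with parameter ``patch_growth``),
so every patch meets the 2-cell minimum mapping unit by construction; growth
is confined to the seed's hazard regime, and the seed probability is
conditioned on the eligible pool so that the marginal per-forest-cell annual
disturbance probability equals the nominal hazard exactly.
Severity is drawn per patch from Beta(alpha, beta), jittered per cell with
clipped Gaussian noise, and assigned only for years within the severity
window.

Defaults echo the magnitudes of the European assessment: hazards of
0.0008/yr pre and 0.0015/yr post (0.08 and 0.15 %/yr), a mean patch size of
3 cells (0.27 ha), Beta(4, 2) severity (mean 0.667), 60% forest cover, and
an area-weighted mean mapping year of about 2015.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import box

from .geodata import (
    DOCUMENTED,
    POTENTIAL,
    SEV_NODATA,
    UNDISTURBED,
    DisturbanceLayers,
    ForestPolygon,
    Grid,
    PolygonDataset,
)

_NEIGH = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass(frozen=True)
class DatasetSpec:
    """Layout of one synthetic polygon dataset."""

    dataset_id: str
    status: str
    mapping_year: int | None
    country: str
    bioregion: str
    in_eu: bool
    n_polygons: int = 3


#: Default dataset layout: four documented datasets (mapping years averaging
#: ~2015, area-weighted) plus two potential ones, spread over four countries
#: and four biogeographical regions (Alpine split into Alpine and
#: Alpine-Scandinavian), mixing EU and non-EU members.
DEFAULT_DATASETS: tuple[DatasetSpec, ...] = (
    DatasetSpec("D1", DOCUMENTED, 2016, "RO", "Continental", True),
    DatasetSpec("D2", DOCUMENTED, 2015, "SE", "Boreal", True),
    DatasetSpec("D3", DOCUMENTED, 2014, "NO", "Alpine-Scandinavian", False),
    DatasetSpec("D4", DOCUMENTED, 2015, "BG", "Alpine", True),
    DatasetSpec("P1", POTENTIAL, None, "SE", "Boreal", True, 2),
    DatasetSpec("P2", POTENTIAL, None, "NO", "Alpine-Scandinavian", False, 2),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic landscape."""

    nrows: int = 256
    ncols: int = 256
    cell_size: float = 30.0
    year_min: int = 1986
    year_max: int = 2020
    severity_year_max: int = 2016
    hazard_pre: float = 0.0008
    hazard_post: float = 0.0015
    patch_growth: float = 0.5  # geometric continuation prob.; E[size] = 2 + g/(1-g)
    severity_alpha: float = 4.0
    severity_beta: float = 2.0
    severity_jitter_sd: float = 0.05
    forest_cover_fraction: float = 0.6
    datasets: tuple[DatasetSpec, ...] = DEFAULT_DATASETS
    anthro_hazard_pre: float = 0.0  # selection-bias mode when > 0
    seed: int = 0

    def __post_init__(self) -> None:
        for h in (self.hazard_pre, self.hazard_post, self.anthro_hazard_pre):
            if not (0.0 <= h <= 1.0):
                raise ValueError(f"hazards must lie in [0, 1], got {h}")
        if not (0.0 <= self.patch_growth < 1.0):
            raise ValueError("patch_growth must lie in [0, 1)")
        for spec in self.datasets:
            if spec.mapping_year is not None and not (
                self.year_min <= spec.mapping_year <= self.year_max
            ):
                raise ValueError(f"mapping year {spec.mapping_year} outside window")

    @property
    def mean_patch_size(self) -> float:
        g = self.patch_growth
        return 2.0 + g / (1.0 - g)


@dataclass
class TruthRecord:
    """Ground truth for parameter-recovery tests."""

    hazard_pre: float
    hazard_post: float
    expected_rate_pre: float  # 100 * hazard, %/yr
    expected_rate_post: float
    severity_mean: float  # Beta mean
    mapping_years: dict[str, int | None]
    mean_patch_size: float
    n_candidate_polygons: int = 0
    n_excluded_polygons: int = 0
    realized_disturbed_fraction: float = 0.0


@dataclass
class SyntheticLandscape:
    layers: DisturbanceLayers
    polygons: list[ForestPolygon]
    datasets: list[PolygonDataset]
    truth: TruthRecord


def _forest_mask(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Smoothed random field thresholded at the target cover fraction."""
    noise = rng.standard_normal((cfg.nrows, cfg.ncols))
    smooth = ndimage.gaussian_filter(noise, sigma=4.0)
    thresh = np.quantile(smooth, 1.0 - cfg.forest_cover_fraction)
    return smooth >= thresh


def _place_polygons(cfg: SyntheticConfig, rng: np.random.Generator,
                    grid: Grid) -> list[ForestPolygon]:
    """Non-overlapping axis-aligned rectangles, one per tile slot.

    Rectangle corners snap to cell boundaries, so rasterization is exact and
    polygon cell sets partition cleanly.
    """
    total = sum(spec.n_polygons for spec in cfg.datasets)
    ntiles = int(np.ceil(np.sqrt(total)))
    tile_r = cfg.nrows // ntiles
    tile_c = cfg.ncols // ntiles
    if tile_r < 8 or tile_c < 8:
        raise ValueError("grid too small for the requested polygon count")
    slots = [(i, j) for i in range(ntiles) for j in range(ntiles)]
    rng.shuffle(slots)

    x0, y0 = grid.origin
    s = grid.cell_size
    polygons: list[ForestPolygon] = []
    k = 0
    for spec in cfg.datasets:
        for p in range(spec.n_polygons):
            ti, tj = slots[k]
            k += 1
            # Margin of 2 cells inside the tile; occupy 60-90% of the rest.
            max_h = tile_r - 4
            max_w = tile_c - 4
            h = int(rng.integers(max(2, int(0.6 * max_h)), max_h + 1))
            w = int(rng.integers(max(2, int(0.6 * max_w)), max_w + 1))
            r0 = ti * tile_r + 2 + int(rng.integers(0, max_h - h + 1))
            c0 = tj * tile_c + 2 + int(rng.integers(0, max_w - w + 1))
            geom = box(
                x0 + c0 * s,
                y0 - (r0 + h) * s,
                x0 + (c0 + w) * s,
                y0 - r0 * s,
            )
            polygons.append(
                ForestPolygon(
                    polygon_id=f"{spec.dataset_id}-{p:03d}",
                    dataset_id=spec.dataset_id,
                    geometry=geom,
                    country=spec.country,
                    bioregion=spec.bioregion,
                    in_eu=spec.in_eu,
                )
            )
    return polygons


def _grow_patch(seed_rc: tuple[int, int], target: int, eligible: np.ndarray,
                regime: np.ndarray, rng: np.random.Generator) -> tuple[list[int], list[int]]:
    """Stochastic rook-neighbor region growing from a seed cell.

    Growth is confined to cells sharing the seed's hazard regime: the regime
    is a stand-level property (the owning dataset's mapping year), so a
    synthetic event never straddles a regime boundary.
    """
    nrows, ncols = eligible.shape
    reg = regime[seed_rc]
    rows = [seed_rc[0]]
    cols = [seed_rc[1]]
    eligible[seed_rc] = False
    frontier = [seed_rc]
    while len(rows) < target and frontier:
        # Candidate neighbors of the current patch.
        cand = []
        for r, c in frontier:
            for dr, dc in _NEIGH:
                rr, cc = r + dr, c + dc
                if (0 <= rr < nrows and 0 <= cc < ncols and eligible[rr, cc]
                        and regime[rr, cc] == reg):
                    cand.append((rr, cc))
        if not cand:
            break
        rr, cc = cand[int(rng.integers(0, len(cand)))]
        eligible[rr, cc] = False
        rows.append(rr)
        cols.append(cc)
        frontier.append((rr, cc))
    return rows, cols


def generate(cfg: SyntheticConfig) -> SyntheticLandscape:
    """Generate one landscape bundle; bit-deterministic under ``cfg.seed``.

    When ``cfg.anthro_hazard_pre > 0`` (selection-bias mode) an extra labeled
    "anthropogenic" disturbance stream runs inside candidate documented
    polygons before their mapping year, and any candidate polygon it touches
    is excluded from the documented layer - mirroring how mapped primary
    forests omit stands visibly disturbed by people before the survey.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = Grid(cfg.nrows, cfg.ncols, cfg.cell_size, origin=(0.0, float(cfg.nrows) * cfg.cell_size))
    forest = _forest_mask(cfg, rng)
    polygons = _place_polygons(cfg, rng, grid)
    datasets = [
        PolygonDataset(spec.dataset_id, spec.status, spec.mapping_year)
        for spec in cfg.datasets
    ]
    ds_mapping = {d.dataset_id: d.mapping_year for d in datasets}

    # Per-cell mapping-year map: documented polygon cells switch hazards at
    # their dataset's mapping year; all other cells keep hazard_pre.
    from .geodata import rasterize_polygon  # local to avoid cycle at import

    mapping_map = np.full(grid.shape, cfg.year_max + 1, dtype=np.int32)
    poly_cells: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for poly in polygons:
        rc = rasterize_polygon(poly, grid)
        poly_cells[poly.polygon_id] = rc
        my = ds_mapping[poly.dataset_id]
        if my is not None:
            mapping_map[rc] = my

    year = np.zeros(grid.shape, dtype=np.int16)
    severity = np.full(grid.shape, SEV_NODATA, dtype=np.float32)
    anthro = np.zeros(grid.shape, dtype=bool)
    eligible = forest.copy()
    mean_size = cfg.mean_patch_size
    g = cfg.patch_growth

    # The nominal hazard is the marginal per-forest-cell annual disturbance
    # probability.  Cells are disturbed at most once, so the eligible pool
    # shrinks over the years; the seed probability is therefore conditioned
    # on the eligible pool per hazard regime (p = h/m * N_forest/N_eligible)
    # to keep the marginal probability at the nominal hazard throughout.
    regime_vals, regime_idx = np.unique(mapping_map, return_inverse=True)
    regime_idx = regime_idx.reshape(grid.shape)
    n_forest_by_regime = np.bincount(regime_idx[forest], minlength=regime_vals.size)

    for y in range(cfg.year_min, cfg.year_max + 1):
        hazard = np.where(y <= mapping_map, cfg.hazard_pre, cfg.hazard_post)
        n_elig = np.bincount(regime_idx[eligible], minlength=regime_vals.size)
        with np.errstate(divide="ignore", invalid="ignore"):
            comp = np.where(n_elig > 0, n_forest_by_regime / np.maximum(n_elig, 1), 1.0)
        p_seed = np.minimum(hazard * comp[regime_idx] / mean_size, 1.0)
        if cfg.anthro_hazard_pre > 0:
            p_anthro = np.where(
                (y <= mapping_map) & (mapping_map <= cfg.year_max),
                cfg.anthro_hazard_pre / mean_size, 0.0,
            )
        draws = rng.random(grid.shape)
        seeds = np.argwhere(eligible & (draws < p_seed))
        if cfg.anthro_hazard_pre > 0:
            anthro_seeds = np.argwhere(eligible & (draws >= p_seed) & (draws < p_seed + p_anthro))
        else:
            anthro_seeds = np.empty((0, 2), dtype=int)

        for is_anthro, seed_list in ((False, seeds), (True, anthro_seeds)):
            for sr, sc in seed_list:
                if not eligible[sr, sc]:
                    continue  # consumed by an earlier patch this year
                target = 2 + int(rng.geometric(1.0 - g) - 1)
                rows, cols = _grow_patch((int(sr), int(sc)), target, eligible,
                                         mapping_map, rng)
                year[rows, cols] = y
                if is_anthro:
                    anthro[rows, cols] = True
                if y <= cfg.severity_year_max:
                    base = rng.beta(cfg.severity_alpha, cfg.severity_beta)
                    jitter = rng.normal(0.0, cfg.severity_jitter_sd, size=len(rows))
                    severity[rows, cols] = np.clip(base + jitter, 0.0, 1.0)

    # Selection-bias exclusion: candidate documented polygons containing any
    # pre-mapping anthropogenic disturbance are dropped from the layer.
    n_candidates = sum(1 for p in polygons if ds_mapping[p.dataset_id] is not None)
    excluded: set[str] = set()
    if cfg.anthro_hazard_pre > 0:
        for poly in polygons:
            if ds_mapping[poly.dataset_id] is None:
                continue
            rc = poly_cells[poly.polygon_id]
            if anthro[rc].any():
                excluded.add(poly.polygon_id)
    kept_polygons = [p for p in polygons if p.polygon_id not in excluded]

    layers = DisturbanceLayers(
        grid=grid,
        year=year,
        severity=severity,
        forest=forest,
        year_min=cfg.year_min,
        year_max=cfg.year_max,
        severity_year_max=cfg.severity_year_max,
    )
    truth = TruthRecord(
        hazard_pre=cfg.hazard_pre,
        hazard_post=cfg.hazard_post,
        expected_rate_pre=100.0 * cfg.hazard_pre,
        expected_rate_post=100.0 * cfg.hazard_post,
        severity_mean=cfg.severity_alpha / (cfg.severity_alpha + cfg.severity_beta),
        mapping_years=dict(ds_mapping),
        mean_patch_size=mean_size,
        n_candidate_polygons=n_candidates,
        n_excluded_polygons=len(excluded),
        realized_disturbed_fraction=float((year != UNDISTURBED)[forest].mean()) if forest.any() else 0.0,
    )
    return SyntheticLandscape(layers, kept_polygons, datasets, truth)


def fixture_config(seed: int = 7) -> SyntheticConfig:
    """A tiny deterministic bundle (64x64) used by the test suite.

    Hazards are raised well above the study defaults so the small grid still
    contains enough patches to exercise every code path.
    """
    return SyntheticConfig(
        nrows=64,
        ncols=64,
        hazard_pre=0.004,
        hazard_post=0.010,
        forest_cover_fraction=0.7,
        datasets=(
            DatasetSpec("D1", DOCUMENTED, 2012, "RO", "Continental", True, 2),
            DatasetSpec("D2", DOCUMENTED, 2015, "SE", "Boreal", True, 2),
            DatasetSpec("P1", POTENTIAL, None, "NO", "Alpine-Scandinavian", False, 2),
        ),
        seed=seed,
    )
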