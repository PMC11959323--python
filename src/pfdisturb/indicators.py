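"""Disturbance indicators over primary-forest polygon layers.

Disturbed cells inside each polygon are attributed to the period *predating*
(disturbance year <= the dataset's mapping year, natural by assumption) or
*postdating* (later, natural or anthropogenic) the survey of the polygon's
source dataset.  Potential primary forests have no mapping year and are
assessed over the full window.  Three indicator expressions are computed per
stratum (country, biogeographical region, EU, Europe) and status:

* total disturbed area (ha),
* proportion of forest area disturbed (%),
* mean annual rate of area disturbed (% of forest area per year), which
  normalizes the unequal pre/post window lengths.

Denominators are the MMU-filtered forest-mask area within the polygons, so
numerators count only disturbed cells that are also forest-mask cells inside
a polygon.  Proportions and rates are always recomputed from pooled areas at
each aggregation level, never averaged across members; with mixed mapping
years the rate pools area-time exposure: ``100 * sum(disturbed) /
sum(forest_d * n_years_d)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geodata import (
    DOCUMENTED,
    POTENTIAL,
    DisturbanceLayers,
    ForestPolygon,
    PolygonDataset,
    cell_area_ha,
    rasterize_polygon,
)
from .patching import MmuRule, Patch, apply_mmu, filtered_forest_mask, label_patches, patch_label_raster

PRE = "PRE"
POST = "POST"
FULL = "FULL"

LEVELS = ("country", "bioregion", "eu", "europe")


class IndicatorError(ValueError):
    pass


@dataclass(frozen=True)
class Period:
    """An attribution window within the disturbance record."""

    label: str
    start_year: int
    end_year: int

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1


def periods_for(mapping_year: int | None, year_min: int, year_max: int) -> dict[str, Period | None]:
    """PRE/POST windows for a documented dataset, or FULL for a potential one.

    PRE ends at the mapping year inclusive; POST starts the year after.  A
    dataset mapped in the final year has an empty POST window (``None``).
    """
    if mapping_year is None:
        return {FULL: Period(FULL, year_min, year_max)}
    if not (year_min <= mapping_year <= year_max):
        raise IndicatorError(f"mapping year {mapping_year} outside [{year_min}, {year_max}]")
    post = Period(POST, mapping_year + 1, year_max) if mapping_year < year_max else None
    return {PRE: Period(PRE, year_min, mapping_year), POST: post}


def attribute_period(disturbance_year: int, mapping_year: int,
                     year_min: int = 1986, year_max: int = 2020) -> str:
    """PRE if the disturbance occurred before or during the mapping year, else POST."""
    for name, y in (("disturbance", disturbance_year), ("mapping", mapping_year)):
        if not (year_min <= y <= year_max):
            raise IndicatorError(f"{name} year {y} outside [{year_min}, {year_max}]")
    return PRE if disturbance_year <= mapping_year else POST


def proportion_disturbed(disturbed_ha: float, total_forest_ha: float) -> float | None:
    """Percent of forest area disturbed; ``None`` when there is no forest."""
    if total_forest_ha <= 0:
        return None
    return 100.0 * disturbed_ha / total_forest_ha


def annual_rate(disturbed_ha: float, forest_ha: float, n_years: int) -> float:
    """Mean annual rate of area disturbed, in percent of forest area per year."""
    if n_years < 1:
        raise IndicatorError(f"n_years must be >= 1, got {n_years}")
    if forest_ha <= 0:
        raise IndicatorError("forest_ha must be positive")
    return 100.0 * disturbed_ha / (forest_ha * n_years)


def rate_change(rate_pre: float, rate_post: float) -> float:
    """Postdating minus predating mean annual rate."""
    return rate_post - rate_pre


def weighted_mean_mapping_year(areas_ha: Sequence[float], mapping_years: Sequence[int]) -> float:
    """Mean mapping year of the datasets, weighted by their polygon area."""
    areas = np.asarray(areas_ha, dtype=float)
    years = np.asarray(mapping_years, dtype=float)
    if areas.size == 0 or areas.sum() <= 0:
        raise IndicatorError("weighted mean mapping year requires positive total area")
    return float((areas * years).sum() / areas.sum())


def polygon_forest_area(cells: tuple[np.ndarray, np.ndarray], forest_mask: np.ndarray,
                        grid) -> float:
    """Forest area (ha) of the polygon cells under an MMU-filtered mask."""
    rows, cols = cells
    if rows.size == 0:
        return 0.0
    return float(forest_mask[rows, cols].sum()) * cell_area_ha(grid)


def disturbed_area_by_period(cells: tuple[np.ndarray, np.ndarray], patches: Sequence[Patch],
                             mapping_year: int | None, grid,
                             year_min: int = 1986, year_max: int = 2020) -> dict[str, float]:
    """Disturbed area (ha) inside a polygon split by attribution period.

    ``patches`` must already be MMU-filtered and ``cells`` intersected with
    the filtered forest mask.  With ``mapping_year=None`` (potential data)
    everything lands in FULL.
    """
    rows, cols = cells
    cellset = set(zip(rows.tolist(), cols.tolist()))
    area = cell_area_ha(grid)
    if mapping_year is None:
        out = {FULL: 0.0}
    else:
        out = {PRE: 0.0, POST: 0.0}
    for p in patches:
        inside = sum((r, c) in cellset for r, c in zip(p.rows.tolist(), p.cols.tolist()))
        if inside == 0:
            continue
        key = FULL if mapping_year is None else attribute_period(p.year, mapping_year, year_min, year_max)
        out[key] += inside * area
    return out


# ---------------------------------------------------------------------------
# Vectorized polygon/patch overlay
# ---------------------------------------------------------------------------

@dataclass
class Overlay:
    """Cell-resolved intersection of patches, polygons, and the forest mask.

    ``polygon_df`` has one row per polygon (attributes + forest area).
    ``contrib_df`` has one row per (patch, polygon) pair with at least one
    disturbed forest cell inside the polygon: the disturbed area contributed,
    the patch's disturbance year, and the patch-level mean severity (over all
    of the patch's cells, the any-cell membership rule).
    """

    polygon_df: pd.DataFrame
    contrib_df: pd.DataFrame
    patches: list[Patch]
    forest_mask: np.ndarray
    cell_area_ha: float
    year_min: int
    year_max: int
    severity_year_max: int


def overlay(layers: DisturbanceLayers, polygons: Sequence[ForestPolygon],
            datasets: Sequence[PolygonDataset], mmu: MmuRule = MmuRule()) -> Overlay:
    """Delineate patches, apply the MMU, and resolve polygons to cell sets.

    Cells covered by documented polygons are removed from potential polygons
    (documented wins on overlap); polygons of the same status are assumed
    non-overlapping.
    """
    ds_by_id = {d.dataset_id: d for d in datasets}
    for p in polygons:
        if p.dataset_id not in ds_by_id:
            raise IndicatorError(f"polygon {p.polygon_id!r} references unknown dataset {p.dataset_id!r}")

    fmask = filtered_forest_mask(layers, mmu)
    patches = apply_mmu(label_patches(layers, "disturbance"), mmu)
    plabel = patch_label_raster(patches, layers.grid)  # patch index + 1
    area = cell_area_ha(layers.grid)

    documented_cells = np.zeros(layers.grid.shape, dtype=bool)
    for p in polygons:
        if ds_by_id[p.dataset_id].status == DOCUMENTED:
            rows, cols = rasterize_polygon(p, layers.grid)
            documented_cells[rows, cols] = True

    poly_rows = []
    contrib_rows = []
    for p in polygons:
        ds = ds_by_id[p.dataset_id]
        rows, cols = rasterize_polygon(p, layers.grid)
        if ds.status == POTENTIAL and rows.size:
            keep = ~documented_cells[rows, cols]
            rows, cols = rows[keep], cols[keep]
        n_cells = int(rows.size)
        if n_cells:
            in_forest = fmask[rows, cols]
            forest_ha = float(in_forest.sum()) * area
            lab = plabel[rows, cols]
            sel = (lab > 0) & in_forest
            counts = np.bincount(lab[sel], minlength=len(patches) + 1)
            for idx in np.nonzero(counts)[0]:
                patch = patches[idx - 1]
                contrib_rows.append(
                    {
                        "patch_idx": int(idx - 1),
                        "polygon_id": p.polygon_id,
                        "dataset_id": p.dataset_id,
                        "status": ds.status,
                        "country": p.country,
                        "bioregion": p.bioregion,
                        "in_eu": p.in_eu,
                        "year": patch.year,
                        "area_ha": float(counts[idx]) * area,
                        "patch_area_ha": patch.area_ha,
                        "mean_severity": patch.mean_severity,
                    }
                )
        else:
            forest_ha = 0.0
        poly_rows.append(
            {
                "polygon_id": p.polygon_id,
                "dataset_id": p.dataset_id,
                "status": ds.status,
                "mapping_year": ds.mapping_year,
                "country": p.country,
                "bioregion": p.bioregion,
                "in_eu": p.in_eu,
                "n_cells": n_cells,
                "forest_area_ha": forest_ha,
            }
        )

    contrib_cols = ["patch_idx", "polygon_id", "dataset_id", "status", "country",
                    "bioregion", "in_eu", "year", "area_ha", "patch_area_ha", "mean_severity"]
    poly_cols = ["polygon_id", "dataset_id", "status", "mapping_year", "country",
                 "bioregion", "in_eu", "n_cells", "forest_area_ha"]
    contrib_df = pd.DataFrame(contrib_rows, columns=contrib_cols)
    return Overlay(
        polygon_df=pd.DataFrame(poly_rows, columns=poly_cols),
        contrib_df=contrib_df,
        patches=patches,
        forest_mask=fmask,
        cell_area_ha=area,
        year_min=layers.year_min,
        year_max=layers.year_max,
        severity_year_max=layers.severity_year_max,
    )


# ---------------------------------------------------------------------------
# Stratified aggregation
# ---------------------------------------------------------------------------

@dataclass
class IndicatorRecord:
    """One stratum x status x period indicator row (Table-2/4 style)."""

    level: str
    code: str
    status: str
    period: str
    forest_area_ha: float
    disturbed_area_ha: float
    proportion_pct: float | None
    rate_pct_per_year: float | None
    n_years_equiv: float | None
    exposure_ha_years: float
    n_patches: int
    severity_mean: float | None = None
    severity_n_patches: int = 0
    disturbed_ci_low: float | None = None
    disturbed_ci_high: float | None = None
    rate_ci_low: float | None = None
    rate_ci_high: float | None = None
    severity_ci_low: float | None = None
    severity_ci_high: float | None = None
    # Patch-level contribution arrays for resampling; not serialized.
    contrib_areas: np.ndarray | None = field(default=None, repr=False, compare=False)
    severities: np.ndarray | None = field(default=None, repr=False, compare=False)


def _strata(polygon_df: pd.DataFrame, levels: Sequence[str]) -> list[tuple[str, str, pd.Series]]:
    out = []
    for level in levels:
        if level == "country":
            for code in sorted(polygon_df["country"].unique()):
                out.append((level, code, polygon_df["country"] == code))
        elif level == "bioregion":
            for code in sorted(polygon_df["bioregion"].unique()):
                out.append((level, code, polygon_df["bioregion"] == code))
        elif level == "eu":
            out.append((level, "EU", polygon_df["in_eu"].astype(bool)))
        elif level == "europe":
            out.append((level, "EUROPE", pd.Series(True, index=polygon_df.index)))
        else:
            raise IndicatorError(f"unknown stratification level {level!r}")
    return out


def aggregate(ov: Overlay, datasets: Sequence[PolygonDataset],
              levels: Sequence[str] = LEVELS) -> list[IndicatorRecord]:
    """Indicator records for every stratum, status, and period.

    Documented strata yield PRE and POST records; potential strata yield one
    FULL record.  Areas sum across member polygons; proportions and rates are
    recomputed from the pooled areas and pooled area-time exposure.  Severity
    is the unweighted mean of member patch mean severities, each patch counted
    once per stratum even if it touches several member polygons.
    """
    ds_by_id = {d.dataset_id: d for d in datasets}
    pdf, cdf = ov.polygon_df, ov.contrib_df
    records: list[IndicatorRecord] = []

    # Vectorized period attribution for every (patch, polygon) contribution.
    cdf = cdf.copy()
    if not cdf.empty:
        mapping = cdf["dataset_id"].map(lambda d: ds_by_id[d].mapping_year)
        cdf["period"] = np.where(
            mapping.isna(), FULL, np.where(cdf["year"] <= mapping.fillna(0), PRE, POST)
        )
    else:
        cdf["period"] = pd.Series(dtype=object)

    # Window length per dataset and period, for pooled area-time exposure.
    n_years_of = {
        (d.dataset_id, lbl): (per.n_years if per is not None else 0)
        for d in datasets
        for lbl, per in periods_for(d.mapping_year, ov.year_min, ov.year_max).items()
    }

    for level, code, poly_sel in _strata(pdf, levels):
        for status in (DOCUMENTED, POTENTIAL):
            members = pdf[poly_sel & (pdf["status"] == status)]
            if members.empty:
                continue
            member_ids = set(members["polygon_id"])
            contribs = cdf[cdf["polygon_id"].isin(member_ids)] if not cdf.empty else cdf
            forest_ha = float(members["forest_area_ha"].sum())

            period_labels = [FULL] if status == POTENTIAL else [PRE, POST]

            for plabel in period_labels:
                exposure = float(
                    sum(
                        poly_forest * n_years_of.get((ds_id, plabel), 0)
                        for ds_id, poly_forest in zip(members["dataset_id"], members["forest_area_ha"])
                    )
                )
                sub = contribs[contribs["period"] == plabel] if not contribs.empty else contribs
                areas = sub["area_ha"].to_numpy(dtype=float) if not sub.empty else np.empty(0)
                disturbed = float(areas.sum())
                if not sub.empty:
                    sev_sub = sub.dropna(subset=["mean_severity"]).drop_duplicates("patch_idx")
                    sev_vals = np.sort(sev_sub["mean_severity"].to_numpy(dtype=float))
                else:
                    sev_vals = np.empty(0)

                rate = 100.0 * disturbed / exposure if exposure > 0 else None
                n_years_equiv = exposure / forest_ha if forest_ha > 0 else None
                records.append(
                    IndicatorRecord(
                        level=level,
                        code=code,
                        status=status,
                        period=plabel,
                        forest_area_ha=forest_ha,
                        disturbed_area_ha=disturbed,
                        proportion_pct=proportion_disturbed(disturbed, forest_ha),
                        rate_pct_per_year=rate,
                        n_years_equiv=n_years_equiv,
                        exposure_ha_years=exposure,
                        n_patches=len(areas),
                        severity_mean=float(sev_vals.mean()) if sev_vals.size else None,
                        severity_n_patches=int(sev_vals.size),
                        contrib_areas=np.asarray(areas, dtype=float),
                        severities=sev_vals,
                    )
                )
    return records


_FRAME_COLS = [f.name for f in fields(IndicatorRecord) if f.name not in ("contrib_areas", "severities")]


def records_frame(records: Iterable[IndicatorRecord]) -> pd.DataFrame:
    """Tidy one-row-per-record DataFrame (CSV-ready, resampling arrays dropped)."""
    return pd.DataFrame([{c: getattr(r, c) for c in _FRAME_COLS} for r in records],
                        columns=_FRAME_COLS)
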