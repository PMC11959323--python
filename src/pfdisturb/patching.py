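"""Patch delineation by rook contiguity and minimum-mapping-unit filtering.

Disturbance patches are maximal 4-connected (rook) components of cells
sharing the same disturbance year; cells disturbed in different years never
share a patch, because the source product is annual and severity is
aggregated at patch level per year.  Forest patches are 4-connected
components of the forest mask.  The minimum mapping unit (MMU) removes
patches below a cell-count threshold (default 2 cells, i.e. 0.18 ha on a
30-m grid) from both the disturbance map and the forest mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geodata import UNDISTURBED, DisturbanceLayers, Grid, cell_area_ha

#: Rook (4-neighbor) structuring element.
ROOK = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class PatchingError(ValueError):
    pass


@dataclass(frozen=True)
class MmuRule:
    """Minimum mapping unit expressed in cells.

    The hectare figure follows from the grid (``min_cells * cell_area_ha``),
    which keeps the rule meaningful on non-30-m synthetic grids.
    """

    min_cells: int = 2

    def __post_init__(self) -> None:
        if self.min_cells < 1:
            raise PatchingError(f"min_cells must be >= 1, got {self.min_cells}")

    def min_area_ha(self, grid: Grid) -> float:
        return self.min_cells * cell_area_ha(grid)


@dataclass
class Patch:
    """A rook-connected set of same-year disturbed cells (or forest cells).

    ``mean_severity`` is the arithmetic mean severity over the patch's cells;
    it is ``None`` for forest patches, for disturbance years past the severity
    window, and for patches containing any nodata severity cell (such patches
    are flagged via ``severity_nodata`` and excluded from severity summaries).
    """

    patch_id: int
    year: int | None
    rows: np.ndarray
    cols: np.ndarray
    area_ha: float
    mean_severity: float | None = None
    severity_nodata: bool = False

    @property
    def n_cells(self) -> int:
        return int(self.rows.size)

    @property
    def cells(self) -> list[tuple[int, int]]:
        return list(zip(self.rows.tolist(), self.cols.tolist()))


def _components(mask: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Index arrays of each rook-connected component of a boolean mask."""
    labels, n = ndimage.label(mask, structure=ROOK)
    if n == 0:
        return []
    rows, cols = np.nonzero(labels)
    lab = labels[rows, cols]
    order = np.argsort(lab, kind="stable")
    rows, cols, lab = rows[order], cols[order], lab[order]
    counts = np.bincount(lab, minlength=n + 1)[1:]
    splits = np.cumsum(counts)[:-1]
    return list(zip(np.split(rows, splits), np.split(cols, splits)))


def label_patches(layers: DisturbanceLayers, scope: str = "disturbance") -> list[Patch]:
    """Delineate patches by rook contiguity.

    For ``scope="disturbance"``, components are formed per disturbance year
    and carry the mean cell severity when the year falls in the severity
    window and every cell has valid severity.  For ``scope="forest"``,
    components of the forest mask are returned with ``year=None``.
    """
    if scope not in ("disturbance", "forest"):
        raise PatchingError(f"unknown scope {scope!r}")
    area = cell_area_ha(layers.grid)
    patches: list[Patch] = []
    pid = 0
    if scope == "forest":
        for rows, cols in _components(layers.forest):
            patches.append(Patch(pid, None, rows, cols, rows.size * area))
            pid += 1
        return patches

    years = np.unique(layers.year[layers.year != UNDISTURBED])
    for y in years.tolist():
        for rows, cols in _components(layers.year == y):
            mean_sev = None
            nodata = False
            if y <= layers.severity_year_max:
                sev = layers.severity[rows, cols]
                if (sev < 0).any():
                    nodata = True
                else:
                    mean_sev = float(sev.mean())
            patches.append(
                Patch(pid, int(y), rows, cols, rows.size * area, mean_sev, nodata)
            )
            pid += 1
    return patches


def apply_mmu(patches: list[Patch], rule: MmuRule) -> list[Patch]:
    """Keep patches meeting the MMU (``n_cells >= min_cells``), preserving order.

    The boundary is inclusive: a 2-cell patch is exactly the minimum mapping
    unit and is retained.
    """
    return [p for p in patches if p.n_cells >= rule.min_cells]


def filtered_forest_mask(layers: DisturbanceLayers, rule: MmuRule) -> np.ndarray:
    """Forest mask with sub-MMU forest components removed."""
    labels, n = ndimage.label(layers.forest, structure=ROOK)
    if n == 0:
        return np.zeros(layers.grid.shape, dtype=bool)
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    keep = counts >= rule.min_cells
    keep[0] = False
    return keep[labels]


def patch_label_raster(patches: list[Patch], grid: Grid) -> np.ndarray:
    """Raster of patch indices + 1 (0 = no patch) for cell-level overlay."""
    out = np.zeros(grid.shape, dtype=np.int32)
    for i, p in enumerate(patches):
        out[p.rows, p.cols] = i + 1
    return out


def patch_table(patches: list[Patch]):
    """Patch attribute table (patch_id, year, n_cells, area_ha, mean_severity, centroid)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "patch_id": [p.patch_id for p in patches],
            "year": [p.year for p in patches],
            "n_cells": [p.n_cells for p in patches],
            "area_ha": [p.area_ha for p in patches],
            "mean_severity": [p.mean_severity for p in patches],
            "centroid_row": [float(p.rows.mean()) for p in patches],
            "centroid_col": [float(p.cols.mean()) for p in patches],
        }
    )
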