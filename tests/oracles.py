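"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid scipy.ndimage and the package's own labeling code:
components are grown by an explicit BFS flood fill over 4-neighborhoods.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def flood_fill_components(mask: np.ndarray) -> list[frozenset[tuple[int, int]]]:
    """4-connected components of a boolean mask via BFS flood fill."""
    nrows, ncols = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r0 in range(nrows):
        for c0 in range(ncols):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            comp = set()
            queue = deque([(r0, c0)])
            seen[r0, c0] = True
            while queue:
                r, c = queue.popleft()
                comp.add((r, c))
                for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                    if 0 <= rr < nrows and 0 <= cc < ncols and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        queue.append((rr, cc))
            comps.append(frozenset(comp))
    return comps


def year_partition(year: np.ndarray) -> set[tuple[int, frozenset[tuple[int, int]]]]:
    """Set of (year, cellset) patches: per-year 4-connected components."""
    out = set()
    for y in np.unique(year[year > 0]).tolist():
        for comp in flood_fill_components(year == y):
            out.add((int(y), comp))
    return out


def mmu_filter_cells(partition, min_cells: int):
    """Brute-force MMU filter on a (year, cellset) partition."""
    return {p for p in partition if len(p[1]) >= min_cells}


def repaint_filtered_mask(mask: np.ndarray, min_cells: int) -> np.ndarray:
    """Label, filter, repaint oracle for forest-mask MMU filtering."""
    out = np.zeros_like(mask, dtype=bool)
    for comp in flood_fill_components(mask):
        if len(comp) >= min_cells:
            for r, c in comp:
                out[r, c] = True
    return out


def disturbed_area_double_loop(cells, year: np.ndarray, kept_mask: np.ndarray,
                               mapping_year: int, cell_area: float) -> dict[str, float]:
    """Cell-by-cell PRE/POST disturbed-area accounting inside a polygon."""
    out = {"PRE": 0.0, "POST": 0.0}
    cellset = set(zip(cells[0].tolist(), cells[1].tolist()))
    for r, c in cellset:
        if kept_mask[r, c] and year[r, c] > 0:
            key = "PRE" if year[r, c] <= mapping_year else "POST"
            out[key] += cell_area
    return out
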