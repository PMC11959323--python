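"""Patch-level and stratum-level disturbance-severity statistics.

Severity is a per-cell canopy-loss index in [0, 1] (1 = complete canopy
loss), valid for disturbance years up to the severity window end (2016 by
default even though the disturbance record runs to 2020).  A patch's
severity is the arithmetic mean over its cells; a stratum's severity is the
unweighted mean over its patches' means, so a 2-cell patch counts as much as
a 100-cell patch.  Patch membership in a polygon (and hence a stratum)
follows the any-cell rule: one shared cell is enough, and the patch mean is
computed over all of the patch's cells, not just the cells inside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geodata import DisturbanceLayers
from .patching import Patch


class SeverityError(ValueError):
    pass


@dataclass
class SeveritySummary:
    """Stratum x status x period severity row (Table-3 style)."""

    stratum: str
    status: str
    period: str
    n_patches: int
    mean_severity: float | None
    ci_low: float | None = None
    ci_high: float | None = None


def patch_mean_severity(patch: Patch, layers: DisturbanceLayers) -> float:
    """Arithmetic mean severity over a patch's cells.

    Raises for patches outside the severity window or containing nodata
    cells; the pipeline flags such patches and excludes them from summaries
    instead of calling this.
    """
    if patch.year is None or patch.year > layers.severity_year_max:
        raise SeverityError(
            f"patch year {patch.year} outside severity window (<= {layers.severity_year_max})"
        )
    sev = layers.severity[patch.rows, patch.cols]
    if (sev < 0).any():
        raise SeverityError(f"patch {patch.patch_id} contains nodata severity cells")
    return float(sev.mean())


def stratum_mean_severity(patch_means, stratum: str = "", status: str = "",
                          period: str = "") -> SeveritySummary:
    """Unweighted mean of patch mean severities for one stratum/period."""
    vals = np.asarray(list(patch_means), dtype=float)
    if vals.size == 0:
        return SeveritySummary(stratum, status, period, 0, None)
    if (vals < 0).any() or (vals > 1).any():
        raise SeverityError("patch severities must lie in [0, 1]")
    return SeveritySummary(stratum, status, period, int(vals.size), float(vals.mean()))


def severity_change(mean_pre: float, mean_post: float) -> float:
    """Postdating minus predating mean severity."""
    return mean_post - mean_pre
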