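"""End-to-end assessment: overlay -> indicators -> CIs -> tests -> sensitivity.

This is the programmatic surface behind the ``assess`` CLI subcommand and
the reproduction script: one call turns co-registered layers plus polygon
datasets into the tidy indicator, severity, test, and sensitivity tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .geodata import DisturbanceLayers, ForestPolygon, PolygonDataset
from .indicators import LEVELS, IndicatorRecord, Overlay, aggregate, overlay, records_frame
from .inference import (
    DEFAULT_SHIFTS,
    BootstrapSpec,
    SensitivityResult,
    attach_cis,
    sensitivity_analysis,
    stratum_tests,
)
from .patching import MmuRule


@dataclass
class AssessmentConfig:
    """Tunable knobs of one assessment run (defaults = study conditions)."""

    mmu: MmuRule = field(default_factory=MmuRule)
    bootstrap: BootstrapSpec = field(default_factory=BootstrapSpec)
    mw_max_n: int = 1000
    shifts: Sequence[int] = DEFAULT_SHIFTS
    levels: Sequence[str] = LEVELS


@dataclass
class AssessmentResult:
    overlay: Overlay
    records: list[IndicatorRecord]
    indicator_table: pd.DataFrame
    test_table: pd.DataFrame
    sensitivity: list[SensitivityResult]
    sensitivity_table: pd.DataFrame


def assess(layers: DisturbanceLayers, polygons: Sequence[ForestPolygon],
           datasets: Sequence[PolygonDataset],
           config: AssessmentConfig | None = None) -> AssessmentResult:
    """Run the full disturbance assessment.

    Returns the raw records (with resampling arrays attached) plus tidy
    tables ready for CSV export.  Deterministic for a fixed bootstrap seed.
    """
    cfg = config or AssessmentConfig()
    ov = overlay(layers, polygons, datasets, cfg.mmu)
    records = aggregate(ov, datasets, levels=cfg.levels)
    attach_cis(records, cfg.bootstrap, cell_area_ha=ov.cell_area_ha)
    tests = stratum_tests(records, cfg.bootstrap, max_n=cfg.mw_max_n)
    sens = sensitivity_analysis(ov, datasets, shifts=cfg.shifts, levels=cfg.levels)

    sens_rows = []
    for res in sens:
        frame = records_frame(res.records)
        frame.insert(0, "shift", res.shift)
        sens_rows.append(frame)
    sensitivity_table = (
        pd.concat(sens_rows, ignore_index=True) if sens_rows else pd.DataFrame()
    )
    test_cols = ["level", "code", "kind", "statistic", "p_value", "n_pre", "n_post", "stars"]
    return AssessmentResult(
        overlay=ov,
        records=records,
        indicator_table=records_frame(records),
        test_table=pd.DataFrame(tests, columns=test_cols),
        sensitivity=sens,
        sensitivity_table=sensitivity_table,
    )
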