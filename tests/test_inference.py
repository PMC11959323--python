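import numpy as np
import pytest

from conftest import make_layers
from pfdisturb.geodata import ForestPolygon, PolygonDataset
from pfdisturb.indicators import POST, PRE, aggregate, overlay, records_frame
from pfdisturb.inference import (
    BootstrapSpec,
    InferenceError,
    attach_cis,
    bootstrap_ci,
    mann_whitney_severity_test,
    rate_difference_test,
    sensitivity_analysis,
    significance_stars,
)


def test_bootstrap_ci_constant_values_collapse():
    assert bootstrap_ci([5.0, 5.0, 5.0], "mean", BootstrapSpec(n_iter=200, seed=0)) == (5.0, 5.0)


def test_bootstrap_ci_single_value_degenerate():
    lo, hi = bootstrap_ci([3.0], "mean", BootstrapSpec(n_iter=100, seed=0))
    assert lo == hi == 3.0


def test_bootstrap_ci_empty_input_rejected():
    with pytest.raises(InferenceError):
        bootstrap_ci([], "mean", BootstrapSpec(n_iter=10, seed=0))


def test_bootstrap_ci_reproducible_and_order_invariant():
    rng = np.random.default_rng(1)
    vals = rng.exponential(size=40)
    spec = BootstrapSpec(n_iter=2000, seed=42)
    a = bootstrap_ci(vals, "total", spec)
    b = bootstrap_ci(vals[::-1], "total", spec)
    assert a == b


def test_bootstrap_ci_contains_point_statistic():
    rng = np.random.default_rng(2)
    vals = rng.gamma(2.0, size=60)
    lo, hi = bootstrap_ci(vals, "mean", BootstrapSpec(n_iter=2000, seed=3))
    assert lo <= vals.mean() <= hi
    lo, hi = bootstrap_ci(vals, "total", BootstrapSpec(n_iter=2000, seed=3))
    assert lo <= vals.sum() <= hi


def test_rate_difference_null_by_construction():
    areas = [0.18, 0.27, 0.09, 0.36] * 10
    res = rate_difference_test(areas, 1000.0, areas, 1000.0, BootstrapSpec(n_iter=2000, seed=5))
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value > 0.5


def test_rate_difference_maximal_separation_hits_floor():
    spec = BootstrapSpec(n_iter=1000, seed=6)
    res = rate_difference_test([0.18] * 2, 1000.0, [0.27] * 80, 1000.0, spec)
    assert res.statistic > 0
    assert res.p_value <= 4 / spec.n_iter


def test_rate_difference_empty_period_yields_null_p():
    res = rate_difference_test([], 1000.0, [0.27] * 5, 1000.0, BootstrapSpec(n_iter=100, seed=0))
    assert res.p_value is None
    assert res.statistic > 0


def test_mann_whitney_exact_small_sample():
    # U = 0 for x below y; exact two-sided p = 2 * (1 / C(4,2)) = 1/3.
    res = mann_whitney_severity_test([0.1, 0.2], [0.8, 0.9])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(1 / 3)
    assert res.meta["method"] == "exact"


def test_mann_whitney_tied_groups_midranks():
    res = mann_whitney_severity_test([0.3, 0.7], [0.3, 0.7])
    assert res.statistic == pytest.approx(2.0)  # n1 * n2 / 2 under midranks
    assert res.p_value == pytest.approx(1.0, abs=0.05)


def test_mann_whitney_subsampling_cap():
    rng = np.random.default_rng(7)
    res = mann_whitney_severity_test(rng.random(3000), rng.random(50), max_n=1000, seed=1)
    assert res.n_pre == 1000 and res.n_post == 50
    assert res.meta["subsampled"]
    # reproducible under the same seed
    res2 = mann_whitney_severity_test(rng.random(3000), rng.random(50), max_n=1000, seed=1)
    assert res2.p_value is not None


def test_mann_whitney_empty_group_rejected():
    with pytest.raises(InferenceError):
        mann_whitney_severity_test([], [0.5])


@pytest.mark.parametrize("p,stars", [(0.04, "**"), (0.07, "*"), (0.2, ""), (None, "")])
def test_significance_convention(p, stars):
    assert significance_stars(p) == stars


def test_attach_cis_independent_of_record_order(fixture_assessment):
    recs = [r for r in fixture_assessment.records if r.n_patches > 0]
    spec = BootstrapSpec(n_iter=300, seed=11)
    fwd = attach_cis([__import__("copy").deepcopy(r) for r in recs], spec)
    rev = attach_cis([__import__("copy").deepcopy(r) for r in recs[::-1]], spec)
    fwd_by = {(r.level, r.code, r.status, r.period): r for r in fwd}
    for r in rev:
        other = fwd_by[(r.level, r.code, r.status, r.period)]
        assert r.disturbed_ci_low == other.disturbed_ci_low
        assert r.disturbed_ci_high == other.disturbed_ci_high


def test_ci_brackets_point_estimates(fixture_assessment):
    for r in fixture_assessment.records:
        if r.disturbed_ci_low is not None and r.n_patches >= 5:
            assert r.disturbed_ci_low <= r.disturbed_area_ha <= r.disturbed_ci_high
        if r.severity_ci_low is not None and r.severity_n_patches >= 5:
            assert r.severity_ci_low <= r.severity_mean <= r.severity_ci_high


def test_sensitivity_shift_zero_is_baseline(fixture_assessment, fixture_land):
    base = records_frame(aggregate(fixture_assessment.overlay, fixture_land.datasets,
                                   levels=("europe",)))
    for res in sensitivity_analysis(fixture_assessment.overlay, fixture_land.datasets,
                                    shifts=(0,), levels=("europe",)):
        got = records_frame(res.records)
        assert got.to_csv(index=False) == base.to_csv(index=False)


def test_sensitivity_large_negative_shift_empties_pre():
    # All disturbances strictly after year_min: a shift clamping the mapping
    # year to the window start leaves nothing predating.
    year = np.zeros((8, 8), dtype=int)
    year[2, 2:6] = 2005
    year[5, 1:4] = 2015
    layers = make_layers(year)
    from shapely.geometry import box

    poly = ForestPolygon("p", "D", box(0, 0, 240, 240), "AA", "Boreal", True)
    datasets = [PolygonDataset("D", "documented", 2010)]
    ov = overlay(layers, [poly], datasets)
    res = sensitivity_analysis(ov, datasets, shifts=(-50,), levels=("europe",))
    rec = {r.period: r for r in res[0].records}
    assert rec[PRE].disturbed_area_ha == 0.0
    assert rec[POST].disturbed_area_ha == pytest.approx(7 * 0.09)


def test_cell_unit_bootstrap_narrower_than_patch_unit(fixture_assessment):
    """Cell-level resampling ignores the spatial clustering of disturbance
    into patches, so its area CIs are narrower than patch-level ones."""
    import copy

    recs = [r for r in fixture_assessment.records if r.n_patches >= 10]
    assert recs
    rec = recs[0]
    patch = attach_cis([copy.deepcopy(rec)], BootstrapSpec(n_iter=1000, seed=3, unit="patch"))[0]
    cell = attach_cis([copy.deepcopy(rec)], BootstrapSpec(n_iter=1000, seed=3, unit="cell"),
                      cell_area_ha=0.09)[0]
    assert (cell.disturbed_ci_high - cell.disturbed_ci_low) < (
        patch.disturbed_ci_high - patch.disturbed_ci_low
    )
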