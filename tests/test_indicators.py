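import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from conftest import make_layers
from oracles import disturbed_area_double_loop
from pfdisturb.geodata import ForestPolygon, PolygonDataset
from pfdisturb.indicators import (
    FULL,
    POST,
    PRE,
    IndicatorError,
    aggregate,
    annual_rate,
    attribute_period,
    disturbed_area_by_period,
    overlay,
    periods_for,
    polygon_forest_area,
    proportion_disturbed,
    rate_change,
    records_frame,
    weighted_mean_mapping_year,
)
from pfdisturb.patching import MmuRule, apply_mmu, filtered_forest_mask, label_patches
from pfdisturb.geodata import rasterize_polygon


@pytest.mark.parametrize("dist,mapping,expected", [
    (2015, 2015, PRE),   # the mapping year itself predates
    (1990, 2015, PRE),
    (2016, 2015, POST),
])
def test_attribute_period(dist, mapping, expected):
    assert attribute_period(dist, mapping) == expected


def test_attribute_period_out_of_window():
    with pytest.raises(IndicatorError):
        attribute_period(1970, 2015)


def test_periods_partition_the_window():
    pers = periods_for(2015, 1986, 2020)
    assert (pers[PRE].start_year, pers[PRE].end_year) == (1986, 2015)
    assert (pers[POST].start_year, pers[POST].end_year) == (2016, 2020)
    assert pers[PRE].n_years + pers[POST].n_years == 35
    # Mapping in the final year: empty POST, not a zero division.
    assert periods_for(2020, 1986, 2020)[POST] is None
    assert periods_for(None, 1986, 2020)[FULL].n_years == 35


@pytest.mark.parametrize("disturbed,forest,expected", [
    (61_836, 2_401_000, 2.6),   # continental pre-mapping share
    (14_388, 2_401_000, 0.6),   # continental post-mapping share
    (0, 1000, 0.0),
])
def test_proportion_disturbed(disturbed, forest, expected):
    assert round(proportion_disturbed(disturbed, forest), 1) == expected


def test_proportion_with_zero_forest_is_undefined():
    assert proportion_disturbed(5.0, 0.0) is None


def test_annual_rate_arithmetic():
    assert annual_rate(1.0, 100.0, 10) == pytest.approx(0.1)
    assert annual_rate(0.0, 100.0, 10) == 0.0
    with pytest.raises(IndicatorError):
        annual_rate(1.0, 100.0, 0)


@pytest.mark.parametrize("pre,post,expected", [
    (0.08, 0.32, 0.24),   # Alpine-style increase
    (0.08, 0.15, 0.07),   # continental total
    (0.5, 0.5, 0.0),
])
def test_rate_change(pre, post, expected):
    assert rate_change(pre, post) == pytest.approx(expected)


def test_weighted_mean_mapping_year():
    assert weighted_mean_mapping_year([10.0], [2015]) == 2015
    assert weighted_mean_mapping_year([5.0, 5.0], [2010, 2020]) == 2015
    assert weighted_mean_mapping_year([1.0, 3.0], [2000, 2020]) == 2015
    with pytest.raises(IndicatorError):
        weighted_mean_mapping_year([], [])


def test_polygon_forest_area_brute_force():
    rng = np.random.default_rng(5)
    layers = make_layers(np.zeros((10, 10), dtype=int), forest=rng.random((10, 10)) < 0.5)
    rows, cols = np.meshgrid(np.arange(3, 9), np.arange(2, 7), indexing="ij")
    cells = (rows.ravel(), cols.ravel())
    expected = sum(layers.forest[r, c] for r, c in zip(*cells)) * 0.09
    assert polygon_forest_area(cells, layers.forest, layers.grid) == pytest.approx(expected)


def test_disturbed_area_by_period_direct_arithmetic():
    # 10 cells disturbed 2010, 5 cells 2018, mapping year 2015, 30-m grid.
    year = np.zeros((8, 8), dtype=int)
    year[0, :] = 2010
    year[1, :2] = 2010
    year[3, :5] = 2018
    layers = make_layers(year)
    patches = apply_mmu(label_patches(layers), MmuRule(2))
    rows, cols = np.meshgrid(np.arange(8), np.arange(8), indexing="ij")
    out = disturbed_area_by_period((rows.ravel(), cols.ravel()), patches, 2015, layers.grid)
    assert out == {PRE: pytest.approx(0.9), POST: pytest.approx(0.45)}
    assert disturbed_area_by_period((np.empty(0, int), np.empty(0, int)), patches, 2015,
                                    layers.grid) == {PRE: 0.0, POST: 0.0}


@pytest.mark.parametrize("seed", range(3))
def test_disturbed_area_matches_cell_level_oracle(seed):
    rng = np.random.default_rng(seed)
    year = rng.choice([0, 2000, 2010, 2018], size=(16, 16), p=[0.6, 0.15, 0.15, 0.1])
    forest = rng.random((16, 16)) < 0.7
    layers = make_layers(year, forest=forest)
    fmask = filtered_forest_mask(layers, MmuRule(2))
    patches = apply_mmu(label_patches(layers), MmuRule(2))
    kept = np.zeros((16, 16), dtype=bool)
    for p in patches:
        kept[p.rows, p.cols] = True
    rows, cols = np.meshgrid(np.arange(2, 14), np.arange(1, 10), indexing="ij")
    cells = (rows.ravel(), cols.ravel())
    sel = fmask[cells]
    masked_cells = (cells[0][sel], cells[1][sel])
    got = disturbed_area_by_period(masked_cells, patches, 2010, layers.grid)
    want = disturbed_area_double_loop(masked_cells, np.where(kept, year, 0),
                                     np.ones((16, 16), bool), 2010, 0.09)
    assert got[PRE] == pytest.approx(want["PRE"])
    assert got[POST] == pytest.approx(want["POST"])


# ---------------------------------------------------------------------------
# Overlay and aggregation
# ---------------------------------------------------------------------------

def _two_country_setup():
    """One dataset per country; disjoint rectangles on a 20x20 grid."""
    year = np.zeros((20, 20), dtype=int)
    year[2, 2:4] = 2010   # PRE patch in country A
    year[5, 2:5] = 2018   # POST patch in country A
    year[12, 12:16] = 2018  # POST patch in country B
    layers = make_layers(year)
    s = 30.0
    top = 20 * s
    polys = [
        ForestPolygon("a1", "DA", box(0, top - 10 * s, 10 * s, top), "AA", "Boreal", True),
        ForestPolygon("b1", "DB", box(10 * s, 0, 20 * s, top - 10 * s), "BB", "Alpine", False),
    ]
    datasets = [PolygonDataset("DA", "documented", 2015),
                PolygonDataset("DB", "documented", 2015)]
    return layers, polys, datasets


def test_aggregate_pools_areas_then_recomputes_ratios():
    layers, polys, datasets = _two_country_setup()
    ov = overlay(layers, polys, datasets)
    recs = aggregate(ov, datasets)
    by = {(r.level, r.code, r.period): r for r in recs}
    a_pre = by[("country", "AA", PRE)]
    assert a_pre.forest_area_ha == pytest.approx(100 * 0.09)
    assert a_pre.disturbed_area_ha == pytest.approx(2 * 0.09)
    eu_post = by[("europe", "EUROPE", POST)]
    assert eu_post.disturbed_area_ha == pytest.approx((3 + 4) * 0.09)
    # rate recomputed from pooled area and exposure, not averaged
    assert eu_post.rate_pct_per_year == pytest.approx(
        100 * 7 * 0.09 / (200 * 0.09 * 5)
    )
    # EU stratum contains only the in_eu country
    assert by[("eu", "EU", POST)].disturbed_area_ha == pytest.approx(3 * 0.09)


def test_single_country_europe_record_is_identity(fixture_land):
    # With all countries pooled, Europe equals the column sums of countries.
    from pfdisturb.indicators import overlay as _ov

    ov = _ov(fixture_land.layers, fixture_land.polygons, fixture_land.datasets)
    recs = aggregate(ov, fixture_land.datasets)
    df = records_frame(recs)
    for status in df["status"].unique():
        for period in df[df["status"] == status]["period"].unique():
            c = df[(df["level"] == "country") & (df["status"] == status) & (df["period"] == period)]
            e = df[(df["level"] == "europe") & (df["status"] == status) & (df["period"] == period)]
            assert c["disturbed_area_ha"].sum() == pytest.approx(float(e["disturbed_area_ha"].iloc[0]))
            assert c["forest_area_ha"].sum() == pytest.approx(float(e["forest_area_ha"].iloc[0]))


def test_rate_invariant_to_splitting_polygons():
    layers, polys, datasets = _two_country_setup()
    # Split country A's polygon into two halves referencing the same dataset.
    s = 30.0
    top = 20 * s
    split = [
        ForestPolygon("a1", "DA", box(0, top - 10 * s, 5 * s, top), "AA", "Boreal", True),
        ForestPolygon("a2", "DA", box(5 * s, top - 10 * s, 10 * s, top), "AA", "Boreal", True),
        polys[1],
    ]
    r1 = {(r.level, r.code, r.period): r for r in aggregate(overlay(layers, polys, datasets), datasets)}
    r2 = {(r.level, r.code, r.period): r for r in aggregate(overlay(layers, split, datasets), datasets)}
    for key, rec in r1.items():
        assert r2[key].rate_pct_per_year == pytest.approx(rec.rate_pct_per_year)
        assert r2[key].disturbed_area_ha == pytest.approx(rec.disturbed_area_ha)


def test_pre_post_conservation_per_polygon(fixture_assessment, fixture_land):
    """PRE + POST disturbed area equals the polygon's total disturbed area."""
    ov = fixture_assessment.overlay
    ds_my = {d.dataset_id: d.mapping_year for d in fixture_land.datasets}
    for pid, grp in ov.contrib_df.groupby("polygon_id"):
        my = ds_my[grp["dataset_id"].iloc[0]]
        total = grp["area_ha"].sum()
        if my is None:
            continue
        pre = grp[grp["year"] <= my]["area_ha"].sum()
        post = grp[grp["year"] > my]["area_ha"].sum()
        assert pre + post == pytest.approx(total)


def test_potential_polygons_clipped_by_documented():
    year = np.zeros((10, 10), dtype=int)
    layers = make_layers(year)
    s, top = 30.0, 300.0
    doc = ForestPolygon("d", "D1", box(0, 0, 6 * s, top), "AA", "Boreal", True)
    pot = ForestPolygon("p", "P1", box(0, 0, 10 * s, top), "AA", "Boreal", True)
    datasets = [PolygonDataset("D1", "documented", 2015), PolygonDataset("P1", "potential")]
    ov = overlay(layers, [doc, pot], datasets)
    pdf = ov.polygon_df.set_index("polygon_id")
    assert pdf.loc["d", "n_cells"] == 60
    assert pdf.loc["p", "n_cells"] == 40  # overlap went to the documented layer
    assert pdf.loc["d", "forest_area_ha"] + pdf.loc["p", "forest_area_ha"] == pytest.approx(100 * 0.09)


def test_unknown_dataset_reference_rejected():
    layers, polys, datasets = _two_country_setup()
    with pytest.raises(IndicatorError, match="unknown dataset"):
        overlay(layers, polys, datasets[:1])
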