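import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, box

from trackcloud import CellSet, GridSpec, TrackCloud
from trackcloud.ecoregions import (EcoregionMap, OUTSIDE, assign_cells,
                                   monthly_region_share, per_bird_region_count,
                                   region_metrics, synthetic_ecoregions)

GRID = GridSpec(45.0)


def _cloud(bird, cells, year=2008, sex="F", colony="colony_A", month=10):
    """One replicate, one day per requested cell (placed at cell centers)."""
    days = len(cells)
    dates = pd.date_range(f"{year}-{month:02d}-01", periods=days, freq="D")
    x = np.array([[ (i + 0.5) * 45.0 for i, _ in cells ]])
    y = np.array([[ (j + 0.5) * 45.0 for _, j in cells ]])
    return TrackCloud(bird_id=bird, year=year, colony=colony, sex=sex,
                      dates=dates, x=x, y=y)


def test_half_plane_assignment_by_cell_center():
    emap = EcoregionMap(regions={"left": box(0, 0, 450, 450),
                                 "right": box(450, 0, 900, 450)})
    out = assign_cells(GRID, emap)
    assert out.cell_assignment[(0, 0)] == "left"
    assert out.cell_assignment[(9, 0)] == "left"   # center x = 427.5 < 450
    assert out.cell_assignment[(10, 0)] == "right"  # center x = 472.5


def test_boundary_center_goes_to_lexicographically_first_region():
    # cell (0,0) center (22.5, 22.5) lies exactly on the shared edge x=22.5
    emap = EcoregionMap(regions={"b_region": box(22.5, 0, 90, 90),
                                 "a_region": box(0, 0, 22.5, 90)})
    out = assign_cells(GRID, emap, bounds=(0, 0, 90, 90))
    assert out.cell_assignment[(0, 0)] == "a_region"


def test_assignment_matches_point_in_polygon_oracle():
    emap = synthetic_ecoregions(extent=900.0)
    out = assign_cells(GRID, emap)
    items = sorted(out.cell_assignment.items())[::7]  # sample for speed
    for (i, j), label in items:
        center = Point((i + 0.5) * 45.0, (j + 0.5) * 45.0)
        covering = sorted(n for n, g in emap.regions.items() if g.covers(center))
        expected = covering[0] if covering else OUTSIDE
        assert label == expected


def test_invalid_geometry_names_region():
    from shapely.geometry import Polygon
    bowtie = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])
    emap = EcoregionMap(regions={"bad": bowtie})
    with pytest.raises(ValueError, match="bad"):
        assign_cells(GRID, emap)


def _ten_cell_map():
    # region R: 10 cells in a row, j = 0, i = 0..9; nothing else
    emap = EcoregionMap(regions={"R": box(0, 0, 450, 45)})
    return assign_cells(GRID, emap, bounds=(0, 0, 450, 45))


def test_region_metrics_hand_enumeration_oracle():
    emap = _ten_cell_map()
    bird1 = _cloud("b1", [(0, 0), (1, 0), (2, 0), (3, 0)])
    bird2 = _cloud("b2", [(3, 0), (4, 0)])  # one cell shared with bird1
    m = region_metrics([bird1, bird2], emap, GRID)
    r = m[(m.region == "R") & (m.year == 2008)].iloc[0]
    assert r.n_region_cells == 10
    assert r.n_occupied_cells == 5
    assert r.pct_region_occupied == pytest.approx(50.0)
    assert r.mean_occupied_density == pytest.approx(6 / 5)  # (1+1+1+2+1)/5
    assert r.pct_bird_distribution == pytest.approx(100.0)


def test_empty_region_reports_zero_density():
    emap = EcoregionMap(regions={"R": box(0, 0, 450, 45),
                                 "empty": box(0, 450, 450, 495)})
    emap = assign_cells(GRID, emap, bounds=(0, 0, 450, 495))
    m = region_metrics([_cloud("b1", [(0, 0)])], emap, GRID)
    r = m[m.region == "empty"].iloc[0]
    assert r.n_occupied_cells == 0
    assert r.pct_region_occupied == 0.0
    assert r.mean_occupied_density == 0.0


def test_bird_distribution_shares_sum_to_100(small_population):
    grid = GridSpec(45.0)
    emap = assign_cells(grid, small_population.ecoregions)
    m = region_metrics(small_population.clouds, emap, grid)
    for year, g in m.groupby("year"):
        assert g["pct_bird_distribution"].sum() == pytest.approx(100.0, abs=1e-9)
    # partition conservation: named regions + outside tile the domain
    assert m.groupby("year")["n_region_cells"].sum().nunique() == 1
    assert (m["n_region_cells"].groupby(m["year"]).sum()
            == len(emap.cell_assignment)).all()


def test_metrics_invariant_to_bird_order(small_population):
    grid = GridSpec(45.0)
    emap = assign_cells(grid, small_population.ecoregions)
    a = region_metrics(small_population.clouds, emap, grid)
    b = region_metrics(small_population.clouds[::-1], emap, grid)
    pd.testing.assert_frame_equal(a, b)


def test_per_bird_region_counts():
    emap = EcoregionMap(regions={"r1": box(0, 0, 45, 45),
                                 "r2": box(45, 0, 90, 45),
                                 "r3": box(90, 0, 135, 45)})
    emap = assign_cells(GRID, emap, bounds=(0, 0, 135, 45))
    one = _cloud("b1", [(0, 0)])
    three = _cloud("b2", [(0, 0), (1, 0), (2, 0)])
    per_bird, summ = per_bird_region_count([one, three], emap, GRID)
    counts = per_bird.set_index("bird_id")["n_regions"]
    assert counts["b1"] == 1
    assert counts["b2"] == 3
    assert set(summ["group"]) == {"sex", "colony"}


def test_monthly_share_forced_splits():
    emap = EcoregionMap(regions={"r1": box(0, 0, 45, 45),
                                 "r2": box(45, 0, 90, 45)})
    emap = assign_cells(GRID, emap, bounds=(0, 0, 90, 45))
    # 3 of 10 October days in r1, 7 in r2
    cells = [(0, 0)] * 3 + [(1, 0)] * 7
    share = monthly_region_share([_cloud("b1", cells)], emap, GRID)
    oct_share = share[share.month == 10].set_index("region")["pct_locations"]
    assert oct_share["r1"] == pytest.approx(30.0)
    assert oct_share["r2"] == pytest.approx(70.0)
    assert oct_share.sum() == pytest.approx(100.0)


def test_monthly_share_all_points_one_region():
    emap = EcoregionMap(regions={"r1": box(0, 0, 45, 45)}, )
    emap = assign_cells(GRID, emap, bounds=(0, 0, 45, 45))
    share = monthly_region_share([_cloud("b1", [(0, 0)] * 5)], emap, GRID)
    assert share[share.region == "r1"]["pct_locations"].iloc[0] == pytest.approx(100.0)
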