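import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point, box

from seedpath.assemblage import (
    FilterRules,
    MEGA_SEED_THRESHOLD_MM,
    build_grid,
    classify_mega_seeded,
    filter_assemblages,
    load_mega_seeded_table,
    rasterize_points,
    rasterize_ranges,
    split_by_mega,
    upper_percentile,
)
from seedpath.rasters import Raster


EXTENT = (0.0, 0.0, 60_000.0, 90_000.0)  # 60 x 90 km


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------
def test_grid_cell_counts_scale_with_resolution():
    assert build_grid(EXTENT, 30_000.0).n_cells == 6
    assert build_grid(EXTENT, 15_000.0).n_cells == 24


def test_all_water_mask_gives_zero_land():
    mask = Raster(np.zeros((30, 20)), 0.0, 0.0, 3000.0)
    grid = build_grid(EXTENT, 30_000.0, mask)
    assert np.all(grid.land_fraction == 0.0)


def test_degenerate_extent_rejected():
    with pytest.raises(ValueError):
        build_grid((0, 0, 0, 90_000.0), 30_000.0)


# ---------------------------------------------------------------------------
# presence from points
# ---------------------------------------------------------------------------
def test_point_in_cell_center_marks_single_cell():
    grid = build_grid(EXTENT, 30_000.0)
    occ = pd.DataFrame({"species": ["a"], "x": [15_000.0], "y": [75_000.0]})
    pm = rasterize_points(occ, grid, species=["a"])
    assert pm.matrix.sum() == 1
    assert pm.matrix[0, 0]  # top-left cell, row-major ids


def test_duplicates_and_zero_point_species():
    grid = build_grid(EXTENT, 30_000.0)
    occ = pd.DataFrame(
        {"species": ["a"] * 100, "x": [10_000.0] * 100, "y": [80_000.0] * 100}
    )
    pm = rasterize_points(occ, grid, species=["a", "ghost"])
    assert pm.matrix[:, 0].sum() == 1  # boolean, not a count
    assert not pm.matrix[:, 1].any()  # all-false row retained


@settings(max_examples=25, deadline=None)
@given(st.randoms(use_true_random=False))
def test_presence_invariant_to_row_order(rnd):
    grid = build_grid(EXTENT, 30_000.0)
    rng = np.random.default_rng(rnd.randint(0, 10**6))
    occ = pd.DataFrame(
        {
            "species": rng.choice(["a", "b", "c"], 30),
            "x": rng.uniform(0, 60_000.0, 30),
            "y": rng.uniform(0, 90_000.0, 30),
        }
    )
    pm1 = rasterize_points(occ, grid, species=["a", "b", "c"])
    pm2 = rasterize_points(
        occ.sample(frac=1.0, random_state=1), grid, species=["a", "b", "c"]
    )
    assert np.array_equal(pm1.matrix, pm2.matrix)


# ---------------------------------------------------------------------------
# presence from ranges
# ---------------------------------------------------------------------------
def test_range_overlap_rules():
    grid = build_grid(EXTENT, 30_000.0)
    ranges = {
        "everywhere": box(-1e4, -1e4, 70_000.0, 100_000.0),
        "corner": Point(0.0, 0.0).buffer(5_000.0),  # overlaps one corner cell
        "edge_toucher": box(-10_000.0, 0.0, 0.0, 90_000.0),  # zero-area contact
    }
    pm = rasterize_ranges(ranges, grid)
    idx = {s: k for k, s in enumerate(pm.species)}
    assert pm.matrix[:, idx["everywhere"]].all()
    assert pm.matrix[:, idx["corner"]].sum() == 1
    assert not pm.matrix[:, idx["edge_toucher"]].any()


def test_empty_geometry_raises_with_species_name():
    grid = build_grid(EXTENT, 30_000.0)
    with pytest.raises(ValueError, match="ghost"):
        rasterize_ranges({"ghost": Point(0, 0).buffer(0.0)}, grid)


# ---------------------------------------------------------------------------
# percentile metric
# ---------------------------------------------------------------------------
def test_upper_percentile_examples():
    assert upper_percentile(np.array([10.0, 20.0, 30.0]), 95) == pytest.approx(29.0)
    assert upper_percentile(np.array([12.0]), 95) == 12.0
    vals = np.array([3.0, 9.0, 1.0, 7.0])
    assert upper_percentile(vals, 100) == vals.max()
    with pytest.raises(ValueError):
        upper_percentile(np.array([]), 95)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.floats(0.1, 1e3), min_size=2, max_size=30),
    st.floats(1.0, 99.0),
    st.floats(1.0, 99.0),
)
def test_upper_percentile_monotone_and_bounded(values, lo, hi):
    values = np.asarray(values)
    lo, hi = min(lo, hi), max(lo, hi)
    p_lo = upper_percentile(values, lo)
    p_hi = upper_percentile(values, hi)
    assert p_lo <= p_hi
    assert values.min() <= p_lo and p_hi <= values.max()


# ---------------------------------------------------------------------------
# mega classification against the published list
# ---------------------------------------------------------------------------
def test_published_mega_seeded_species_all_flagged():
    table = load_mega_seeded_table()
    flags = classify_mega_seeded(table)
    assert len(table) == 15
    assert flags.all()
    assert table["seed_width_mm"].max() == 67.5
    assert table["seed_width_mm"].min() == 25.0


def test_threshold_is_strict():
    t = pd.DataFrame({"species": ["s"], "seed_width_mm": [MEGA_SEED_THRESHOLD_MM]})
    assert not classify_mega_seeded(t).any()


def test_missing_width_raises_and_empty_table_ok():
    t = pd.DataFrame({"species": ["s"], "seed_width_mm": [np.nan]})
    with pytest.raises(ValueError, match="s"):
        classify_mega_seeded(t)
    empty = pd.DataFrame({"species": [], "seed_width_mm": []})
    assert len(classify_mega_seeded(empty)) == 0


# ---------------------------------------------------------------------------
# filters and the mega split
# ---------------------------------------------------------------------------
@pytest.fixture()
def toy_table():
    return pd.DataFrame(
        {
            "cell_id": [0, 1, 2, 3, 4],
            "land_fraction": [1.0, 0.4, 1.0, 1.0, 0.9],
            "n_plants": [5, 5, 2, 5, 5],
            "n_extant": [4, 4, 4, 2, 4],
            "n_extinct": [1, 1, 1, 1, 0],
        }
    )


def test_filters_remove_failing_cells(toy_table):
    kept, log = filter_assemblages(toy_table, FilterRules())
    assert list(kept["cell_id"]) == [0]
    assert log == {"land": 1, "plants": 1, "extant": 1, "extinct": 1}


def test_compliant_table_passes_unchanged(toy_table):
    ok = toy_table.assign(
        land_fraction=1.0, n_plants=5, n_extant=4, n_extinct=1
    )
    kept, log = filter_assemblages(ok, FilterRules())
    assert len(kept) == len(ok)
    assert sum(log.values()) == 0


def test_split_by_mega_partitions_table():
    grid_cells = 5
    species = ("big", "small")
    matrix = np.zeros((grid_cells, 2), dtype=bool)
    matrix[[1, 3], 0] = True  # mega species in cells 1 and 3
    matrix[:, 1] = True
    from seedpath.assemblage import PresenceMatrix

    pm = PresenceMatrix(matrix, species)
    flags = pd.Series([True, False], index=species)
    table = pd.DataFrame({"cell_id": range(grid_cells), "v": range(grid_cells)})
    mega, nonmega = split_by_mega(table, pm, flags)
    assert sorted(mega["cell_id"]) == [1, 3]
    assert len(mega) + len(nonmega) == len(table)
    assert set(mega["cell_id"]).isdisjoint(nonmega["cell_id"])


def test_split_edge_cases():
    from seedpath.assemblage import PresenceMatrix

    pm = PresenceMatrix(np.ones((3, 1), dtype=bool), ("sp",))
    table = pd.DataFrame({"cell_id": [0, 1, 2]})
    mega, nonmega = split_by_mega(table, pm, pd.Series([False], index=["sp"]))
    assert mega.empty and len(nonmega) == 3
    mega, nonmega = split_by_mega(table, pm, pd.Series([True], index=["sp"]))
    assert nonmega.empty and len(mega) == 3
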