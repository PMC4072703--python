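"""Grid construction, zonal extraction, availability sampling, stretching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fawnsurv.grid import (
    build_grid,
    distance_to_roads,
    extract_buffer,
    filter_by_error,
    linear_stretch,
    sample_availability,
)
from fawnsurv.io import Raster

from conftest import make_landscape


# -- build_grid ---------------------------------------------------------


def test_cell_side_from_area(small_landscape):
    grid = build_grid(small_landscape, cell_area=2115.0)
    assert round(grid.cell_side, 2) == 45.99


def test_grid_dimensions_from_extent():
    # 460 m x 460 m extent with 46 m cells -> 10 x 10
    land = make_landscape(np.ones((23, 23)), cellsize=20.0)  # 460 m square
    grid = build_grid(land, cell_area=46.0**2)
    assert (grid.nrows, grid.ncols) == (10, 10)


def test_uniform_class_gives_proportion_one():
    land = make_landscape(np.full((20, 20), 3.0), n_classes=4)
    grid = build_grid(land, cell_area=2115.0)
    np.testing.assert_allclose(grid.class_props[2], 1.0)
    np.testing.assert_allclose(grid.class_props[[0, 1, 3]], 0.0)


def test_class_proportions_sum_to_one(small_landscape):
    grid = build_grid(small_landscape, cell_area=2115.0)
    np.testing.assert_allclose(grid.class_props.sum(axis=0), 1.0, atol=1e-9)


def test_grid_frame_row_count(small_landscape):
    grid = build_grid(small_landscape, cell_area=2115.0)
    assert len(grid.to_frame()) == grid.nrows * grid.ncols


# -- extract_buffer -----------------------------------------------------


def test_half_disc_straddling_boundary():
    data = np.ones((10, 10))
    data[:, 5:] = 2.0  # boundary at x = 150
    land = make_landscape(data, cellsize=30.0)
    buf = extract_buffer((150.0, 150.0), 26.0, land)
    assert buf.class_proportions[0] == pytest.approx(0.5, abs=0.02)
    assert buf.class_proportions[1] == pytest.approx(0.5, abs=0.02)


def test_disc_inside_one_class():
    land = make_landscape(np.ones((10, 10)), cellsize=30.0, n_classes=3)
    buf = extract_buffer((150.0, 150.0), 26.0, land)
    np.testing.assert_allclose(buf.class_proportions, [1.0, 0.0, 0.0])


def test_mean_risk_between_two_cells():
    risk = Raster(np.array([[0.2, 0.4]]), cellsize=100.0)
    land = make_landscape(np.ones((1, 2)), cellsize=100.0, risk={"coyote": risk})
    buf = extract_buffer((100.0, 50.0), 26.0, land)  # centered on the shared edge
    assert buf.mean_risk["coyote"] == pytest.approx(0.3, abs=0.01)


def test_buffer_outside_extent_raises(small_landscape):
    with pytest.raises(ValueError, match="outside"):
        extract_buffer((1e6, 1e6), 26.0, small_landscape)


def _brute_force_proportions(center, radius, raster, n_classes):
    """Independent 1 m rasterization oracle for disc class proportions."""
    x0, y0 = center
    xs = np.arange(x0 - radius, x0 + radius + 1.0, 1.0)
    ys = np.arange(y0 - radius, y0 + radius + 1.0, 1.0)
    xx, yy = np.meshgrid(xs + 0.5, ys + 0.5)
    inside = (xx - x0) ** 2 + (yy - y0) ** 2 <= radius**2
    col = np.floor((xx[inside] - raster.xll) / raster.cellsize).astype(int)
    row = np.floor((raster.yll + raster.nrows * raster.cellsize - yy[inside]) / raster.cellsize)
    row = row.astype(int)
    keep = (col >= 0) & (col < raster.ncols) & (row >= 0) & (row < raster.nrows)
    codes = raster.data[row[keep], col[keep]].astype(int)
    return np.bincount(codes - 1, minlength=n_classes)[:n_classes] / len(codes)


def test_zonal_matches_bruteforce_oracle(small_landscape):
    rng = np.random.default_rng(5)
    xmin, ymin, xmax, ymax = small_landscape.extent
    for _ in range(12):
        center = (rng.uniform(xmin + 30, xmax - 30), rng.uniform(ymin + 30, ymax - 30))
        buf = extract_buffer(center, 26.0, small_landscape)
        oracle = _brute_force_proportions(
            center, 26.0, small_landscape.landcover, small_landscape.n_classes
        )
        np.testing.assert_allclose(buf.class_proportions, oracle, atol=0.02)


def _point_segment_distance(px, py, ax, ay, bx, by):
    apx, apy = px - ax, py - ay
    abx, aby = bx - ax, by - ay
    denom = abx**2 + aby**2
    t = 0.0 if denom == 0 else max(0.0, min(1.0, (apx * abx + apy * aby) / denom))
    dx, dy = px - (ax + t * abx), py - (ay + t * aby)
    return np.hypot(dx, dy)


def test_distance_to_road_matches_exhaustive_oracle(small_landscape):
    rng = np.random.default_rng(9)
    pts = rng.uniform(100, 1400, size=(25, 2))
    got = distance_to_roads(pts[:, 0], pts[:, 1], small_landscape.roads)
    for (px, py), d in zip(pts, got):
        expected = min(
            _point_segment_distance(px, py, *a, *b)
            for line in small_landscape.roads
            for a, b in zip(line.coords[:-1], line.coords[1:])
        )
        assert d == pytest.approx(expected, abs=1e-8)


# -- sample_availability ------------------------------------------------


def test_availability_within_radius():
    rng = np.random.default_rng(0)
    used = rng.uniform(500, 2500, size=(200, 2))
    avail = sample_availability(used, radius=415.0, seed=1)
    dists = np.hypot(*(avail - used).T)
    assert np.all(dists <= 415.0)


def test_availability_uniform_on_disc():
    used = np.tile([[0.0, 0.0]], (10_000, 1))
    avail = sample_availability(used, radius=415.0, seed=2)
    u = (np.hypot(*avail.T) / 415.0) ** 2  # should be Uniform(0, 1)
    assert stats.kstest(u, "uniform").pvalue > 0.01


def test_availability_deterministic():
    used = np.random.default_rng(3).uniform(0, 1000, size=(50, 2))
    a = sample_availability(used, radius=415.0, extent=(0, 0, 1000, 1000), seed=7)
    b = sample_availability(used, radius=415.0, extent=(0, 0, 1000, 1000), seed=7)
    np.testing.assert_array_equal(a, b)


def test_availability_respects_extent():
    used = np.array([[5.0, 5.0]])
    avail = sample_availability(used, radius=415.0, extent=(0, 0, 1000, 1000), seed=0)
    assert 0 <= avail[0, 0] <= 1000 and 0 <= avail[0, 1] <= 1000


def test_availability_unsampleable_raises():
    used = np.array([[5000.0, 5000.0]])
    with pytest.raises(ValueError, match="cannot sample"):
        sample_availability(used, radius=10.0, extent=(0, 0, 100, 100), seed=0, max_tries=50)


# -- filter_by_error ----------------------------------------------------


def test_filter_keeps_boundary_value():
    df = pd.DataFrame({"ellipse_area": [1000.0, 2115.0, 3000.0]})
    kept = filter_by_error(df, threshold=2115.0)
    assert len(kept) == 2
    assert kept["ellipse_area"].tolist() == [1000.0, 2115.0]


def test_filter_noop_below_threshold():
    df = pd.DataFrame({"ellipse_area": [10.0, 20.0], "x": [1, 2]})
    kept = filter_by_error(df, threshold=100.0)
    pd.testing.assert_frame_equal(kept, df)


def test_filter_empty_table():
    df = pd.DataFrame({"ellipse_area": []})
    assert len(filter_by_error(df, threshold=1.0)) == 0


def test_filter_missing_column_raises():
    with pytest.raises(KeyError, match="ellipse_area"):
        filter_by_error(pd.DataFrame({"x": [1]}), threshold=1.0)


# -- linear_stretch -----------------------------------------------------


def test_stretch_affine():
    np.testing.assert_allclose(linear_stretch(np.array([2.0, 4.0, 6.0])), [0.0, 0.5, 1.0])


def test_stretch_degenerate_warns():
    with pytest.warns(UserWarning, match="degenerate"):
        out = linear_stretch(np.array([5.0, 5.0, 5.0]))
    np.testing.assert_array_equal(out, [0.0, 0.0, 0.0])


@settings(max_examples=50, deadline=None)
@given(
    st.lists(
        st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=2, max_size=50
    ).filter(lambda v: max(v) > min(v))
)
def test_stretch_preserves_rank_order(values):
    arr = np.asarray(values)
    out = linear_stretch(arr)
    assert out.min() == 0.0 and out.max() == 1.0
    # order preserved: stretched values are non-decreasing along the sorted input
    assert np.all(np.diff(out[np.argsort(arr, kind="stable")]) >= 0)
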