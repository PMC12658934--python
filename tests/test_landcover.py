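"""Boundary extraction, rasterization, aggregation, and radius metrics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from beecorridors.landcover import (
    LandCoverGrid,
    LineSet,
    BinaryFeatureGrid,
    aggregate_proportion,
    extract_boundaries,
    grassland_proportion,
    length_within_radius,
    nonforest_length,
    rasterize_lines,
)


def grid_from_mask(mask, cell_size=10.0):
    """0/1 mask -> land-cover grid with code 6 inside, 7 outside."""
    vals = np.where(np.asarray(mask, dtype=bool), 6, 7).astype(np.int64)
    return LandCoverGrid(vals, cell_size)


def face_scan_length(mask, cell_size=10.0):
    """Independent oracle: count interior faces where membership flips."""
    m = np.asarray(mask, dtype=bool)
    faces = (m[:, :-1] != m[:, 1:]).sum() + (m[:-1, :] != m[1:, :]).sum()
    return faces * cell_size


class TestExtractBoundaries:
    def test_single_cell_patch_has_full_perimeter(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        ls = extract_boundaries(grid_from_mask(mask), {6})
        assert ls.total_length == pytest.approx(40.0)
        assert len(ls) == 4

    def test_full_grid_has_no_edges_border_excluded(self):
        ls = extract_boundaries(grid_from_mask(np.ones((3, 3), bool)), {6})
        assert ls.total_length == 0.0

    def test_all_512_3x3_masks_match_face_scan(self):
        for bits in range(512):
            mask = np.array([(bits >> k) & 1 for k in range(9)], bool).reshape(3, 3)
            ls = extract_boundaries(grid_from_mask(mask), {6})
            assert ls.total_length == pytest.approx(face_scan_length(mask))

    def test_random_4x4_masks_match_face_scan(self, rng):
        for _ in range(50):
            mask = rng.random((4, 4)) < 0.5
            ls = extract_boundaries(grid_from_mask(mask), {6})
            assert ls.total_length == pytest.approx(face_scan_length(mask))

    def test_complement_parity(self, rng):
        mask = rng.random((5, 6)) < 0.4
        a = extract_boundaries(grid_from_mask(mask), {6}).total_length
        b = extract_boundaries(grid_from_mask(~mask), {6}).total_length
        assert a == pytest.approx(b)

    def test_shared_face_of_two_class_sets_counted_once(self):
        # forest–grassland boundary: one segment, not two
        vals = np.array([[2, 6], [2, 6]], dtype=np.int64)
        grid = LandCoverGrid(vals, 10.0)
        ls = extract_boundaries(grid, [{2, 3}, {6}])
        assert ls.total_length == pytest.approx(20.0)

    def test_nodata_faces_excluded(self):
        vals = np.array([[6, -1], [6, 7]], dtype=np.int64)
        grid = LandCoverGrid(vals, 10.0, nodata=-1)
        ls = extract_boundaries(grid, {6})
        assert ls.total_length == pytest.approx(10.0)  # only the 6|7 face

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="unknown class codes"):
            extract_boundaries(grid_from_mask(np.ones((2, 2), bool)), {99})

    def test_empty_class_sets_rejected(self):
        with pytest.raises(ValueError):
            extract_boundaries(grid_from_mask(np.ones((2, 2), bool)), [])


class TestNonforestLength:
    def test_subtraction_and_floor(self):
        a = LineSet([np.array([[0.0, 0.0], [100.0, 0.0]])])
        f = LineSet([np.array([[0.0, 0.0], [40.0, 0.0]])])
        assert nonforest_length(a, f) == pytest.approx(60.0)
        assert nonforest_length(f, a) == 0.0

    def test_forest_equals_all_gives_zero(self):
        a = LineSet([np.array([[0.0, 0.0], [25.0, 0.0]])])
        assert nonforest_length(a, a) == 0.0


class TestRasterizeLines:
    def test_segment_along_cell_edges_marks_both_rows(self):
        # 40 m horizontal line lying exactly on the boundary y=10
        ls = LineSet([np.array([[0.0, 10.0], [40.0, 10.0]])])
        out = rasterize_lines(ls, 10.0, origin=(0.0, 0.0), shape=(3, 4))
        assert out.values[1, :].sum() == 4  # row above the edge
        assert out.values[2, :].sum() == 4  # row below the edge
        assert out.values[0, :].sum() == 0

    def test_empty_lineset_gives_all_zeros(self):
        out = rasterize_lines(LineSet([]), 10.0, origin=(0.0, 0.0), shape=(2, 2))
        assert out.values.sum() == 0

    def test_diagonal_matches_shapely_intersection_oracle(self, rng):
        from shapely.geometry import LineString, box

        for _ in range(30):
            p = rng.uniform(0, 30, 2)
            q = rng.uniform(0, 30, 2)
            ls = LineSet([np.stack([p, q])])
            out = rasterize_lines(ls, 10.0, origin=(0.0, 0.0), shape=(3, 3))
            seg = LineString([p, q])
            expect = np.zeros((3, 3), dtype=np.uint8)
            for r in range(3):
                for c in range(3):
                    cell = box(c * 10.0, (2 - r) * 10.0, (c + 1) * 10.0, (3 - r) * 10.0)
                    expect[r, c] = seg.intersects(cell)
            assert np.array_equal(out.values, expect)

    def test_faces_fast_path_equals_generic(self, rng):
        mask = rng.random((6, 6)) < 0.5
        grid = grid_from_mask(mask)
        ls = extract_boundaries(grid, {6})
        fast = rasterize_lines(ls, 10.0)
        generic = rasterize_lines(
            LineSet([s for s in ls.segments]), 10.0, origin=(0.0, 0.0), shape=(6, 6)
        )
        assert np.array_equal(fast.values, generic.values)


class TestAggregateProportion:
    def test_all_ones_single_cell(self):
        fine = BinaryFeatureGrid(np.ones((10, 10)), 10.0)
        coarse = aggregate_proportion(fine, 10)
        assert coarse.values.shape == (1, 1)
        assert coarse.values[0, 0] == 1.0
        assert coarse.cell_size == 100.0

    def test_counting(self, rng):
        vals = np.zeros(100)
        vals[:37] = 1
        rng.shuffle(vals)
        fine = BinaryFeatureGrid(vals.reshape(10, 10), 10.0)
        assert aggregate_proportion(fine, 10).values[0, 0] == pytest.approx(0.37)

    def test_block_sum_oracle_and_conservation(self, rng):
        fine = BinaryFeatureGrid((rng.random((20, 20)) < 0.3).astype(int), 10.0)
        coarse = aggregate_proportion(fine, 10)
        expect = fine.values.reshape(2, 10, 2, 10).sum(axis=(1, 3)) / 100
        assert np.allclose(coarse.values, expect)
        assert coarse.values.sum() * 100 == fine.values.sum()

    def test_padding_preserves_count(self, rng):
        fine = BinaryFeatureGrid((rng.random((13, 17)) < 0.4).astype(int), 10.0)
        coarse = aggregate_proportion(fine, 5)
        total = coarse.values.sum() * 25
        assert total == pytest.approx(fine.values.sum())

    def test_bad_factor_rejected(self):
        with pytest.raises(ValueError):
            aggregate_proportion(BinaryFeatureGrid(np.ones((2, 2)), 10.0), 0)


class TestLengthWithinRadius:
    def test_fully_inside_counts_whole_length(self):
        ls = LineSet([np.array([[0.0, 0.0], [30.0, 40.0]])])
        assert length_within_radius(ls, (15.0, 20.0), 1000.0) == pytest.approx(50.0)

    def test_symmetric_clip(self):
        ls = LineSet([np.array([[-100.0, 0.0], [100.0, 0.0]])])
        assert length_within_radius(ls, (0.0, 0.0), 50.0) == pytest.approx(100.0)

    def test_sampling_oracle(self, rng):
        segs = [rng.uniform(-200, 200, (2, 2)) for _ in range(20)]
        ls = LineSet(segs)
        center, radius = (10.0, -20.0), 120.0
        got = length_within_radius(ls, center, radius)
        # oracle: 1 cm sampling of the in-disc fraction of each segment
        total = 0.0
        for seg in segs:
            d = np.hypot(*(seg[1] - seg[0]))
            n = max(int(d / 0.01), 2)
            t = (np.arange(n) + 0.5) / n
            pts = seg[0] + t[:, None] * (seg[1] - seg[0])
            frac = (((pts - center) ** 2).sum(1) <= radius**2).mean()
            total += frac * d
        assert got == pytest.approx(total, rel=1e-3)

    def test_zero_radius(self):
        ls = LineSet([np.array([[0.0, 0.0], [10.0, 0.0]])])
        assert length_within_radius(ls, (0.0, 0.0), 0.0) == 0.0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_monotone_in_radius(self, seed):
        r = np.random.default_rng(seed)
        ls = LineSet([r.uniform(-50, 50, (2, 2)) for _ in range(5)])
        center = (float(r.uniform(-20, 20)), float(r.uniform(-20, 20)))
        lengths = [length_within_radius(ls, center, rad) for rad in (10, 20, 40, 80)]
        assert all(a <= b + 1e-9 for a, b in zip(lengths, lengths[1:]))


class TestGrasslandProportion:
    def test_uniform_grassland(self):
        g = LandCoverGrid(np.full((5, 5), 6, dtype=np.int64), 10.0)
        assert grassland_proportion(g, (25.0, 25.0), 20.0) == 1.0

    def test_no_grassland(self):
        g = LandCoverGrid(np.full((5, 5), 7, dtype=np.int64), 10.0)
        assert grassland_proportion(g, (25.0, 25.0), 20.0) == 0.0

    def test_center_count_oracle(self, rng):
        vals = np.where(rng.random((8, 8)) < 0.3, 6, 7).astype(np.int64)
        g = LandCoverGrid(vals, 10.0)
        center, radius = (40.0, 35.0), 25.0
        got = grassland_proportion(g, center, radius)
        xs, ys = g.cell_centers()
        inside = (xs - center[0]) ** 2 + (ys - center[1]) ** 2 <= radius**2
        assert got == pytest.approx((vals[inside] == 6).mean())

    def test_empty_disc_is_error(self):
        g = LandCoverGrid(np.full((5, 5), 6, dtype=np.int64), 10.0)
        with pytest.raises(ValueError, match="no cell centers"):
            grassland_proportion(g, (-500.0, -500.0), 1.0)
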