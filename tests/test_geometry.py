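"""Contour validation, morphometry, and polygon differencing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliamet.geometry import (AREA_EPS, Contour, ContourSeries,
                              DegenerateContourError, DisjointContoursWarning,
                              InvalidGeometryError, SamplingError,
                              morphometry, polygon_difference, shoelace_area,
                              validate_contour)

from conftest import random_star_polygon, raster_area


class TestValidateContour:
    def test_clockwise_square_is_reoriented(self):
        c = validate_contour([(0, 0), (0, 2), (2, 2), (2, 0)])
        assert shoelace_area(c.vertices) > 0
        assert c.area == pytest.approx(4.0)

    def test_bowtie_is_rejected(self):
        with pytest.raises(InvalidGeometryError):
            validate_contour([(0, 0), (2, 2), (2, 0), (0, 2)])

    def test_repeated_vertex_is_deduplicated(self):
        c = validate_contour([(0, 0), (1, 0), (1, 0), (0, 1)])
        assert c.n_vertices == 3

    def test_closing_duplicate_is_dropped(self):
        c = validate_contour([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)])
        assert c.n_vertices == 4

    @pytest.mark.parametrize("verts", [
        [(0, 0), (1, 0)],                      # too few
        [(0, 0), (1, 0), (1, 0), (0, 0)],      # too few after dedup
        [(0, 0), (1, 1), (2, 2)],              # collinear, zero area
        [(0, 0), (1, 0), (np.nan, 1)],         # non-finite
    ])
    def test_degenerate_inputs(self, verts):
        with pytest.raises(DegenerateContourError):
            validate_contour(verts)


class TestMorphometry:
    def test_square_closed_form(self):
        c = validate_contour([(0, 0), (2, 0), (2, 2), (0, 2)])
        m = morphometry(c)
        assert m.area == pytest.approx(4.0)
        assert m.perimeter == pytest.approx(8.0)
        assert m.compactness_pa == pytest.approx(2.0)
        assert m.compactness_iq == pytest.approx(np.pi / 4.0)
        assert m.centroid == pytest.approx((1.0, 1.0))

    def test_scaling_laws(self):
        c = validate_contour([(0, 0), (2, 0), (2, 2), (0, 2)])
        m = morphometry(c)
        m3 = morphometry(c.scaled(3.0))
        assert m3.area == pytest.approx(9 * m.area)
        assert m3.perimeter == pytest.approx(3 * m.perimeter)
        assert m3.compactness_pa == pytest.approx(m.compactness_pa / 3.0)
        assert m3.compactness_iq == pytest.approx(m.compactness_iq)

    def test_matches_rasterization_oracle(self, rng):
        for _ in range(20):
            c = random_star_polygon(rng)
            oracle = raster_area(c.vertices)
            assert morphometry(c).area == pytest.approx(oracle, rel=0.01)

    def test_matches_shapely_area(self, rng):
        for _ in range(20):
            c = random_star_polygon(rng)
            assert c.area == pytest.approx(c.to_shapely().area, rel=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        dx=st.floats(-50, 50), dy=st.floats(-50, 50),
        angle=st.floats(0, 2 * np.pi), shift=st.integers(0, 11),
        seed=st.integers(0, 100),
    )
    def test_rigid_motion_and_cyclic_invariance(self, dx, dy, angle, shift, seed):
        """Area/perimeter/compactness are invariant under rigid motion and
        under cyclic rotation of the vertex list."""
        c = random_star_polygon(np.random.default_rng(seed))
        m = morphometry(c)
        moved = morphometry(c.rotated(angle).translated(dx, dy))
        assert moved.area == pytest.approx(m.area, rel=1e-9)
        assert moved.perimeter == pytest.approx(m.perimeter, rel=1e-9)
        cyc = morphometry(Contour(np.roll(c.vertices, shift, axis=0)))
        assert cyc.area == pytest.approx(m.area, rel=1e-12)
        assert cyc.perimeter == pytest.approx(m.perimeter, rel=1e-12)
        assert cyc.centroid == pytest.approx(m.centroid, rel=1e-9, abs=1e-9)


class TestPolygonDifference:
    def test_identical_contours_give_empty_list(self, unit_square):
        assert polygon_difference(unit_square, unit_square) == []

    def test_shifted_square_closed_form(self, unit_square):
        shifted = unit_square.translated(0.2, 0.0)
        comps = polygon_difference(unit_square, shifted)
        ext = [c for c in comps if c.sign == "extension"]
        ret = [c for c in comps if c.sign == "retraction"]
        assert len(ext) == 1 and len(ret) == 1
        assert ext[0].area == pytest.approx(0.2)
        assert ret[0].area == pytest.approx(0.2)

    def test_disjoint_contours_warn_and_decompose_whole(self, unit_square):
        far = unit_square.translated(10.0, 0.0)
        with pytest.warns(DisjointContoursWarning):
            comps = polygon_difference(unit_square, far)
        assert sorted(c.sign for c in comps) == ["extension", "retraction"]
        assert all(c.area == pytest.approx(1.0) for c in comps)

    def test_conservation_on_random_pairs(self, rng):
        """area(b) - area(a) == sum(ext) - sum(ret) to 1e-9 relative."""
        for _ in range(100):
            a = random_star_polygon(rng)
            b = random_star_polygon(rng, center=tuple(rng.uniform(-1, 1, 2)))
            comps = polygon_difference(a, b)
            net = sum(c.area for c in comps if c.sign == "extension") \
                - sum(c.area for c in comps if c.sign == "retraction")
            tol = 1e-9 * max(a.area, b.area)
            assert abs((b.area - a.area) - net) < tol

    def test_components_match_rasterization_oracle(self, rng):
        from conftest import raster_masks
        for _ in range(5):
            a = random_star_polygon(rng)
            b = random_star_polygon(rng, center=(0.5, 0.2))
            in_a, in_b, cell = raster_masks(a.vertices, b.vertices)
            comps = polygon_difference(a, b)
            ext = sum(c.area for c in comps if c.sign == "extension")
            ret = sum(c.area for c in comps if c.sign == "retraction")
            assert ext == pytest.approx(float((in_b & ~in_a).sum()) * cell, rel=0.01)
            assert ret == pytest.approx(float((in_a & ~in_b).sum()) * cell, rel=0.01)

    def test_touching_squares_produce_no_sliver(self, unit_square):
        neighbor = unit_square.translated(1.0, 0.0)  # shares an edge
        comps = polygon_difference(unit_square, neighbor)
        assert all(c.area > AREA_EPS for c in comps)

    def test_centroid_alignment_flag(self, unit_square):
        shifted = unit_square.translated(5.0, -3.0)
        comps = polygon_difference(unit_square, shifted, align_centroids=True)
        assert comps == []


class TestContourSeries:
    def _series(self, times):
        return ContourSeries([
            validate_contour([(0, 0), (1, 0), (1, 1)], cell_id="c", t=t)
            for t in times
        ])

    def test_uniform_sampling_accepted(self):
        s = self._series([0, 1, 2, 3])
        assert s.dt == 1.0 and s.n_frames == 4

    def test_gap_rejected_without_flag(self):
        with pytest.raises(SamplingError):
            self._series([0, 1, 3])

    def test_gap_allowed_with_flag(self):
        contours = [validate_contour([(0, 0), (1, 0), (1, 1)], cell_id="c", t=t)
                    for t in [0, 1, 3]]
        s = ContourSeries(contours, allow_gaps=True)
        assert s.n_frames == 3

    def test_non_increasing_times_rejected(self):
        with pytest.raises(SamplingError):
            self._series([0, 2, 1])
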