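"""Geometry of subchondral ROI propagation, rasterization and pixel pooling."""

import numpy as np
import pytest
import shapely

from beach_sij.maps import QuantitativeMap
from beach_sij.roi import (
    DelineationError,
    JointDelineation,
    OffsetError,
    pool_pixels,
    propagate_rois,
    rasterize_polygon,
    select_slices,
)

from conftest import point_in_polygon_oracle, random_delineation, straight_delineation


class TestPropagateRois:
    def test_straight_joint_gives_two_rectangles(self):
        delin = straight_delineation(length=40.0)
        rois = propagate_rois(delin, depth_mm=10.0)
        assert set(rois.polygons) == {"sacral", "iliac"}
        for poly in rois.polygons.values():
            assert poly.area == pytest.approx(400.0, abs=1e-9)
            minx, miny, maxx, maxy = poly.bounds
            assert maxx - minx == pytest.approx(10.0, abs=1e-9)
            assert maxy - miny == pytest.approx(40.0, abs=1e-9)

    def test_left_joint_side_labels(self):
        delin = straight_delineation(joint_side="left")
        rois = propagate_rois(delin, 10.0)
        # lateral (iliac) side of a left joint is toward smaller x
        assert rois.polygons["iliac"].centroid.x < rois.polygons["sacral"].centroid.x

    def test_depth_zero_degenerates(self):
        rois = propagate_rois(straight_delineation(), depth_mm=0.0)
        assert all(p.area == 0 for p in rois.polygons.values())

    def test_bend_area_matches_closed_form_and_grid_oracle(self):
        # one 45-degree bend, perpendicular anchors: the mitered offset adds
        # (convex side) or removes (concave side) a wedge of depth^2 tan(phi/2)
        depth = 10.0
        l1, l2 = 30.0, 25.0
        phi = np.pi / 4
        p0 = np.array([50.0, 20.0])
        p1 = p0 + [0.0, l1]
        p2 = p1 + l2 * np.array([np.sin(phi), np.cos(phi)])
        poly = np.array([p0, p1, p2])

        def perp_anchor(p, t):
            n = np.array([-t[1], t[0]])
            return np.array([p - 4 * n, p + 4 * n])

        t0 = (p1 - p0) / np.linalg.norm(p1 - p0)
        t1 = (p2 - p1) / np.linalg.norm(p2 - p1)
        delin = JointDelineation(0, "left", poly, perp_anchor(p0, t0), perp_anchor(p2, t1))
        rois = propagate_rois(delin, depth)
        wedge = depth**2 * np.tan(phi / 2)
        base = (l1 + l2) * depth
        areas = sorted(p.area for p in rois.polygons.values())
        assert areas[0] == pytest.approx(base - wedge, rel=1e-9)
        assert areas[1] == pytest.approx(base + wedge, rel=1e-9)
        # brute-force fine-grid classification agrees to <0.5%
        for poly_geom in rois.polygons.values():
            ring = np.asarray(poly_geom.exterior.coords)
            minx, miny, maxx, maxy = poly_geom.bounds
            step = 0.05
            gx, gy = np.meshgrid(
                np.arange(minx - step, maxx + step, step),
                np.arange(miny - step, maxy + step, step),
            )
            inside = point_in_polygon_oracle(gx, gy, ring)
            grid_area = inside.sum() * step**2
            assert grid_area == pytest.approx(poly_geom.area, rel=5e-3)

    def test_sharp_curvature_raises_named_vertex(self):
        # hairpin: curvature radius far below the 10 mm depth on one side
        poly = np.array([[50.0, 20.0], [52.0, 40.0], [46.0, 41.0], [40.0, 25.0]])
        a0 = np.array([[46.0, 20.0], [54.0, 20.0]])
        a1 = np.array([[40.0, 21.0], [40.0, 29.0]])
        delin = JointDelineation(0, "left", poly, a0, a1)
        with pytest.raises(OffsetError, match="vertex"):
            propagate_rois(delin, 10.0)

    def test_sides_share_boundary_without_overlap(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            rois = propagate_rois(random_delineation(rng), 10.0)
            inter = rois.polygons["sacral"].intersection(rois.polygons["iliac"])
            assert inter.area < 1e-6

    def test_invalid_delineations_rejected(self):
        with pytest.raises(DelineationError):
            JointDelineation(
                0, "left",
                np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]]),
                np.array([[-1.0, 0.0], [1.0, 0.0]]),
                np.array([[0.0, 1.0], [2.0, 1.0]]),
            )
        with pytest.raises(DelineationError, match="anchor"):
            JointDelineation(
                0, "left",
                np.array([[0.0, 0.0], [0.0, 10.0]]),
                np.array([[5.0, 5.0], [6.0, 5.0]]),  # detached
                np.array([[-1.0, 10.0], [1.0, 10.0]]),
            )


class TestRasterize:
    def test_square_pixel_count(self):
        # 10x10 mm axis-aligned square at 1 mm spacing; pixel centres on the
        # integer lattice, boundary centres included
        square = shapely.box(5.0, 5.0, 15.0, 15.0)
        mask = rasterize_polygon(square, (30, 30), (1.0, 1.0))
        assert mask.sum() == 11 * 11  # centres 5..15 inclusive both axes

    def test_half_integer_centres_count(self):
        square = shapely.box(4.5, 4.5, 14.5, 14.5)
        mask = rasterize_polygon(square, (30, 30), (1.0, 1.0))
        assert mask.sum() == 100

    def test_random_polygons_match_exhaustive_oracle(self):
        rng = np.random.default_rng(11)
        grid = (100, 100)
        spacing = (1.4, 1.4)
        for _ in range(25):
            rois = propagate_rois(random_delineation(rng), rng.uniform(5, 12))
            for poly in rois.polygons.values():
                mask = rasterize_polygon(poly, grid, spacing)
                cc, rr = np.meshgrid(np.arange(grid[1]), np.arange(grid[0]))
                oracle = point_in_polygon_oracle(
                    cc.ravel() * spacing[1],
                    rr.ravel() * spacing[0],
                    np.asarray(poly.exterior.coords),
                ).reshape(grid)
                assert np.array_equal(mask, oracle)

    def test_empty_polygon(self):
        from shapely.geometry import Polygon

        assert rasterize_polygon(Polygon(), (10, 10), (1.0, 1.0)).sum() == 0

    def test_outside_grid_warns_empty(self):
        square = shapely.box(500.0, 500.0, 510.0, 510.0)
        with pytest.warns(UserWarning):
            mask = rasterize_polygon(square, (20, 20), (1.0, 1.0))
        assert mask.sum() == 0


class TestSelectSlices:
    def test_adc_uses_all_synovial_slices(self):
        assert select_slices("ADC", range(3, 13)) == list(range(3, 13))

    def test_pdff_uses_alternate_slices_from_first(self):
        assert select_slices("PDFF", range(3, 13)) == [3, 5, 7, 9, 11]

    def test_single_slice(self):
        assert select_slices("ADC", [4]) == [4]
        assert select_slices("PDFF", [4]) == [4]

    def test_empty_range_errors(self):
        with pytest.raises(ValueError):
            select_slices("ADC", [])


def _constant_map(value, n_slices=3, shape=(60, 60)):
    return QuantitativeMap(
        np.full((n_slices, *shape), float(value)), "ADC", (1.0, 1.0), 3.0
    )


class TestPoolPixels:
    def test_constant_map_pools_constant(self):
        delin = straight_delineation()
        rois = {s: [propagate_rois(delin, 10.0)] for s in range(3)}
        sample = pool_pixels(_constant_map(7.0), rois, [0, 1, 2])
        assert np.all(sample.values == 7.0)
        one_slice = pool_pixels(_constant_map(7.0), rois, [0])
        assert sample.n_pixels == 3 * one_slice.n_pixels

    def test_disjoint_rois_counts_add(self):
        d1 = straight_delineation(x=15.0)
        d2 = straight_delineation(x=45.0, joint_side="right")
        rois = {0: [propagate_rois(d1, 10.0), propagate_rois(d2, 10.0)]}
        sample = pool_pixels(_constant_map(1.0, n_slices=1), rois, [0])
        s1 = pool_pixels(_constant_map(1.0, n_slices=1), {0: [propagate_rois(d1, 10.0)]}, [0])
        s2 = pool_pixels(_constant_map(1.0, n_slices=1), {0: [propagate_rois(d2, 10.0)]}, [0])
        assert sample.n_pixels == s1.n_pixels + s2.n_pixels

    def test_pooled_multiset_matches_oracle_masks(self):
        rng = np.random.default_rng(3)
        delin = random_delineation(rng)
        qmap = QuantitativeMap(
            rng.normal(200, 50, (2, 100, 100)).clip(0), "ADC", (1.4, 1.4), 3.0
        )
        rois = {s: [propagate_rois(delin, 10.0)] for s in (0, 1)}
        sample = pool_pixels(qmap, rois, [0, 1])
        expected = []
        for s in (0, 1):
            for poly in rois[s][0].polygons.values():
                cc, rr = np.meshgrid(np.arange(100), np.arange(100))
                inside = point_in_polygon_oracle(
                    cc.ravel() * 1.4, rr.ravel() * 1.4,
                    np.asarray(poly.exterior.coords),
                ).reshape(100, 100)
                expected.append(qmap.values[s][inside])
        expected = np.concatenate(expected)
        assert np.array_equal(np.sort(sample.values), np.sort(expected))

    def test_missing_slice_errors_with_slice_listed(self):
        delin = straight_delineation()
        rois = {0: [propagate_rois(delin, 10.0)]}
        with pytest.raises(ValueError, match=r"\[1\]"):
            pool_pixels(_constant_map(1.0), rois, [0, 1])


class TestInvariants:
    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        delin = random_delineation(rng)
        shift = np.array([7.3, -4.1])
        shifted = JointDelineation(
            delin.slice_index, delin.joint_side,
            delin.polyline + shift,
            delin.anchor_start + shift,
            delin.anchor_end + shift,
        )
        big = (200, 200)
        n0 = sum(
            rasterize_polygon(p, big, (1.0, 1.0)).sum()
            for p in propagate_rois(delin, 10.0).polygons.values()
        )
        # shift the grid origin with the delineation: pixel counts persist
        from shapely import affinity

        n1 = sum(
            rasterize_polygon(
                affinity.translate(p, -shift[0], -shift[1]), big, (1.0, 1.0)
            ).sum()
            for p in propagate_rois(shifted, 10.0).polygons.values()
        )
        assert n0 == n1

    def test_pixel_count_monotone_in_depth(self):
        rng = np.random.default_rng(9)
        delin = random_delineation(rng)
        counts = []
        for depth in (2.0, 5.0, 8.0, 11.0):
            counts.append(
                sum(
                    rasterize_polygon(p, (120, 120), (1.2, 1.2)).sum()
                    for p in propagate_rois(delin, depth).polygons.values()
                )
            )
        assert counts == sorted(counts)

    def test_non_synovial_slices_contribute_nothing(self, patient):
        """ROIs exist only for synovial slices; others raise when requested."""
        truth = patient.truth
        from beach_sij.synthetic import simulate_reader_delineation

        delins = simulate_reader_delineation(truth, 0.0, 1)
        covered = {s for s, _ in delins}
        assert covered == set(truth.synovial_slices)
        qmap = patient.maps[("ADC", "pre")]
        ligamentous = set(range(qmap.n_slices)) - covered
        rois = {}
        for (s, _j), d in delins.items():
            rois.setdefault(s, []).append(propagate_rois(d, 10.0))
        with pytest.raises(ValueError):
            pool_pixels(qmap, rois, sorted(covered | set(list(ligamentous)[:1])))
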