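"""Convex polygons in brain-body log space: hulls, classification, extension."""

import itertools

import numpy as np
import pytest
from shapely.geometry import Point, Polygon as ShapelyPolygon

from paleoneuro import hullspace, synthetic_data
from paleoneuro.errors import DegenerateGeometryError, DomainError
from paleoneuro.hullspace import PointClass


def random_points(n, seed):
    rng = np.random.default_rng(seed)
    return [
        (float(10 ** rng.uniform(1, 6)), float(10 ** rng.uniform(-1, 3)))
        for _ in range(n)
    ]


def brute_force_hull_vertices(logged):
    """All-triples oracle: a point is interior iff it lies strictly inside
    some triangle of input points; the rest are hull vertices. Vectorized
    over the C(n, 3) triangles, one pass per query point."""
    pts = np.asarray(logged)
    n = len(pts)
    triples = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), 3)),
        dtype=np.int64,
    ).reshape(-1, 3)
    a, b, c = pts[triples[:, 0]], pts[triples[:, 1]], pts[triples[:, 2]]
    ab, ac = b - a, c - a
    area2 = ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0]
    ok = np.abs(area2) > 1e-12
    a, ab, ac, area2 = a[ok], ab[ok], ac[ok], area2[ok]
    interior = np.zeros(n, dtype=bool)
    chunk = 50_000  # interior points are usually caught by the first chunk
    for m in range(n):
        for lo in range(0, len(a), chunk):
            sl = slice(lo, lo + chunk)
            d = pts[m] - a[sl]
            u = (d[:, 0] * ac[sl, 1] - d[:, 1] * ac[sl, 0]) / area2[sl]
            v = (d[:, 1] * ab[sl, 0] - d[:, 0] * ab[sl, 1]) / area2[sl]
            if np.any((u > 1e-12) & (v > 1e-12) & (u + v < 1 - 1e-12)):
                interior[m] = True
                break
    return {tuple(p) for p, inner in zip(map(tuple, pts), interior) if not inner}


class TestMinimumConvexPolygon:
    def test_triangle_is_its_own_hull(self):
        pts = [(10.0, 1.0), (1000.0, 1.0), (100.0, 100.0)]
        poly = hullspace.minimum_convex_polygon(pts)
        assert sorted(poly.vertices) == sorted(
            (np.log10(p), np.log10(e)) for p, e in pts)

    def test_hull_of_hull_is_identity(self):
        pts = random_points(60, seed=1)
        poly = hullspace.minimum_convex_polygon(pts)
        again = hullspace.polygon_from_log_vertices(poly.vertices)
        assert again.vertices == poly.vertices

    def test_matches_all_triples_brute_force_oracle(self):
        """On a 200-point seeded cloud the hull's vertex set equals the
        brute-force interior/vertex partition, every vertex is an input
        point, and no input point falls strictly outside."""
        pts = random_points(200, seed=7)
        logged = [(np.log10(p), np.log10(e)) for p, e in pts]
        poly = hullspace.minimum_convex_polygon(pts)
        assert set(poly.vertices) == brute_force_hull_vertices(logged)
        assert set(poly.vertices) <= set(logged)
        shp = ShapelyPolygon(poly.vertices)
        assert all(shp.intersects(Point(q)) for q in logged)  # inside or on

    def test_every_generating_point_classifies_inside_or_on(self):
        pts = random_points(120, seed=3)
        poly = hullspace.minimum_convex_polygon(pts)
        for q in pts:
            assert hullspace.classify_point(q, poly) in (
                PointClass.INSIDE, PointClass.ON_BOUNDARY)

    def test_area_invariant_under_permutation_and_duplication(self):
        pts = random_points(40, seed=11)
        a = hullspace.minimum_convex_polygon(pts).area()
        rng = np.random.default_rng(0)
        shuffled = [pts[i] for i in rng.permutation(len(pts))] + pts[:10]
        assert hullspace.minimum_convex_polygon(shuffled).area() == pytest.approx(a)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            hullspace.minimum_convex_polygon([(10.0, 1.0), (100.0, 2.0)])
        collinear = [(10.0 ** x, 10.0 ** x) for x in (1.0, 2.0, 3.0, 4.0)]
        with pytest.raises(DegenerateGeometryError):
            hullspace.minimum_convex_polygon(collinear)
        with pytest.raises(DomainError):
            hullspace.minimum_convex_polygon([(10.0, 1.0), (-5.0, 2.0), (7.0, 3.0)])


class TestClassifyPoint:
    @pytest.fixture()
    def poly(self):
        return hullspace.polygon_from_log_vertices(
            [(0.0, 0.0), (2.0, 0.0), (2.0, 1.0), (0.0, 1.0)], label="box")

    def test_centroid_is_inside(self, poly):
        assert hullspace.classify_point((10.0, 10 ** 0.5), poly) is PointClass.INSIDE

    def test_vertex_is_on_boundary(self, poly):
        assert hullspace.classify_point((1.0, 1.0), poly) is PointClass.ON_BOUNDARY

    def test_above_below_and_out_of_range(self, poly):
        assert hullspace.classify_point((10.0, 100.0), poly) is PointClass.ABOVE
        assert hullspace.classify_point((10.0, 0.1), poly) is PointClass.BELOW
        assert hullspace.classify_point((10_000.0, 1.0), poly) is PointClass.OUTSIDE_RANGE

    def test_agreement_with_shapely_on_containment(self):
        pts = random_points(80, seed=23)
        poly = hullspace.minimum_convex_polygon(pts)
        shp = ShapelyPolygon(poly.vertices)
        rng = np.random.default_rng(1)
        for _ in range(300):
            x, y = rng.uniform(*poly.x_range), rng.uniform(-2, 4)
            verdict = hullspace.classify_point((10 ** x, 10 ** y), poly)
            if shp.buffer(-1e-9).contains(Point(x, y)):
                assert verdict is PointClass.INSIDE
            elif not shp.buffer(1e-9).intersects(Point(x, y)):
                assert verdict in (PointClass.ABOVE, PointClass.BELOW)


class TestArctocyonVersusReptiles:
    """The earliest Paleocene mammal in the table (7.14 ml brain, 16.1 kg
    body) must classify above a reptile-grade polygon whose upper-right
    boundary is anchored at the printed crocodilian maxima."""

    def test_above_reptile_polygon(self):
        pts = synthetic_data.reptile_brain_body_points(seed=0)
        poly = hullspace.minimum_convex_polygon(pts, label="reptiles")
        assert hullspace.classify_point((16_144.0, 7.14), poly) is PointClass.ABOVE

    def test_still_above_after_extension_to_dinosaur_body_sizes(self):
        pts = synthetic_data.reptile_brain_body_points(seed=0)
        poly = hullspace.minimum_convex_polygon(pts, label="reptiles")
        extended = hullspace.extend_polygon(poly, 7.0)
        assert hullspace.classify_point((16_144.0, 7.14), extended) is PointClass.ABOVE


class TestExtendPolygon:
    def test_zero_length_extension_is_identity(self):
        pts = random_points(30, seed=2)
        poly = hullspace.minimum_convex_polygon(pts)
        same = hullspace.extend_polygon(poly, poly.x_range[1])
        assert same.vertices == poly.vertices

    def test_unit_square_with_flat_slope_becomes_double_rectangle(self):
        square = hullspace.polygon_from_log_vertices(
            [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)])
        rect = hullspace.extend_polygon(square, 2.0, slope=0.0)
        assert sorted(rect.vertices) == [
            (0.0, 0.0), (0.0, 1.0), (2.0, 0.0), (2.0, 1.0)]

    @pytest.mark.parametrize("seed", range(50))
    def test_extension_contains_original(self, seed):
        pts = random_points(25, seed=100 + seed)
        poly = hullspace.minimum_convex_polygon(pts)
        extended = hullspace.extend_polygon(poly, poly.x_range[1] + 1.5)
        for v in poly.vertices:
            assert hullspace.classify_point((10 ** v[0], 10 ** v[1]), extended) in (
                PointClass.INSIDE, PointClass.ON_BOUNDARY)
        assert extended.area() >= poly.area() - 1e-12

    def test_extension_not_beyond_current_extent_rejected(self):
        pts = random_points(10, seed=5)
        poly = hullspace.minimum_convex_polygon(pts)
        with pytest.raises(DomainError):
            hullspace.extend_polygon(poly, poly.x_range[1] - 0.5)
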