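"""Spatial queries against brute-force containment oracles."""

import numpy as np
import pytest
import shapely

from spatialkit import (
    BoxRegion,
    PolygonRegion,
    Scale,
    SpatialDataset,
    bounding_box_query,
    build_element,
    polygon_query,
    validate_dataset,
)
from spatialkit.query import QueryError
from spatialkit.transforms import Translation, compose


# ---------------------------------------------------------------------------
# independent oracles (no shapely, except to read coordinates out)


def point_in_box(p, bounds):
    return all(bounds[a][0] <= v < bounds[a][1] for a, v in zip(("x", "y"), p))


def ray_cast(p, ring):
    """Even-odd point-in-polygon with boundary points counted inside."""
    x, y = p
    inside = False
    n = len(ring)
    for i in range(n):
        (x1, y1), (x2, y2) = ring[i], ring[(i + 1) % n]
        # on-edge check (closed convention)
        dx, dy = x2 - x1, y2 - y1
        cross = (x - x1) * dy - (y - y1) * dx
        if abs(cross) < 1e-12 and min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12 \
                and min(y1, y2) - 1e-12 <= y <= max(y1, y2) + 1e-12:
            return True
        if (y1 > y) != (y2 > y):
            xs = x1 + (y - y1) * dx / dy
            if x < xs:
                inside = not inside
    return inside


def circle_touches_box(center, radius, bounds):
    cx = min(max(center[0], bounds["x"][0]), bounds["x"][1])
    cy = min(max(center[1], bounds["y"][0]), bounds["y"][1])
    return (center[0] - cx) ** 2 + (center[1] - cy) ** 2 <= radius**2


def segments_intersect(a, b, c, d):
    def orient(p, q, r):
        return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])

    o1, o2 = orient(a, b, c), orient(a, b, d)
    o3, o4 = orient(c, d, a), orient(c, d, b)
    if ((o1 > 0) != (o2 > 0)) and ((o3 > 0) != (o4 > 0)):
        return True
    return False


def polygon_touches_box(ring, bounds):
    corners = [
        (bounds["x"][0], bounds["y"][0]), (bounds["x"][1], bounds["y"][0]),
        (bounds["x"][1], bounds["y"][1]), (bounds["x"][0], bounds["y"][1]),
    ]
    if any(
        bounds["x"][0] <= vx <= bounds["x"][1] and bounds["y"][0] <= vy <= bounds["y"][1]
        for vx, vy in ring
    ):
        return True
    if any(ray_cast(c, ring) for c in corners):
        return True
    n = len(ring)
    for i in range(n):
        for j in range(4):
            if segments_intersect(
                ring[i], ring[(i + 1) % n], corners[j], corners[(j + 1) % 4]
            ):
                return True
    return False


# ---------------------------------------------------------------------------


class TestPointBoxQuery:
    def test_simple_filter(self):
        pts = build_element("points", {"x": [0.0, 5.0], "y": [0.0, 5.0]})
        out = bounding_box_query(pts, BoxRegion({"x": (1, 6), "y": (1, 6)}))
        assert np.allclose(out.coordinates, [[5.0, 5.0]])

    def test_half_open_interval(self):
        pts = build_element("points", {"x": [1.0, 6.0], "y": [1.0, 6.0]})
        out = bounding_box_query(pts, BoxRegion({"x": (1, 6), "y": (1, 6)}))
        # min edge included, max edge excluded
        assert list(out.records["x"]) == [1.0]

    def test_disjoint_box_empty_but_valid(self, blobs):
        region = BoxRegion({"x": (1e6, 1e6 + 1), "y": (1e6, 1e6 + 1)})
        out = bounding_box_query(blobs, region)
        assert len(out.points["transcripts"]) == 0
        assert len(out.shapes["circles"]) == 0
        assert out.images["image"].is_empty
        assert validate_dataset(out) == []

    def test_missing_transformation_errors(self):
        pts = build_element("points", {"x": [0.0], "y": [0.0]})
        with pytest.raises(QueryError, match="stage"):
            bounding_box_query(pts, BoxRegion({"x": (0, 1), "y": (0, 1)}, frame="stage"))


class TestRasterBoxQuery:
    def test_identity_crop_with_translation(self):
        img = build_element("image", np.arange(100.0).reshape(1, 10, 10))
        out = bounding_box_query(img, BoxRegion({"y": (2, 5), "x": (2, 5)}))
        # pixel centers 2.5, 3.5, 4.5 fall inside [2, 5)
        assert np.asarray(out.data).shape == (1, 3, 3)
        assert np.array_equal(
            np.asarray(out.data)[0], np.arange(100.0).reshape(10, 10)[2:5, 2:5]
        )
        m = out.transformations["global"].to_matrix(("y", "x"))
        assert np.allclose(m[:2, 2], [2.0, 2.0])

    def test_scaled_crop(self):
        img = build_element(
            "image",
            np.arange(100.0).reshape(1, 10, 10),
            transformations={"global": Scale({"y": 2, "x": 2})},
        )
        out = bounding_box_query(img, BoxRegion({"y": (2, 6), "x": (2, 6)}))
        # intrinsic box [1, 3): centers 1.5 and 2.5 -> 2x2 crop
        assert np.asarray(out.data).shape == (1, 2, 2)
        assert np.array_equal(
            np.asarray(out.data)[0], np.arange(100.0).reshape(10, 10)[1:3, 1:3]
        )

    def test_crop_position_preserved_in_frame(self):
        # querying the crop again with the same box returns the same pixels
        img = build_element("image", np.arange(100.0).reshape(1, 10, 10))
        region = BoxRegion({"y": (2, 5), "x": (3, 7)})
        once = bounding_box_query(img, region)
        twice = bounding_box_query(once, region)
        assert np.array_equal(np.asarray(once.data), np.asarray(twice.data))


class TestPolygonQuery:
    def test_square_polygon_equals_box(self, rng):
        pts = build_element(
            "points", {"x": rng.uniform(0, 10, 200), "y": rng.uniform(0, 10, 200)}
        )
        box = BoxRegion({"x": (2, 7), "y": (3, 8)})
        poly = PolygonRegion(shapely.box(2, 3, 7, 8))
        got_box = bounding_box_query(pts, box)
        got_poly = polygon_query(pts, poly)
        # boundary measure-zero for random points: same survivors
        assert list(got_box.records.index) == list(got_poly.records.index)

    def test_point_on_edge_kept(self):
        pts = build_element("points", {"x": [0.0], "y": [0.5]})
        poly = PolygonRegion(shapely.box(0, 0, 1, 1))
        assert len(polygon_query(pts, poly)) == 1

    def test_concave_pocket_excluded(self):
        # C-shape: the pocket lies inside the bounding box but outside
        ring = [(0, 0), (4, 0), (4, 1), (1, 1), (1, 3), (4, 3), (4, 4), (0, 4)]
        pts = build_element("points", {"x": [2.0, 0.5], "y": [2.0, 2.0]})
        out = polygon_query(pts, PolygonRegion(shapely.Polygon(ring)))
        assert list(out.records["x"]) == [0.5]
        assert ray_cast((2.0, 2.0), ring) is False
        assert ray_cast((0.5, 2.0), ring) is True

    def test_raster_masked_outside_polygon(self):
        img = build_element("image", np.ones((1, 8, 8)))
        tri = shapely.Polygon([(0, 0), (8, 0), (0, 8)])
        out = polygon_query(img, PolygonRegion(tri))
        data = np.asarray(out.data)[0]
        # center (0.5, 0.5) inside, center (7.5, 7.5) outside the triangle
        assert data[0, 0] == 1.0 and data[7, 7] == 0.0
        total = sum(
            1 for i in range(8) for j in range(8)
            if ray_cast((j + 0.5, i + 0.5), [(0, 0), (8, 0), (0, 8)])
        )
        assert data.sum() == total


class TestOracleEquivalence:
    def test_points_and_shapes_match_brute_force(self, rng):
        for _ in range(50):
            n = rng.integers(5, 40)
            coords = rng.uniform(0, 20, (n, 2))
            pts = build_element("points", {"x": coords[:, 0], "y": coords[:, 1]})
            lo = rng.uniform(0, 10, 2)
            hi = lo + rng.uniform(1, 10, 2)
            bounds = {"x": (lo[0], hi[0]), "y": (lo[1], hi[1])}
            got = bounding_box_query(pts, BoxRegion(bounds))
            expected = [i for i, p in enumerate(coords) if point_in_box(p, bounds)]
            assert list(got.records.index) == expected

            # random convex polygon region for the same point set
            hull = shapely.MultiPoint(rng.uniform(0, 20, (6, 2))).convex_hull
            ring = list(hull.exterior.coords)[:-1]
            gotp = polygon_query(pts, PolygonRegion(shapely.Polygon(ring)))
            expectedp = [i for i, p in enumerate(coords) if ray_cast(tuple(p), ring)]
            assert list(gotp.records.index) == expectedp

            # shapes: circles + triangles vs the box
            m = rng.integers(3, 10)
            records = []
            for k in range(m):
                if k % 2 == 0:
                    records.append(
                        {"center": rng.uniform(0, 20, 2).tolist(),
                         "radius": float(rng.uniform(0.5, 3))}
                    )
                else:
                    def area2(t):
                        u, v = t[1] - t[0], t[2] - t[0]
                        return u[0] * v[1] - u[1] * v[0]

                    tri = rng.uniform(0, 20, (3, 2))
                    while abs(area2(tri)) < 1e-6:
                        tri = rng.uniform(0, 20, (3, 2))
                    records.append({"geometry": shapely.Polygon(tri)})
            shp = build_element("shapes", records)
            got_s = bounding_box_query(shp, BoxRegion(bounds))
            expected_s = []
            for k, rec in enumerate(records):
                if "radius" in rec:
                    if circle_touches_box(rec["center"], rec["radius"], bounds):
                        expected_s.append(k)
                else:
                    ring_s = list(rec["geometry"].exterior.coords)[:-1]
                    if polygon_touches_box(ring_s, bounds):
                        expected_s.append(k)
            assert list(got_s.table.index) == expected_s

    def test_idempotence(self, rng):
        coords = rng.uniform(0, 20, (100, 2))
        pts = build_element("points", {"x": coords[:, 0], "y": coords[:, 1]})
        region = BoxRegion({"x": (3, 12), "y": (5, 15)})
        once = bounding_box_query(pts, region)
        twice = bounding_box_query(once, region)
        assert list(once.records.index) == list(twice.records.index)


class TestDatasetQuery:
    def test_tables_stay_consistent(self, blobs):
        region = BoxRegion({"x": (10, 90), "y": (10, 90)})
        out = bounding_box_query(blobs, region)
        assert validate_dataset(out) == []
        # every surviving table row resolves to a surviving label id
        kept_ids = set(out.labels["segmentation"].instance_ids.tolist())
        assert set(out.tables["annotation"].obs["instance_id"]) <= kept_ids

    def test_frame_invariance_for_points(self, rng):
        # query in frame B == query in frame A with the region mapped A<-B
        coords = rng.uniform(0, 20, (100, 2))
        t_ab = compose(Scale({"x": 2, "y": 2}), Translation({"x": 3, "y": -1}))
        pts = build_element(
            "points",
            {"x": coords[:, 0], "y": coords[:, 1]},
            transformations={"A": __import__("spatialkit").Identity(), "B": t_ab},
        )
        region_b = BoxRegion({"x": (5, 25), "y": (3, 23)}, frame="B")
        # map the box corners B -> A through the inverse (axis-aligned map)
        from spatialkit import invert

        inv = invert(t_ab)
        lo = inv.apply(np.array([[5.0, 3.0]]), ("x", "y"))[0]
        hi = inv.apply(np.array([[25.0, 23.0]]), ("x", "y"))[0]
        region_a = BoxRegion({"x": (lo[0], hi[0]), "y": (lo[1], hi[1])}, frame="A")
        got_b = bounding_box_query(pts, region_b)
        got_a = bounding_box_query(pts, region_a)
        assert list(got_b.records.index) == list(got_a.records.index)
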