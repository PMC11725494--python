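"""Aggregation: counts, area-weighted fractions, conservation, oracles."""

import math

import numpy as np
import pandas as pd
import pytest
import shapely

from spatialkit import (
    AggregationSpec,
    Identity,
    SpatialDataset,
    aggregate,
    build_element,
    filter_low_fractions,
)
from spatialkit.aggregate import (
    AggregationError,
    aggregate_labels_by_shapes,
    aggregate_points_by_shapes,
    aggregate_shapes_by_shapes,
    circle_circle_overlap_area,
    store_as_layer,
)
from spatialkit.transforms import Affine, transform_vector_element

from conftest import random_affine_2d


def _pts(x, y, **cols):
    return build_element("points", {"x": x, "y": y, **cols})


def _circles(centers, radius):
    return build_element(
        "shapes", [{"center": c, "radius": radius} for c in centers]
    )


class TestPointsByShapes:
    def test_count_inside_circle(self):
        ds = SpatialDataset(
            points={"p": _pts([0.0, 0.1, -0.2, 5.0], [0.0, 0.1, 0.2, 5.0])},
            shapes={"s": _circles([(0, 0)], 1.0)},
        )
        out = aggregate_points_by_shapes(AggregationSpec("p", "s"), ds)
        assert np.asarray(out.X).ravel().tolist() == [3.0]

    def test_categorical_counts(self):
        ds = SpatialDataset(
            points={"p": _pts([0.2, 0.4, 0.6], [0.5, 0.5, 0.5],
                              feature=pd.Categorical(["A", "A", "B"]))},
            shapes={"s": build_element("shapes", [shapely.box(0, 0, 1, 1)])},
        )
        out = aggregate_points_by_shapes(
            AggregationSpec("p", "s", value_key="feature"), ds
        )
        assert [str(v) for v in out.var.index] == ["A", "B"]
        assert np.asarray(out.X).tolist() == [[2.0, 1.0]]

    def test_matches_brute_force_matrix(self, rng):
        n, m = 1000, 10
        coords = rng.uniform(0, 50, (n, 2))
        cats = rng.integers(0, 4, n)
        names = ["c0", "c1", "c2", "c3"]
        centers = rng.uniform(5, 45, (m, 2))
        radius = 4.0
        ds = SpatialDataset(
            points={"p": _pts(coords[:, 0], coords[:, 1],
                              feature=pd.Categorical.from_codes(cats, names))},
            shapes={"s": _circles(centers, radius)},
        )
        out = aggregate_points_by_shapes(
            AggregationSpec("p", "s", value_key="feature"), ds
        )
        expected = np.zeros((m, 4))
        for i in range(n):
            for j in range(m):
                d2 = (coords[i, 0] - centers[j, 0]) ** 2 + (coords[i, 1] - centers[j, 1]) ** 2
                if d2 <= radius**2:
                    expected[j, cats[i]] += 1
        assert np.array_equal(np.asarray(out.X), expected)

    def test_count_conservation_under_disjoint_tiling(self, rng):
        coords = rng.uniform(0, 4, (200, 2))
        tiles = [shapely.box(i, j, i + 1, j + 1) for i in range(4) for j in range(4)]
        ds = SpatialDataset(
            points={"p": _pts(coords[:, 0], coords[:, 1])},
            shapes={"s": build_element("shapes", tiles)},
        )
        out = aggregate_points_by_shapes(AggregationSpec("p", "s"), ds)
        # closed tiles share edges: a point on a shared edge counts twice,
        # but random points avoid edges almost surely
        assert np.asarray(out.X).sum() == 200.0

    def test_numeric_sum_and_mean(self):
        ds = SpatialDataset(
            points={"p": _pts([0.5, 0.6, 5.0], [0.5, 0.5, 5.0], v=[1.0, 3.0, 100.0])},
            shapes={"s": build_element("shapes", [shapely.box(0, 0, 1, 1)])},
        )
        s = aggregate_points_by_shapes(AggregationSpec("p", "s", "v", agg="sum"), ds)
        m = aggregate_points_by_shapes(AggregationSpec("p", "s", "v", agg="mean"), ds)
        assert np.asarray(s.X).ravel()[0] == 4.0
        assert np.asarray(m.X).ravel()[0] == 2.0

    def test_result_table_links_to_target(self):
        ds = SpatialDataset(
            points={"p": _pts([0.5], [0.5])},
            shapes={"s": build_element("shapes", [shapely.box(0, 0, 1, 1)])},
        )
        out = aggregate(AggregationSpec("p", "s"), ds)
        assert out.region == "s"
        ds.tables["agg"] = out
        from spatialkit import validate_dataset

        assert validate_dataset(ds) == []


class TestShapesByShapes:
    def test_source_fully_inside(self):
        ds = SpatialDataset(shapes={
            "cells": build_element("shapes", [shapely.box(1, 1, 2, 2)]),
            "spots": build_element("shapes", [shapely.box(0, 0, 5, 5)]),
        })
        ds.shapes["cells"].table["ctype"] = pd.Categorical(["A"])
        out = aggregate_shapes_by_shapes(
            AggregationSpec("cells", "spots", "ctype", fractions=True), ds
        )
        assert np.asarray(out.X).tolist() == [[1.0]]

    def test_half_overlap_weight(self):
        ds = SpatialDataset(shapes={
            "cells": build_element("shapes", [shapely.box(-0.5, 0, 0.5, 1)]),
            "spots": build_element("shapes", [shapely.box(0, 0, 5, 5)]),
        })
        out = aggregate_shapes_by_shapes(AggregationSpec("cells", "spots"), ds)
        assert np.asarray(out.X).ravel()[0] == pytest.approx(0.5, abs=1e-12)

    def test_fractions_normalized(self):
        # A contributes weight 1.0, B weight 0.5 -> fractions 2/3 and 1/3
        ds = SpatialDataset(shapes={
            "cells": build_element(
                "shapes", [shapely.box(1, 1, 2, 2), shapely.box(-0.5, 3, 0.5, 4)]
            ),
            "spots": build_element("shapes", [shapely.box(0, 0, 5, 5)]),
        })
        ds.shapes["cells"].table["ctype"] = pd.Categorical(["A", "B"])
        out = aggregate_shapes_by_shapes(
            AggregationSpec("cells", "spots", "ctype", fractions=True), ds
        )
        assert np.allclose(np.asarray(out.X), [[2 / 3, 1 / 3]])

    def test_circle_square_weight_vs_segment_area(self):
        # big square covering the half-plane x >= d cuts a unit circle:
        # overlap = r^2 acos(d/r) - d sqrt(r^2 - d^2) (circular segment)
        r, d = 1.0, 0.3
        ds = SpatialDataset(shapes={
            "cells": _circles([(0, 0)], r),
            "spots": build_element("shapes", [shapely.box(d, -10, 20, 10)]),
        })
        out = aggregate_shapes_by_shapes(AggregationSpec("cells", "spots"), ds)
        segment = r * r * math.acos(d / r) - d * math.sqrt(r * r - d * d)
        expected = segment / (math.pi * r * r)
        got = np.asarray(out.X).ravel()[0]
        assert got == pytest.approx(expected, rel=0.01)

    def test_circle_circle_analytic(self):
        # concentric circles: overlap = area of the smaller
        assert circle_circle_overlap_area((0, 0), 2.0, (0, 0), 1.0) == pytest.approx(
            math.pi
        )
        # far apart: zero
        assert circle_circle_overlap_area((0, 0), 1.0, (5, 0), 1.0) == 0.0
        ds = SpatialDataset(shapes={
            "cells": _circles([(0, 0)], 1.0),
            "spots": _circles([(1, 0)], 1.0),
        })
        out = aggregate_shapes_by_shapes(AggregationSpec("cells", "spots"), ds)
        lens = circle_circle_overlap_area((0, 0), 1.0, (1, 0), 1.0)
        assert np.asarray(out.X).ravel()[0] == pytest.approx(lens / math.pi, abs=1e-12)

    def test_source_weight_conservation(self, rng):
        # sum_j w_ij <= 1 always; == 1 when tiles disjointly cover the source
        cells = [shapely.box(x, y, x + 0.8, y + 0.8)
                 for x, y in rng.uniform(0.5, 2.5, (5, 2))]
        cells.append(shapely.Point(2.0, 2.0).buffer(0.7, quad_segs=16))
        tiles = [shapely.box(i, j, i + 1, j + 1) for i in range(4) for j in range(4)]
        ds = SpatialDataset(shapes={
            "cells": build_element("shapes", cells),
            "spots": build_element("shapes", tiles),
        })
        from spatialkit.aggregate import _source_area_weights

        w = _source_area_weights(ds.shapes["cells"], ds.shapes["spots"])
        sums = w.sum(axis=1)
        assert np.all(sums <= 1 + 1e-6)
        assert np.allclose(sums, 1.0, atol=1e-6)  # tiles cover [0,4)^2 fully

    def test_fraction_rows_sum_to_one_or_zero(self, rng):
        cells = [shapely.box(x, y, x + 1, y + 1) for x, y in rng.uniform(0, 8, (12, 2))]
        ds = SpatialDataset(shapes={
            "cells": build_element("shapes", cells),
            "spots": _circles(rng.uniform(0, 9, (6, 2)), 1.5),
        })
        ds.shapes["cells"].table["ctype"] = pd.Categorical(
            rng.choice(["A", "B", "C"], size=12).tolist()
        )
        out = aggregate_shapes_by_shapes(
            AggregationSpec("cells", "spots", "ctype", fractions=True), ds
        )
        sums = np.asarray(out.X).sum(axis=1)
        zero = out.obs["no_overlap"].to_numpy()
        assert np.allclose(sums[~zero], 1.0, atol=1e-9)
        assert np.allclose(sums[zero], 0.0)

    def test_frame_covariance_polygons_any_affine(self, rng):
        # the same affine applied to source and target leaves weights
        # unchanged: areas rescale jointly by |det|
        cells = [shapely.box(x, y, x + 1, y + 1) for x, y in rng.uniform(0, 8, (6, 2))]
        spots = build_element(
            "shapes",
            [shapely.Point(*c).buffer(1.5, quad_segs=16) for c in rng.uniform(0, 9, (4, 2))],
        )
        src = build_element("shapes", cells)
        t = Affine(random_affine_2d(rng, max_entry=1.5, min_det=0.3), ("x", "y"), ("x", "y"))
        from spatialkit.aggregate import _source_area_weights

        w1 = _source_area_weights(src, spots)
        w2 = _source_area_weights(
            transform_vector_element(src, t), transform_vector_element(spots, t)
        )
        assert np.allclose(w1, w2, atol=1e-6)

    def test_frame_covariance_circles_similarity(self, rng):
        # circles stay circles only under similarity transforms: rotation +
        # isotropic scale + translation keeps overlap weights unchanged
        cells = _circles(rng.uniform(0, 8, (5, 2)), 1.0)
        spots = _circles(rng.uniform(0, 8, (4, 2)), 1.6)
        theta = rng.uniform(0, 2 * np.pi)
        s = rng.uniform(0.5, 2.0)
        lin = s * np.array([[np.cos(theta), -np.sin(theta)],
                            [np.sin(theta), np.cos(theta)]])
        t = Affine.from_linear(lin, rng.uniform(-5, 5, 2), ("x", "y"))
        from spatialkit.aggregate import _source_area_weights

        w1 = _source_area_weights(cells, spots)
        w2 = _source_area_weights(
            transform_vector_element(cells, t), transform_vector_element(spots, t)
        )
        assert np.allclose(w1, w2, atol=1e-6)

    def test_fractions_need_categorical(self):
        ds = SpatialDataset(shapes={
            "cells": build_element("shapes", [shapely.box(0, 0, 1, 1)]),
            "spots": build_element("shapes", [shapely.box(0, 0, 5, 5)]),
        })
        ds.shapes["cells"].table["v"] = [1.5]
        with pytest.raises(AggregationError, match="categorical"):
            aggregate_shapes_by_shapes(
                AggregationSpec("cells", "spots", "v", fractions=True), ds
            )


class TestLabelsByShapes:
    def test_pixel_counting_weights(self):
        data = np.zeros((4, 4), dtype=np.int32)
        data[0:2, 0:2] = 1  # 4 pixels, 2 of them (column x<1) inside the box
        ds = SpatialDataset(
            labels={"seg": build_element("labels", data)},
            shapes={"roi": build_element("shapes", [shapely.box(0, 0, 1, 4)])},
        )
        out = aggregate_labels_by_shapes(AggregationSpec("seg", "roi"), ds)
        assert np.asarray(out.X).ravel()[0] == pytest.approx(0.5)


class TestHelpers:
    def test_filter_low_fractions_renormalizes(self):
        table = build_element(
            "table", np.array([[0.9, 0.07, 0.03], [0.0, 0.0, 0.0]]),
            obs=pd.DataFrame({"region": ["s", "s"], "instance_id": [0, 1]}),
            region="s", region_key="region", instance_key="instance_id",
        )
        out = filter_low_fractions(table, threshold=0.05)
        X = np.asarray(out.X)
        assert np.allclose(X[0], [0.9 / 0.97, 0.07 / 0.97, 0.0])
        assert np.allclose(X[1], 0.0)

    def test_store_as_layer_matches_instances(self):
        base = build_element(
            "table", np.zeros((2, 1)),
            obs=pd.DataFrame({"region": ["s", "s"], "instance_id": [1, 0]}),
            region="s", region_key="region", instance_key="instance_id",
        )
        result = build_element(
            "table", np.array([[10.0], [20.0]]),
            obs=pd.DataFrame({"region": ["s", "s"], "instance_id": [0, 1]}),
            region="s", region_key="region", instance_key="instance_id",
        )
        store_as_layer(base, "agg", result)
        assert np.allclose(np.asarray(base.layers["agg"]).ravel(), [20.0, 10.0])
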