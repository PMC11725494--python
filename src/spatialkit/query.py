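"""Spatial queries: subset elements or whole datasets by a region.

A query region (axis-aligned box or polygon) is expressed in a named
coordinate system; each queried element is tested through its own
transformation into that system, so datasets aligned to a common coordinate
system can be queried jointly.

Conventions (fixed globally):

* box membership for points and pixel centers is half-open per axis:
  ``min <= v < max``;
* polygon membership is closed (a point exactly on the boundary is kept),
  with the even-odd interior rule;
* shapes survive on *intersection* with the region by default (an ROI
  captures cells partially inside it); ``mode="centroid"`` switches to
  centroid containment;
* raster queries never resample: a crop keeps its pixels and records its
  position by composing a translation into the element's transformation.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping

import numpy as np
import shapely

from . import elements as el
from .elements import SpatialDataset, element_instance_ids
from .transforms import Sequence, Transformation, Translation, invert

__all__ = ["BoxRegion", "PolygonRegion", "bounding_box_query", "polygon_query"]


class QueryError(ValueError):
    pass


@dataclasses.dataclass
class BoxRegion:
    """Axis-aligned box ``{axis: (min, max)}`` in coordinate system ``frame``."""

    bounds: Mapping[str, tuple[float, float]]
    frame: str = "global"

    def __post_init__(self):
        for axis, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise QueryError(f"box axis {axis!r}: min {lo} must be < max {hi}")


@dataclasses.dataclass
class PolygonRegion:
    """Polygonal region (shapely Polygon in (x, y)) in system ``frame``."""

    polygon: shapely.Polygon
    frame: str = "global"

    def __post_init__(self):
        if not isinstance(self.polygon, (shapely.Polygon, shapely.MultiPolygon)):
            raise QueryError("region polygon must be a shapely (Multi)Polygon")
        if not self.polygon.is_valid:
            raise QueryError("region polygon is invalid (self-intersecting?)")


def _transform_into(element, frame: str) -> Transformation:
    t = element.transformations.get(frame)
    if t is None:
        raise QueryError(
            f"element has no transformation into coordinate system {frame!r}"
        )
    return t


# ---------------------------------------------------------------------------
# per-kind box query


def _points_in_box(points: el.Points, region: BoxRegion) -> el.Points:
    t = _transform_into(points, region.frame)
    axes = points.coordinate_axes
    coords = t.apply(points.coordinates, axes)
    mask = np.ones(len(points), dtype=bool)
    for axis, (lo, hi) in region.bounds.items():
        if axis not in axes:
            continue
        v = coords[:, axes.index(axis)]
        mask &= (v >= lo) & (v < hi)
    return points.replace(records=points.records.loc[mask])


def _box_geometry(region: BoxRegion) -> shapely.Polygon:
    big = 1e15  # effectively unbounded; shapely cannot box infinities
    (x0, x1) = region.bounds.get("x", (-big, big))
    (y0, y1) = region.bounds.get("y", (-big, big))
    return shapely.box(x0, y0, x1, y1)


def _shapes_in_region(shapes: el.Shapes, region, region_geom, mode: str) -> el.Shapes:
    from .transforms import transform_vector_element

    t = _transform_into(shapes, region.frame)
    moved = transform_vector_element(shapes, t)
    keep = []
    for iid, geom, radius in zip(
        moved.table.index, moved.table["geometry"], moved.table["radius"]
    ):
        if mode == "centroid":
            probe = geom.centroid if not np.isfinite(radius) else geom
            keep.append(bool(region_geom.covers(probe)))
        elif np.isfinite(radius):
            # exact center-distance test for circles against any region
            keep.append(bool(region_geom.distance(geom) <= radius))
        else:
            keep.append(bool(region_geom.intersects(geom)))
    mask = np.asarray(keep, dtype=bool)
    return shapes.replace(table=shapes.table.loc[mask])


def _raster_intrinsic_bounds(raster, t, frame_bounds: Mapping[str, tuple[float, float]]):
    """Axis-aligned intrinsic bounds of the inverse-transformed region box."""
    spatial = raster.spatial_axes
    m_inv = invert(t).to_matrix(spatial)
    d = len(spatial)
    corners = np.array(
        list(itertools.product(*[frame_bounds[a] for a in spatial])), dtype=float
    )
    src = corners @ m_inv[:d, :d].T + m_inv[:d, d]
    return src.min(axis=0), src.max(axis=0)


def _crop_raster(raster, t, lo: np.ndarray, hi: np.ndarray, frame: str):
    """Crop to pixels whose centers fall in [lo, hi) per intrinsic axis."""
    spatial = raster.spatial_axes
    d = len(spatial)
    shape = np.asarray(raster.data.shape[-d:])
    i0 = np.clip(np.ceil(lo - 0.5).astype(int), 0, shape)
    i1 = np.clip(np.ceil(hi - 0.5).astype(int), 0, shape)
    i1 = np.maximum(i1, i0)
    sl = tuple([slice(None)] * (raster.data.ndim - d)) + tuple(
        slice(a, b) for a, b in zip(i0, i1)
    )
    data = np.asarray(raster.data[sl])
    offset = Translation({a: float(v) for a, v in zip(spatial, i0)})
    new_t = Sequence([offset, t])
    return raster.replace(pyramid=[data], transformations={frame: new_t}), i0


def _raster_in_box(raster, region: BoxRegion):
    t = _transform_into(raster, region.frame)
    spatial = raster.spatial_axes
    missing = [a for a in spatial if a not in region.bounds]
    bounds = dict(region.bounds)
    for a in missing:  # unbounded axes pass through whole extent
        d = len(spatial)
        size = raster.data.shape[-d:][spatial.index(a)]
        bounds[a] = (0.0, float(size))
    lo, hi = _raster_intrinsic_bounds(raster, t, bounds)
    cropped, _ = _crop_raster(raster, t, lo, hi, region.frame)
    return cropped


def bounding_box_query(target, region: BoxRegion, mode: str = "intersect"):
    """Subset an element or dataset to an axis-aligned box.

    Points keep rows whose transformed coordinates lie in ``[min, max)``
    per axis; shapes keep instances whose transformed geometry touches the
    closed box; rasters crop to the pixels whose centers fall inside the
    inverse-transformed box's axis-aligned intrinsic bounds, recording the
    crop offset in their transformation.  Datasets apply this per element
    and restrict their tables to surviving instances.
    """
    if isinstance(target, SpatialDataset):
        return _query_dataset(target, region, mode)
    if isinstance(target, el.Points):
        return _points_in_box(target, region)
    if isinstance(target, el.Shapes):
        return _shapes_in_region(target, region, _box_geometry(region), mode)
    if isinstance(target, (el.Image, el.Labels)):
        return _raster_in_box(target, region)
    raise TypeError(f"cannot query {type(target).__name__}")


# ---------------------------------------------------------------------------
# polygon query


def _points_in_polygon(points: el.Points, region: PolygonRegion) -> el.Points:
    t = _transform_into(points, region.frame)
    axes = points.coordinate_axes
    coords = t.apply(points.coordinates, axes)
    pts = shapely.points(coords[:, axes.index("x")], coords[:, axes.index("y")])
    mask = shapely.covers(region.polygon, pts)  # closed containment
    return points.replace(records=points.records.loc[mask])


def _raster_in_polygon(raster, region: PolygonRegion):
    t = _transform_into(raster, region.frame)
    spatial = raster.spatial_axes
    if spatial != ("y", "x"):
        raise QueryError("polygon queries support 2D rasters only")
    minx, miny, maxx, maxy = region.polygon.bounds
    lo, hi = _raster_intrinsic_bounds(raster, t, {"y": (miny, maxy), "x": (minx, maxx)})
    cropped, i0 = _crop_raster(raster, t, lo, hi, region.frame)
    data = np.asarray(cropped.data).copy()
    ny, nx = data.shape[-2:]
    if ny and nx:
        yy, xx = np.meshgrid(
            i0[0] + np.arange(ny) + 0.5, i0[1] + np.arange(nx) + 0.5, indexing="ij"
        )
        m = t.to_matrix(spatial)
        centers = np.stack([yy.ravel(), xx.ravel()])
        mapped = m[:2, :2] @ centers + m[:2, 2:]
        pts = shapely.points(mapped[1], mapped[0])  # frame (x, y)
        inside = shapely.covers(region.polygon, pts).reshape(ny, nx)
        data[..., ~inside] = 0
    return cropped.replace(pyramid=[data])


def polygon_query(target, region: PolygonRegion, mode: str = "intersect"):
    """Subset an element or dataset to a polygonal region.

    Points are kept inside or on the polygon boundary; shapes survive on
    intersection; rasters are cropped to the polygon's bounding box and
    pixels whose centers fall outside the polygon are zeroed.
    """
    if isinstance(target, SpatialDataset):
        return _query_dataset(target, region, mode)
    if isinstance(target, el.Points):
        return _points_in_polygon(target, region)
    if isinstance(target, el.Shapes):
        return _shapes_in_region(target, region, region.polygon, mode)
    if isinstance(target, (el.Image, el.Labels)):
        return _raster_in_polygon(target, region)
    raise TypeError(f"cannot query {type(target).__name__}")


# ---------------------------------------------------------------------------
# dataset-level query


def _query_dataset(ds: SpatialDataset, region, mode: str) -> SpatialDataset:
    query = bounding_box_query if isinstance(region, BoxRegion) else polygon_query
    out = SpatialDataset()
    for kind, name, element in ds.spatial_elements():
        getattr(out, kind)[name] = query(element, region, mode=mode)
    for tname, table in ds.tables.items():
        if not table.is_linked():
            out.tables[tname] = table
            continue
        regions = (
            table.region if isinstance(table.region, (list, tuple)) else [table.region]
        )
        keep = np.zeros(table.n_obs, dtype=bool)
        obs = table.obs
        for rname in regions:
            try:
                element = out.get_element(rname)
            except KeyError:
                continue
            ids = set(np.asarray(element_instance_ids(element)).tolist())
            in_region = obs[table.region_key].astype(str) == str(rname)
            resolved = obs[table.instance_key].map(lambda i: i in ids)
            keep |= (in_region & resolved).to_numpy()
        out.tables[tname] = table.subset(keep)
    return out
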