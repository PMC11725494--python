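"""The five primitive spatial element types and their container.

A spatial dataset is a named collection of five kinds of element:

* :class:`Image` — dense raster with axes ``(c, y, x)`` or ``(c, z, y, x)``,
  optionally carrying a multiscale pyramid;
* :class:`Labels` — non-negative integer raster over ``(y, x)`` or
  ``(z, y, x)`` where each nonzero value is the id of a segmented instance
  (0 is background);
* :class:`Points` — point records (e.g. transcript locations) with float
  coordinate columns ``x, y[, z]`` plus arbitrary attribute columns;
* :class:`Shapes` — per-instance vector geometries: circles (center +
  radius, e.g. array capture locations) or polygons/multipolygons;
* :class:`AnnotationTable` — an instances × variables matrix with
  per-instance metadata, linked to the element it annotates through the
  ``(region, region_key, instance_key)`` triple.

Raster pixel ``(i, j)`` occupies the half-open square
``[i, i+1) × [j, j+1)`` in intrinsic ``(y, x)`` units; its center is
``(i + 0.5, j + 0.5)``.  Every element carries a mapping from coordinate
system name to the transformation that places it there; a fresh element maps
into ``"global"`` with the identity.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import shapely
from anndata import AnnData

from .transforms import Identity, Transformation

__all__ = [
    "VALID_AXES",
    "validate_axes",
    "Image",
    "Labels",
    "Points",
    "Shapes",
    "AnnotationTable",
    "SpatialDataset",
    "Violation",
    "build_element",
    "validate_dataset",
    "match_table_to_element",
    "read_points_csv",
    "read_shapes_geojson",
    "read_raster_file",
]

#: canonical axis order for rasters; any element uses an ordered subset
VALID_AXES = ("c", "z", "y", "x")

#: maximum spatial dimension above which pyramid levels keep being added
PYRAMID_STOP = 64


class ElementError(ValueError):
    """Raised when an element payload violates its kind's contract."""


def validate_axes(axes) -> tuple[str, ...]:
    """Check that ``axes`` is an ordered subset of ``(c, z, y, x)``."""
    axes = tuple(axes)
    if len(set(axes)) != len(axes):
        raise ElementError(f"duplicate axes in {axes}")
    order = [VALID_AXES.index(a) if a in VALID_AXES else -1 for a in axes]
    if -1 in order:
        raise ElementError(f"unknown axis in {axes}; valid axes are {VALID_AXES}")
    if order != sorted(order):
        raise ElementError(f"axes {axes} must follow the order {VALID_AXES}")
    return axes


def _default_transformations(transformations):
    if transformations:
        return dict(transformations)
    return {"global": Identity()}


# ---------------------------------------------------------------------------
# raster elements


def _image_pyramid(data: np.ndarray, n_spatial: int) -> list[np.ndarray]:
    """Factor-2 mean-pooled levels until the max spatial dim falls below 64.

    Trailing odd rows/columns are dropped before pooling so each level is an
    exact 2x(2x...) block mean of the previous one.
    """
    levels = [data]
    while max(levels[-1].shape[-n_spatial:]) >= PYRAMID_STOP:
        cur = levels[-1]
        sl = tuple([slice(None)] * (cur.ndim - n_spatial)) + tuple(
            slice(0, (s // 2) * 2) for s in cur.shape[-n_spatial:]
        )
        cur = cur[sl]
        new_shape = list(cur.shape[: cur.ndim - n_spatial])
        for s in cur.shape[-n_spatial:]:
            new_shape.extend([s // 2, 2])
        blocks = cur.reshape(new_shape)
        axes_to_mean = tuple(
            cur.ndim - n_spatial + 2 * i + 1 for i in range(n_spatial)
        )
        levels.append(blocks.astype(float).mean(axis=axes_to_mean))
    return levels


def _labels_pyramid(data: np.ndarray, n_spatial: int) -> list[np.ndarray]:
    """Stride-2 subsampled levels (nearest: keeps only existing label ids)."""
    levels = [data]
    while max(levels[-1].shape[-n_spatial:]) >= PYRAMID_STOP:
        cur = levels[-1]
        sl = tuple([slice(None)] * (cur.ndim - n_spatial)) + tuple(
            slice(0, None, 2) for _ in range(n_spatial)
        )
        levels.append(cur[sl])
    return levels


@dataclasses.dataclass
class _Raster:
    pyramid: list  # level 0 = full resolution; entries may be lazy arrays
    axes: tuple[str, ...]
    transformations: dict[str, Transformation]

    @property
    def data(self):
        return self.pyramid[0]

    @property
    def spatial_axes(self) -> tuple[str, ...]:
        return tuple(a for a in self.axes if a in ("z", "y", "x"))

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(self.data.shape)

    @property
    def is_empty(self) -> bool:
        return 0 in self.data.shape

    def replace(self, **updates) -> "_Raster":
        return dataclasses.replace(self, **updates)

    def materialize(self) -> "_Raster":
        """Load any lazy pyramid levels into memory."""
        return self.replace(pyramid=[np.asarray(lv) for lv in self.pyramid])


@dataclasses.dataclass
class Image(_Raster):
    """Dense numeric raster over (c, y, x) or (c, z, y, x)."""


@dataclasses.dataclass
class Labels(_Raster):
    """Integer instance-id raster over (y, x) or (z, y, x); 0 = background."""

    @property
    def instance_ids(self) -> np.ndarray:
        vals = np.unique(np.asarray(self.data))
        return vals[vals != 0]


# ---------------------------------------------------------------------------
# vector elements


@dataclasses.dataclass
class Points:
    """Point records with float coordinate columns and attribute columns.

    The DataFrame index is the stable instance id and is preserved verbatim
    by every operation.
    """

    records: pd.DataFrame
    transformations: dict[str, Transformation]

    @property
    def coordinate_axes(self) -> tuple[str, ...]:
        return ("x", "y", "z") if "z" in self.records.columns else ("x", "y")

    @property
    def coordinates(self) -> np.ndarray:
        return self.records[list(self.coordinate_axes)].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.records)

    def replace(self, **updates) -> "Points":
        return dataclasses.replace(self, **updates)


@dataclasses.dataclass
class Shapes:
    """Per-instance circle or polygon geometries.

    ``table`` has a ``geometry`` column of shapely objects and a ``radius``
    column: circles are stored as a shapely Point center plus a finite
    positive radius; polygons/multipolygons carry ``radius = NaN``.  The
    index is the stable instance id.
    """

    table: pd.DataFrame
    transformations: dict[str, Transformation]

    @property
    def geometry(self) -> pd.Series:
        return self.table["geometry"]

    @property
    def radius(self) -> pd.Series:
        return self.table["radius"]

    @property
    def instance_ids(self) -> pd.Index:
        return self.table.index

    def is_circle(self) -> np.ndarray:
        return np.isfinite(self.table["radius"].to_numpy(dtype=float))

    def __len__(self) -> int:
        return len(self.table)

    def replace(self, **updates) -> "Shapes":
        return dataclasses.replace(self, **updates)

    def resolved_geometry(self, circle_segments: int = 16) -> list:
        """Geometries with circles polygonized (``4 * circle_segments``-gon)."""
        out = []
        for geom, radius in zip(self.table["geometry"], self.table["radius"]):
            if np.isfinite(radius):
                out.append(geom.buffer(radius, quad_segs=circle_segments))
            else:
                out.append(geom)
        return out


# ---------------------------------------------------------------------------
# annotation tables


class AnnotationTable:
    """Instances × variables matrix annotating the instances of an element.

    Thin wrapper around :class:`anndata.AnnData` adding the linkage triple:
    ``region`` names the annotated element, ``region_key`` is the obs column
    holding the element name per row and ``instance_key`` the obs column
    holding the instance id per row.  Either all three are set or none.
    """

    def __init__(
        self,
        adata: AnnData,
        region: str | list[str] | None = None,
        region_key: str | None = None,
        instance_key: str | None = None,
    ):
        self.adata = adata
        self.region = region
        self.region_key = region_key
        self.instance_key = instance_key
        adata.uns["annotation_target"] = {
            "region": region,
            "region_key": region_key,
            "instance_key": instance_key,
        }

    @classmethod
    def from_arrays(
        cls,
        X,
        obs: pd.DataFrame | None = None,
        var: pd.DataFrame | None = None,
        layers: Mapping | None = None,
        region=None,
        region_key=None,
        instance_key=None,
    ) -> "AnnotationTable":
        adata = AnnData(X=X, obs=obs, var=var, layers=dict(layers or {}))
        return cls(adata, region=region, region_key=region_key, instance_key=instance_key)

    @property
    def X(self):
        return self.adata.X

    @property
    def obs(self) -> pd.DataFrame:
        return self.adata.obs

    @property
    def var(self) -> pd.DataFrame:
        return self.adata.var

    @property
    def layers(self):
        return self.adata.layers

    @property
    def n_obs(self) -> int:
        return self.adata.n_obs

    def is_linked(self) -> bool:
        return self.region is not None

    def subset(self, row_mask_or_index) -> "AnnotationTable":
        sub = self.adata[row_mask_or_index].copy()
        return AnnotationTable(
            sub,
            region=self.region,
            region_key=self.region_key,
            instance_key=self.instance_key,
        )

    def __repr__(self):
        return (
            f"AnnotationTable({self.adata.n_obs} x {self.adata.n_vars}, "
            f"region={self.region!r})"
        )


# ---------------------------------------------------------------------------
# container


@dataclasses.dataclass
class SpatialDataset:
    """Named collection of elements; the unit of storage and query."""

    images: dict[str, Image] = dataclasses.field(default_factory=dict)
    labels: dict[str, Labels] = dataclasses.field(default_factory=dict)
    points: dict[str, Points] = dataclasses.field(default_factory=dict)
    shapes: dict[str, Shapes] = dataclasses.field(default_factory=dict)
    tables: dict[str, AnnotationTable] = dataclasses.field(default_factory=dict)

    def spatial_elements(self) -> Iterator[tuple[str, str, object]]:
        """Yield (kind, name, element) for the four spatial kinds."""
        for kind in ("images", "labels", "points", "shapes"):
            for name, el in getattr(self, kind).items():
                yield kind, name, el

    def element_names(self) -> list[str]:
        return [name for _, name, _ in self.spatial_elements()]

    def get_element(self, name: str):
        for _, n, el in self.spatial_elements():
            if n == name:
                return el
        raise KeyError(f"no spatial element named {name!r}")

    def coordinate_systems(self) -> list[str]:
        systems: dict[str, None] = {}
        for _, _, el in self.spatial_elements():
            systems.update(dict.fromkeys(el.transformations))
        return list(systems)

    def __repr__(self):
        parts = []
        for kind in ("images", "labels", "points", "shapes", "tables"):
            d = getattr(self, kind)
            if d:
                parts.append(f"{kind}: {sorted(d)}")
        return "SpatialDataset(" + "; ".join(parts) + ")"


# ---------------------------------------------------------------------------
# instance-id helpers


def element_instance_ids(element) -> np.ndarray:
    """Ordered instance ids of a Labels, Shapes or Points element.

    Labels report their sorted distinct nonzero pixel values; Shapes and
    Points report their row index in row order.
    """
    if isinstance(element, Labels):
        return element.instance_ids
    if isinstance(element, Shapes):
        return np.asarray(element.table.index)
    if isinstance(element, Points):
        return np.asarray(element.records.index)
    raise TypeError(f"{type(element).__name__} has no instance ids")


# ---------------------------------------------------------------------------
# constructors


def _validate_polygon(geom) -> None:
    polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
    for poly in polys:
        if poly.geom_type != "Polygon":
            raise ElementError(f"unsupported geometry type {poly.geom_type}")
        coords = list(poly.exterior.coords)
        distinct = {tuple(c) for c in coords}
        if len(distinct) < 3:
            raise ElementError("polygon ring needs >= 3 distinct vertices")
        if tuple(coords[0]) != tuple(coords[-1]):
            raise ElementError("polygon ring must be closed")


def build_element(kind: str, payload, **options):
    """Construct and validate an element of the given kind.

    Parameters
    ----------
    kind
        One of ``image``, ``labels``, ``points``, ``shapes``, ``table``.
    payload
        Raw data appropriate for the kind: an array for rasters, a DataFrame
        (or dict of columns) for points, a list of geometry records for
        shapes (dicts with either ``center``/``radius`` or a shapely
        (multi)polygon under ``geometry``), or an AnnData/array for tables.
    options
        ``transformations`` (mapping system -> Transformation; defaults to
        identity into "global"), ``pyramid=True`` to build a multiscale
        pyramid for rasters, and for tables the linkage triple
        ``region``/``region_key``/``instance_key`` plus ``obs``/``var``.
    """
    transformations = _default_transformations(options.pop("transformations", None))
    if kind == "image":
        data = np.asarray(payload)
        if data.ndim == 2:
            data = data[np.newaxis]
        if data.ndim == 3:
            axes = ("c", "y", "x")
        elif data.ndim == 4:
            axes = ("c", "z", "y", "x")
        else:
            raise ElementError(f"image payload must be 2D-4D, got {data.ndim}D")
        if not np.issubdtype(data.dtype, np.number):
            raise ElementError(f"image payload must be numeric, got {data.dtype}")
        pyramid = (
            _image_pyramid(data, len(axes) - 1) if options.pop("pyramid", False) else [data]
        )
        return Image(pyramid=pyramid, axes=axes, transformations=transformations)
    if kind == "labels":
        data = np.asarray(payload)
        if data.ndim == 2:
            axes = ("y", "x")
        elif data.ndim == 3:
            axes = ("z", "y", "x")
        else:
            raise ElementError(f"labels payload must be 2D or 3D, got {data.ndim}D")
        if not np.issubdtype(data.dtype, np.integer):
            raise ElementError(f"labels payload must be integer, got {data.dtype}")
        if data.size and data.min() < 0:
            raise ElementError("labels payload must be non-negative (0 = background)")
        pyramid = (
            _labels_pyramid(data, data.ndim) if options.pop("pyramid", False) else [data]
        )
        return Labels(pyramid=pyramid, axes=axes, transformations=transformations)
    if kind == "points":
        records = payload if isinstance(payload, pd.DataFrame) else pd.DataFrame(payload)
        records = records.copy()
        for axis in ("x", "y"):
            if axis not in records.columns:
                raise ElementError(f"points payload lacks coordinate column {axis!r}")
        coord_cols = ["x", "y"] + (["z"] if "z" in records.columns else [])
        coords = records[coord_cols].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ElementError("point coordinates must be finite")
        return Points(records=records, transformations=transformations)
    if kind == "shapes":
        geoms, radii, ids = [], [], []
        index = options.pop("index", None)
        for i, rec in enumerate(payload):
            if isinstance(rec, Mapping) and "radius" in rec:
                radius = float(rec["radius"])
                if not radius > 0:
                    raise ElementError(f"circle radius must be > 0, got {radius}")
                center = rec.get("center")
                geoms.append(shapely.Point(center))
                radii.append(radius)
            else:
                geom = rec["geometry"] if isinstance(rec, Mapping) else rec
                if not isinstance(geom, (shapely.Polygon, shapely.MultiPolygon)):
                    geom = shapely.geometry.shape(geom)
                _validate_polygon(geom)
                geoms.append(geom)
                radii.append(math.nan)
            ids.append(i)
        table = pd.DataFrame(
            {"geometry": geoms, "radius": radii},
            index=(index if index is not None else ids),
        )
        return Shapes(table=table, transformations=transformations)
    if kind == "table":
        if isinstance(payload, AnnData):
            adata = payload
        else:
            adata = AnnData(
                X=payload, obs=options.pop("obs", None), var=options.pop("var", None)
            )
        return AnnotationTable(
            adata,
            region=options.pop("region", None),
            region_key=options.pop("region_key", None),
            instance_key=options.pop("instance_key", None),
        )
    raise ElementError(f"unknown element kind {kind!r}")


# ---------------------------------------------------------------------------
# validation


@dataclasses.dataclass
class Violation:
    """A single invariant violation found during dataset validation."""

    kind: str
    where: str
    message: str

    def __str__(self):
        return f"[{self.kind}] {self.where}: {self.message}"


def validate_dataset(ds: SpatialDataset) -> list[Violation]:
    """Check all element invariants and table linkage; return violations.

    An empty list means every element is internally valid and every linked
    table row resolves to an existing instance of its target element.
    """
    out: list[Violation] = []
    names = [name for _, name, _ in ds.spatial_elements()]
    for name in {n for n in names if names.count(n) > 1}:
        out.append(Violation("container", name, "duplicate element name"))

    for name, img in ds.images.items():
        axes = img.axes
        try:
            validate_axes(axes)
        except ElementError as e:
            out.append(Violation("image", name, str(e)))
        if not img.transformations:
            out.append(Violation("image", name, "element has no transformations"))
        shapes = [lv.shape for lv in img.pyramid]
        for prev, cur in zip(shapes, shapes[1:]):
            if len(prev) != len(cur) or any(c > p for c, p in zip(cur, prev)):
                out.append(Violation("image", name, f"pyramid level grows: {prev} -> {cur}"))
    for name, lab in ds.labels.items():
        data = np.asarray(lab.data)
        if not np.issubdtype(data.dtype, np.integer):
            out.append(Violation("labels", name, f"non-integer dtype {data.dtype}"))
        elif data.size and data.min() < 0:
            out.append(Violation("labels", name, "negative label values"))
        if not lab.transformations:
            out.append(Violation("labels", name, "element has no transformations"))
    for name, pts in ds.points.items():
        coords = pts.coordinates
        if not np.all(np.isfinite(coords)):
            out.append(Violation("points", name, "non-finite coordinates"))
        if not pts.transformations:
            out.append(Violation("points", name, "element has no transformations"))
    for name, shp in ds.shapes.items():
        radii = shp.table["radius"].to_numpy(dtype=float)
        circ = np.isfinite(radii)
        if np.any(radii[circ] <= 0):
            out.append(Violation("shapes", name, "non-positive circle radius"))
        for iid, geom, is_c in zip(shp.table.index, shp.table["geometry"], circ):
            if not is_c:
                try:
                    _validate_polygon(geom)
                except ElementError as e:
                    out.append(Violation("shapes", name, f"instance {iid}: {e}"))
        if not shp.transformations:
            out.append(Violation("shapes", name, "element has no transformations"))

    # coordinate-system consistency: same name => same (spatial) axis set is
    # implied by the fixed global axis vocabulary; nothing further to check
    # until systems carry custom axes.

    for tname, table in ds.tables.items():
        keys = (table.region, table.region_key, table.instance_key)
        n_set = sum(k is not None for k in keys)
        if n_set not in (0, 3):
            out.append(
                Violation(
                    "table",
                    tname,
                    "region, region_key and instance_key must be all set or all absent",
                )
            )
            continue
        if n_set == 0:
            continue
        for key in (table.region_key, table.instance_key):
            if key not in table.obs.columns:
                out.append(Violation("table", tname, f"obs lacks column {key!r}"))
        if any(v.where == tname for v in out):
            continue
        regions = (
            table.region if isinstance(table.region, (list, tuple)) else [table.region]
        )
        for region in regions:
            try:
                element = ds.get_element(region)
            except KeyError:
                out.append(Violation("table", tname, f"annotated element {region!r} not found"))
                continue
            try:
                valid_ids = set(np.asarray(element_instance_ids(element)).tolist())
            except TypeError as e:
                out.append(Violation("table", tname, str(e)))
                continue
            rows = table.obs[table.obs[table.region_key].astype(str) == str(region)]
            for iid in rows[table.instance_key]:
                if iid not in valid_ids:
                    out.append(
                        Violation(
                            "table",
                            tname,
                            f"instance id {iid!r} not present in element {region!r}",
                        )
                    )
    return out


def match_table_to_element(
    ds: SpatialDataset, table_name: str, element_name: str
) -> AnnotationTable:
    """Restrict a table to one element's instances, in the element's order.

    Rows whose instance id is absent from the element are dropped; the
    surviving rows are reordered to match the element's instance order.
    """
    table = ds.tables[table_name]
    if not table.is_linked():
        raise ValueError(f"table {table_name!r} does not annotate any element")
    regions = table.region if isinstance(table.region, (list, tuple)) else [table.region]
    if element_name not in regions:
        raise ValueError(
            f"table {table_name!r} annotates {regions!r}, not {element_name!r}"
        )
    element = ds.get_element(element_name)
    ids = np.asarray(element_instance_ids(element))

    obs = table.obs
    mask = obs[table.region_key].astype(str) == str(element_name)
    id_to_pos = {iid: pos for pos, iid in zip(np.flatnonzero(mask.to_numpy()),
                                              obs.loc[mask, table.instance_key])}
    order = [id_to_pos[i] for i in ids.tolist() if i in id_to_pos]
    return table.subset(order)


# ---------------------------------------------------------------------------
# generic readers


def read_points_csv(
    path,
    x: str = "x",
    y: str = "y",
    z: str | None = None,
    sep: str = ",",
    categorical: list[str] | None = None,
    **options,
) -> Points:
    """Read a delimited text file into a Points element.

    ``x``/``y``/``z`` give the coordinate column names in the file; other
    columns are carried through as attributes.  Columns listed in
    ``categorical`` are converted to pandas categoricals.
    """
    df = pd.read_csv(path, sep=sep)
    rename = {x: "x", y: "y"}
    if z is not None:
        rename[z] = "z"
    df = df.rename(columns=rename)
    for col in categorical or []:
        df[col] = df[col].astype("category")
    return build_element("points", df, **options)


def read_shapes_geojson(path, **options) -> Shapes:
    """Read a GeoJSON feature collection into a Shapes element.

    Polygon/MultiPolygon features become polygon instances; a Point feature
    with a ``radius`` property becomes a circle.
    """
    import json

    with open(path) as fh:
        gj = json.load(fh)
    features = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    records = []
    for feat in features:
        geom = feat["geometry"]
        props = feat.get("properties") or {}
        if geom["type"] == "Point":
            if "radius" not in props:
                raise ElementError("circle Point feature needs a 'radius' property")
            records.append({"center": geom["coordinates"], "radius": props["radius"]})
        else:
            records.append({"geometry": shapely.geometry.shape(geom)})
    return build_element("shapes", records, **options)


def read_raster_file(path, kind: str = "image", **options):
    """Read a TIFF or .npy array file into an Image or Labels element."""
    import pathlib

    path = pathlib.Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        data = tifffile.imread(path)
    elif path.suffix.lower() == ".npy":
        data = np.load(path)
    else:
        raise ElementError(f"unsupported raster file type {path.suffix!r}")
    return build_element(kind, data, **options)
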