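"""Persist and load spatial datasets in a single hierarchical Zarr store.

Layout (Zarr v2 format, one directory per store)::

    root/                   .zattrs: {"format_version": ..., "generator": ...}
      images/<name>/        multiscale arrays "0", "1", ... + NGFF-style
      labels/<name>/          "multiscales" metadata; our transformations in
                              the extension attr "coordinate_transformations"
      points/<name>/        points.parquet (coordinates + attributes,
                              categoricals preserved)
      shapes/<name>/        geometry.parquet (WKB polygons; circles as typed
                              center/radius records, never polygonized)
      tables/<name>/        X (dense array or CSR triplet group), layers/,
                              obs.parquet, var.parquet; linkage keys in attrs

Raster metadata follows the OME-NGFF multiscales vocabulary (axes plus
scale/translation coordinate transformations per level) so NGFF-aware
readers can open the raster groups; the per-coordinate-system transformation
mapping — which may contain affines that core NGFF cannot encode — lives in
a separate extension attribute that strict readers simply ignore.

Raster payloads are read lazily: :func:`read_store` with ``lazy=True``
returns elements whose pyramid entries are zarr arrays, so listing elements,
reading vector data and all transformation metadata touches no raster
chunks.  Call ``element.materialize()`` (or ``np.asarray``) to load pixels.
"""

from __future__ import annotations

import pathlib
import shutil

import numpy as np
import pandas as pd
import shapely
import zarr
from zarr.storage import LocalStore

from . import elements as el
from .elements import AnnotationTable, SpatialDataset, validate_dataset
from .transforms import (
    Transformation,
    transformation_from_dict,
    transformation_to_dict,
)

__all__ = [
    "FORMAT_VERSION",
    "write_store",
    "read_store",
    "describe_store",
    "write_transformation",
    "ChunkCountingStore",
]

FORMAT_VERSION = "0.1"

#: chunk edge length along spatial axes (power of two, pyramid-friendly)
SPATIAL_CHUNK = 256

KINDS = ("images", "labels", "points", "shapes", "tables")


class StoreError(ValueError):
    pass


class ChunkCountingStore(LocalStore):
    """LocalStore that counts reads of raster chunk keys.

    Used to verify the lazy-loading contract: loading a store and listing
    its metadata must read zero chunks from the ``images/`` and ``labels/``
    groups (vector data and tables are small and read eagerly).
    """

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        object.__setattr__(self, "chunk_reads", 0)

    async def get(self, key, prototype, byte_range=None):
        base = key.rsplit("/", 1)[-1]
        is_metadata = base.startswith(".z") or base == "zarr.json"
        if not is_metadata and (key.startswith("images/") or key.startswith("labels/")):
            object.__setattr__(self, "chunk_reads", self.chunk_reads + 1)
        return await super().get(key, prototype, byte_range)


# ---------------------------------------------------------------------------
# writing


def _raster_chunks(shape, axes):
    return tuple(
        min(s, SPATIAL_CHUNK) if a in ("z", "y", "x") else s
        for s, a in zip(shape, axes)
    )


def _write_raster(group: zarr.Group, name: str, element, kind: str) -> None:
    g = group.create_group(name)
    axes = element.axes
    n_spatial = len(element.spatial_axes)
    datasets = []
    for lvl, arr in enumerate(element.pyramid):
        arr = np.asarray(arr)
        z = g.create_array(
            str(lvl), shape=arr.shape, dtype=arr.dtype, chunks=_raster_chunks(arr.shape, axes)
        )
        z[...] = arr
        scale = [1.0] * (len(axes) - n_spatial) + [float(2**lvl)] * n_spatial
        datasets.append(
            {"path": str(lvl), "coordinateTransformations": [{"type": "scale", "scale": scale}]}
        )
    g.attrs.update(
        {
            "element_kind": kind,
            "axes": list(axes),
            "multiscales": [
                {
                    "version": "0.4",
                    "name": name,
                    "axes": [
                        {"name": a, "type": "channel" if a == "c" else "space"}
                        for a in axes
                    ],
                    "datasets": datasets,
                }
            ],
            "coordinate_transformations": {
                cs: transformation_to_dict(t) for cs, t in element.transformations.items()
            },
        }
    )


def _element_dir(root_path: pathlib.Path, kind: str, name: str) -> pathlib.Path:
    return root_path / kind / name


def _write_points(group: zarr.Group, root_path, name: str, element: el.Points) -> None:
    g = group.create_group(name)
    g.attrs.update(
        {
            "element_kind": "points",
            "coordinate_columns": list(element.coordinate_axes),
            "coordinate_transformations": {
                cs: transformation_to_dict(t) for cs, t in element.transformations.items()
            },
        }
    )
    element.records.to_parquet(_element_dir(root_path, "points", name) / "points.parquet")


def _write_shapes(group: zarr.Group, root_path, name: str, element: el.Shapes) -> None:
    g = group.create_group(name)
    g.attrs.update(
        {
            "element_kind": "shapes",
            "coordinate_transformations": {
                cs: transformation_to_dict(t) for cs, t in element.transformations.items()
            },
        }
    )
    kinds, wkbs, cx, cy, radii = [], [], [], [], []
    for geom, radius in zip(element.table["geometry"], element.table["radius"]):
        if np.isfinite(radius):
            kinds.append("circle")
            wkbs.append(None)
            cx.append(geom.x)
            cy.append(geom.y)
            radii.append(float(radius))
        else:
            kinds.append(geom.geom_type.lower())
            wkbs.append(shapely.to_wkb(geom))
            cx.append(np.nan)
            cy.append(np.nan)
            radii.append(np.nan)
    df = pd.DataFrame(
        {"kind": kinds, "wkb": wkbs, "cx": cx, "cy": cy, "radius": radii},
        index=element.table.index,
    )
    for col in element.table.columns:
        if col not in ("geometry", "radius"):
            df[col] = element.table[col]
    df.to_parquet(_element_dir(root_path, "shapes", name) / "geometry.parquet")


def _write_table(group: zarr.Group, root_path, name: str, table: AnnotationTable) -> None:
    import scipy.sparse as sp

    g = group.create_group(name)
    g.attrs.update(
        {
            "element_kind": "table",
            "region": table.region,
            "region_key": table.region_key,
            "instance_key": table.instance_key,
        }
    )

    def write_matrix(parent: zarr.Group, key: str, X) -> None:
        if sp.issparse(X):
            X = sp.csr_matrix(X)
            mg = parent.create_group(key)
            mg.attrs.update({"encoding": "csr", "shape": list(X.shape)})
            for part in ("data", "indices", "indptr"):
                arr = np.asarray(getattr(X, part))
                z = mg.create_array(part, shape=arr.shape, dtype=arr.dtype)
                z[...] = arr
        else:
            X = np.asarray(X)
            z = parent.create_array(key, shape=X.shape, dtype=X.dtype)
            z[...] = X

    write_matrix(g, "X", table.X)
    if len(table.layers):
        lg = g.create_group("layers")
        for lname, mat in table.layers.items():
            write_matrix(lg, lname, mat)
    tdir = _element_dir(root_path, "tables", name)
    table.obs.to_parquet(tdir / "obs.parquet")
    table.var.to_parquet(tdir / "var.parquet")


def write_store(ds: SpatialDataset, path, overwrite: bool = False) -> pathlib.Path:
    """Write a validated dataset to a Zarr v2 store at ``path``.

    Each element is written atomically: a failure while writing one element
    removes its partially written group, leaving the rest of the store
    consistent.
    """
    violations = validate_dataset(ds)
    if violations:
        raise StoreError(
            "dataset fails validation: " + "; ".join(str(v) for v in violations)
        )
    path = pathlib.Path(path)
    if path.exists():
        if not overwrite:
            raise StoreError(f"{path} exists; pass overwrite=True to replace it")
        shutil.rmtree(path)
    root = zarr.open_group(str(path), mode="w", zarr_format=2)
    root.attrs.update({"format_version": FORMAT_VERSION, "generator": "spatialkit"})

    writers = {
        "images": lambda grp, nm, elem: _write_raster(grp, nm, elem, "image"),
        "labels": lambda grp, nm, elem: _write_raster(grp, nm, elem, "labels"),
        "points": lambda grp, nm, elem: _write_points(grp, path, nm, elem),
        "shapes": lambda grp, nm, elem: _write_shapes(grp, path, nm, elem),
        "tables": lambda grp, nm, elem: _write_table(grp, path, nm, elem),
    }
    for kind in KINDS:
        members = getattr(ds, kind)
        if not members:
            continue
        kgroup = root.create_group(kind)
        for name, element in members.items():
            try:
                writers[kind](kgroup, name, element)
            except Exception:
                edir = _element_dir(path, kind, name)
                if edir.exists():
                    shutil.rmtree(edir)
                raise
    return path


def append_table(path, name: str, table: AnnotationTable, overwrite: bool = False) -> None:
    """Add (or replace) one annotation table in an existing store."""
    path = pathlib.Path(path)
    root = zarr.open_group(str(path), mode="r+")
    if "tables" not in root:
        root.create_group("tables")
    tg = root["tables"]
    if name in tg:
        if not overwrite:
            raise StoreError(f"table {name!r} already exists; pass overwrite=True")
        shutil.rmtree(_element_dir(path, "tables", name))
        tg = zarr.open_group(str(path), mode="r+")["tables"]
    try:
        _write_table(tg, path, name, table)
    except Exception:
        edir = _element_dir(path, "tables", name)
        if edir.exists():
            shutil.rmtree(edir)
        raise


def write_transformation(path, kind: str, name: str, system: str, t: Transformation) -> None:
    """Persist one element's transformation into an existing store's metadata."""
    root = zarr.open_group(str(path), mode="r+")
    g = root[f"{kind}/{name}"]
    mapping = dict(g.attrs.get("coordinate_transformations", {}))
    mapping[str(system)] = transformation_to_dict(t)
    g.attrs["coordinate_transformations"] = mapping


# ---------------------------------------------------------------------------
# reading


def _read_transformations(attrs) -> dict[str, Transformation]:
    return {
        cs: transformation_from_dict(d)
        for cs, d in dict(attrs.get("coordinate_transformations", {})).items()
    }


def _read_raster(g: zarr.Group, kind: str, lazy: bool):
    levels = sorted((k for k in g.array_keys()), key=int)
    pyramid = [g[k] if lazy else np.asarray(g[k][...]) for k in levels]
    axes = tuple(g.attrs["axes"])
    cls = el.Image if kind == "images" else el.Labels
    return cls(pyramid=pyramid, axes=axes, transformations=_read_transformations(g.attrs))


def _read_points(g: zarr.Group, pdir: pathlib.Path) -> el.Points:
    records = pd.read_parquet(pdir / "points.parquet")
    return el.Points(records=records, transformations=_read_transformations(g.attrs))


def _read_shapes(g: zarr.Group, sdir: pathlib.Path) -> el.Shapes:
    df = pd.read_parquet(sdir / "geometry.parquet")
    geoms, radii = [], []
    for _, row in df.iterrows():
        if row["kind"] == "circle":
            geoms.append(shapely.Point(row["cx"], row["cy"]))
            radii.append(float(row["radius"]))
        else:
            geoms.append(shapely.from_wkb(row["wkb"]))
            radii.append(float("nan"))
    table = pd.DataFrame({"geometry": geoms, "radius": radii}, index=df.index)
    for col in df.columns:
        if col not in ("kind", "wkb", "cx", "cy", "radius"):
            table[col] = df[col]
    return el.Shapes(table=table, transformations=_read_transformations(g.attrs))


def _read_matrix(node):
    import scipy.sparse as sp

    if isinstance(node, zarr.Group):
        shape = tuple(node.attrs["shape"])
        return sp.csr_matrix(
            (node["data"][...], node["indices"][...], node["indptr"][...]), shape=shape
        )
    return np.asarray(node[...])


def _read_table(g: zarr.Group, tdir: pathlib.Path) -> AnnotationTable:
    from anndata import AnnData

    obs = pd.read_parquet(tdir / "obs.parquet")
    var = pd.read_parquet(tdir / "var.parquet")
    X = _read_matrix(g["X"])
    layers = {}
    if "layers" in g:
        lg = g["layers"]
        for k in list(lg.array_keys()) + list(lg.group_keys()):
            layers[k] = _read_matrix(lg[k])
    adata = AnnData(X=X, obs=obs, var=var, layers=layers)
    return AnnotationTable(
        adata,
        region=g.attrs.get("region"),
        region_key=g.attrs.get("region_key"),
        instance_key=g.attrs.get("instance_key"),
    )


def _open_root(path, store=None, mode: str = "r") -> tuple[zarr.Group, pathlib.Path]:
    path = pathlib.Path(path)
    if not path.exists():
        raise StoreError(f"no store at {path}")
    root = zarr.open_group(store if store is not None else str(path), mode=mode)
    if "format_version" not in root.attrs:
        raise StoreError(f"store at {path} is missing the root 'format_version' marker")
    return root, path


def read_store(path, lazy: bool = True, store=None) -> SpatialDataset:
    """Load a store back into a :class:`SpatialDataset`.

    With ``lazy=True`` (default) raster pyramids stay on disk as zarr
    arrays and no raster chunk is read; pass ``store`` (e.g. a
    :class:`ChunkCountingStore`) to drive reads through an instrumented
    store.
    """
    root, path = _open_root(path, store=store)
    ds = SpatialDataset()
    for kind in KINDS:
        if kind not in root:
            continue
        kgroup = root[kind]
        for name in sorted(kgroup.group_keys()):
            g = kgroup[name]
            ekind = g.attrs.get("element_kind")
            if kind in ("images", "labels"):
                ds_kind = getattr(ds, kind)
                ds_kind[name] = _read_raster(g, kind, lazy)
            elif kind == "points":
                ds.points[name] = _read_points(g, _element_dir(path, kind, name))
            elif kind == "shapes":
                ds.shapes[name] = _read_shapes(g, _element_dir(path, kind, name))
            elif kind == "tables":
                ds.tables[name] = _read_table(g, _element_dir(path, kind, name))
            else:  # pragma: no cover - unreachable with KINDS fixed
                raise StoreError(f"unknown element kind {ekind!r}")
    return ds


def describe_store(path, store=None) -> dict:
    """Summarize a store without touching raster chunks.

    Returns element names, kinds, array shapes / row counts, coordinate
    systems and pyramid level counts.
    """
    import pyarrow.parquet as pq

    root, path = _open_root(path, store=store)
    summary: dict = {"path": str(path), "format_version": root.attrs["format_version"], "elements": []}
    for kind in KINDS:
        if kind not in root:
            continue
        kgroup = root[kind]
        for name in sorted(kgroup.group_keys()):
            g = kgroup[name]
            entry: dict = {"kind": kind[:-1] if kind != "labels" else "labels", "name": name}
            if kind in ("images", "labels"):
                levels = sorted(g.array_keys(), key=int)
                entry["shape"] = list(g[levels[0]].shape)
                entry["pyramid_levels"] = len(levels)
                entry["axes"] = list(g.attrs["axes"])
            elif kind == "points":
                f = pq.ParquetFile(_element_dir(path, kind, name) / "points.parquet")
                entry["rows"] = f.metadata.num_rows
            elif kind == "shapes":
                f = pq.ParquetFile(_element_dir(path, kind, name) / "geometry.parquet")
                entry["rows"] = f.metadata.num_rows
            else:
                f = pq.ParquetFile(_element_dir(path, kind, name) / "obs.parquet")
                entry["rows"] = f.metadata.num_rows
                entry["region"] = g.attrs.get("region")
            if kind != "tables":
                entry["coordinate_systems"] = sorted(
                    dict(g.attrs.get("coordinate_transformations", {}))
                )
            summary["elements"].append(entry)
    return summary
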