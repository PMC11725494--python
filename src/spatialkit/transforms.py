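"""Coordinate transformations and named coordinate systems.

A :class:`Transformation` is an algebraic object mapping an element's
intrinsic coordinates into a named coordinate system (a common coordinate
system, CCS, when several elements share it).  Five variants are provided:
identity, per-axis scale, per-axis translation, general homogeneous affine,
and a sequence (composite) of transformations.

All transformations are defined over *named* axes (``c``, ``z``, ``y``,
``x``), never positionally: an axis a transformation does not mention passes
through unchanged, so e.g. a 2D transform over (y, x) applies cleanly to a
(c, y, x) image.

Order convention
----------------
Members of a :class:`Sequence` apply **left to right**: the first listed
transformation acts first.  Equivalently ``compose(f, g)`` maps ``p`` to
``g(f(p))`` and its matrix is ``M_g @ M_f``.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence as TySequence

import numpy as np

__all__ = [
    "Transformation",
    "Identity",
    "Scale",
    "Translation",
    "Affine",
    "Sequence",
    "CoordinateSystem",
    "to_affine_matrix",
    "compose",
    "invert",
    "transform_vector_element",
    "transform_raster",
    "assign_transformation",
    "transformation_to_dict",
    "transformation_from_dict",
]

#: determinant magnitude below which a linear part is treated as singular
SINGULAR_DET = 1e-12


class TransformationError(ValueError):
    """Raised for axis mismatches, singular transforms and malformed input."""


class Transformation:
    """Base class for all transformation variants."""

    def to_matrix(self, axes: TySequence[str]) -> np.ndarray:
        """Homogeneous ``(d+1, d+1)`` matrix of this transformation on ``axes``.

        Axes the transformation does not touch pass through unchanged.
        """
        raise NotImplementedError

    def inverse(self) -> "Transformation":
        raise NotImplementedError

    def apply(self, coords: np.ndarray, axes: TySequence[str]) -> np.ndarray:
        """Map an ``(n, d)`` coordinate array expressed on ``axes``."""
        coords = np.asarray(coords, dtype=float)
        m = self.to_matrix(axes)
        d = len(axes)
        return coords @ m[:d, :d].T + m[:d, d]

    def __eq__(self, other):
        if not isinstance(other, Transformation):
            return NotImplemented
        axes = sorted(set(self._touched_axes()) | set(other._touched_axes())) or ["x", "y"]
        return np.allclose(self.to_matrix(axes), other.to_matrix(axes), atol=1e-12)

    def _touched_axes(self) -> tuple[str, ...]:
        return ()


class Identity(Transformation):
    """Maps every point to itself on any axes."""

    def to_matrix(self, axes):
        return np.eye(len(axes) + 1)

    def inverse(self):
        return Identity()

    def __repr__(self):
        return "Identity()"


class Scale(Transformation):
    """Per-axis multiplicative scaling, e.g. ``Scale({"x": 2, "y": 2})``."""

    def __init__(self, factors: Mapping[str, float]):
        self.factors = {str(a): float(v) for a, v in factors.items()}
        if any(v == 0 for v in self.factors.values()):
            raise TransformationError("scale factors must be nonzero")

    def to_matrix(self, axes):
        m = np.eye(len(axes) + 1)
        for i, a in enumerate(axes):
            m[i, i] = self.factors.get(a, 1.0)
        return m

    def inverse(self):
        return Scale({a: 1.0 / v for a, v in self.factors.items()})

    def _touched_axes(self):
        return tuple(self.factors)

    def __repr__(self):
        return f"Scale({self.factors})"


class Translation(Transformation):
    """Per-axis additive offset, e.g. ``Translation({"x": 5, "y": 7})``."""

    def __init__(self, offsets: Mapping[str, float]):
        self.offsets = {str(a): float(v) for a, v in offsets.items()}

    def to_matrix(self, axes):
        m = np.eye(len(axes) + 1)
        for i, a in enumerate(axes):
            m[i, -1] = self.offsets.get(a, 0.0)
        return m

    def inverse(self):
        return Translation({a: -v for a, v in self.offsets.items()})

    def _touched_axes(self):
        return tuple(self.offsets)

    def __repr__(self):
        return f"Translation({self.offsets})"


class Affine(Transformation):
    """General homogeneous affine over explicit input and output axes.

    ``matrix`` is ``(d_out + 1, d_in + 1)`` with last row ``(0, ..., 0, 1)``.
    """

    def __init__(self, matrix, input_axes: TySequence[str], output_axes: TySequence[str]):
        self.matrix = np.asarray(matrix, dtype=float)
        self.input_axes = tuple(input_axes)
        self.output_axes = tuple(output_axes)
        d_out, d_in = len(self.output_axes), len(self.input_axes)
        if self.matrix.shape != (d_out + 1, d_in + 1):
            raise TransformationError(
                f"affine matrix shape {self.matrix.shape} does not match axes "
                f"({d_out + 1}, {d_in + 1})"
            )
        expected_last = np.zeros(d_in + 1)
        expected_last[-1] = 1.0
        if not np.allclose(self.matrix[-1], expected_last, atol=1e-12):
            raise TransformationError("affine last row must be (0, ..., 0, 1)")

    @classmethod
    def from_linear(cls, linear, translation, axes: TySequence[str]) -> "Affine":
        """Build a square affine on ``axes`` from a linear part and offset."""
        d = len(axes)
        m = np.eye(d + 1)
        m[:d, :d] = np.asarray(linear, dtype=float)
        m[:d, d] = np.asarray(translation, dtype=float)
        return cls(m, axes, axes)

    def to_matrix(self, axes):
        d = len(axes)
        m = np.eye(d + 1)
        for i, a in enumerate(axes):
            if a not in self.output_axes:
                continue  # pass-through row
            r = self.output_axes.index(a)
            row = np.zeros(d + 1)
            for c_in, ax_in in enumerate(self.input_axes):
                coeff = self.matrix[r, c_in]
                if coeff == 0.0:
                    continue
                if ax_in not in axes:
                    raise TransformationError(
                        f"affine output axis {a!r} needs input axis {ax_in!r}, "
                        f"absent from requested axes {tuple(axes)}"
                    )
                row[axes.index(ax_in)] = coeff
            row[d] = self.matrix[r, -1]
            m[i] = row
        return m

    def inverse(self):
        d = len(self.input_axes)
        lin = self.matrix[:-1, :-1]
        if lin.shape[0] != lin.shape[1] or abs(np.linalg.det(lin)) < SINGULAR_DET:
            raise TransformationError("affine transformation is singular; cannot invert")
        inv = np.linalg.inv(self.matrix)
        inv[-1] = 0.0
        inv[-1, -1] = 1.0
        return Affine(inv, self.output_axes, self.input_axes)

    def _touched_axes(self):
        return tuple(dict.fromkeys(self.input_axes + self.output_axes))

    def __repr__(self):
        return f"Affine({self.matrix.tolist()}, {self.input_axes}, {self.output_axes})"


class Sequence(Transformation):
    """Composite transformation; members apply left-to-right."""

    def __init__(self, transformations: Iterable[Transformation]):
        self.transformations = list(transformations)
        if not self.transformations:
            raise TransformationError("sequence must be non-empty")
        for t in self.transformations:
            if not isinstance(t, Transformation):
                raise TransformationError(f"not a Transformation: {t!r}")

    def to_matrix(self, axes):
        m = np.eye(len(axes) + 1)
        for t in self.transformations:
            m = t.to_matrix(axes) @ m
        return m

    def inverse(self):
        return Sequence([t.inverse() for t in reversed(self.transformations)])

    def _touched_axes(self):
        out: dict[str, None] = {}
        for t in self.transformations:
            out.update(dict.fromkeys(t._touched_axes()))
        return tuple(out)

    def __repr__(self):
        return f"Sequence({self.transformations!r})"


class CoordinateSystem:
    """A named coordinate frame with ordered spatial axes."""

    def __init__(self, name: str, axes: TySequence[str] = ("y", "x")):
        self.name = str(name)
        self.axes = tuple(axes)
        if any(a not in ("z", "y", "x") for a in self.axes):
            raise TransformationError("coordinate systems have spatial axes only")

    def __repr__(self):
        return f"CoordinateSystem({self.name!r}, axes={self.axes})"

    def __eq__(self, other):
        return (
            isinstance(other, CoordinateSystem)
            and self.name == other.name
            and self.axes == other.axes
        )


# ---------------------------------------------------------------------------
# module-level operations


def to_affine_matrix(t: Transformation, axes: TySequence[str]) -> np.ndarray:
    """Homogeneous matrix of ``t`` acting on the ordered ``axes``."""
    return t.to_matrix(list(axes))


def compose(first: Transformation, second: Transformation) -> Transformation:
    """Transformation applying ``first`` then ``second``: ``p -> second(first(p))``."""
    members: list[Transformation] = []
    for t in (first, second):
        if isinstance(t, Sequence):
            members.extend(t.transformations)
        else:
            members.append(t)
    return Sequence(members)


def invert(t: Transformation) -> Transformation:
    """Inverse transformation; raises for singular linear parts."""
    return t.inverse()


def _linear_part(t: Transformation, axes: TySequence[str]) -> np.ndarray:
    m = t.to_matrix(list(axes))
    return m[:-1, :-1]


def _radius_factor(t: Transformation, axes: TySequence[str]) -> float:
    """Geometric mean of the absolute singular values of the linear part.

    Conserves area/volume: a circle of radius r maps to radius r' with
    pi r'^2 = |det| pi r^2 in 2D.
    """
    lin = _linear_part(t, axes)
    s = np.linalg.svd(lin, compute_uv=False)
    if np.any(s <= 0):
        raise TransformationError("singular transformation: cannot scale radii")
    return float(np.exp(np.mean(np.log(s))))


def transform_vector_element(element, t: Transformation):
    """Map a Points or Shapes element through ``t``.

    Point coordinates and polygon vertices are mapped exactly; circle centers
    are mapped and radii multiplied by the geometric mean of the singular
    values of the linear part.  Instance ids and attribute columns are
    preserved verbatim.  The result's transformations mapping is reset to
    identity into "global" (the caller re-assigns systems as needed).
    """
    from . import elements as _el
    import shapely
    import shapely.affinity

    if isinstance(element, _el.Points):
        axes = element.coordinate_axes
        coords = element.records[list(axes)].to_numpy(dtype=float)
        mapped = t.apply(coords, axes)
        records = element.records.copy()
        for i, a in enumerate(axes):
            records[a] = mapped[:, i]
        return _el.Points(records=records, transformations={"global": Identity()})
    if isinstance(element, _el.Shapes):
        axes = ("x", "y")
        m = t.to_matrix(axes)
        a, b, xoff = m[0]
        d, e, yoff = m[1]
        factor = _radius_factor(t, axes)
        geoms = []
        radii = []
        for geom, radius in zip(element.geometry, element.radius):
            geoms.append(shapely.affinity.affine_transform(geom, [a, b, d, e, xoff, yoff]))
            radii.append(radius * factor if np.isfinite(radius) else radius)
        table = element.table.copy()
        table["geometry"] = geoms
        table["radius"] = radii
        return _el.Shapes(table=table, transformations={"global": Identity()})
    raise TypeError(f"transform_vector_element expects Points or Shapes, got {type(element)}")


def transform_raster(
    element,
    t: Transformation,
    output_extent: Mapping[str, tuple[float, float]],
    interpolation: str = "linear",
    frame: str = "global",
):
    """Resample a raster element through ``t`` onto a pixel grid.

    The output grid covers ``output_extent`` (per spatial axis, in the frame
    ``t`` maps into) with unit pixels; the output pixel whose center is ``c``
    takes the value sampled at ``invert(t)(c)`` in the input (inverse
    mapping).  Out-of-bounds samples fill with 0.  Labels force nearest
    interpolation.  Pixel (i, j) occupies [i, i+1) x [j, j+1); its center is
    (i + 0.5, j + 0.5).
    """
    from . import elements as _el
    from scipy import ndimage

    if isinstance(element, _el.Labels):
        interpolation = "nearest"
    if interpolation not in ("nearest", "linear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")

    spatial = element.spatial_axes
    t_inv = invert(t)
    m_inv = t_inv.to_matrix(spatial)
    d = len(spatial)

    lows = np.array([output_extent[a][0] for a in spatial], dtype=float)
    highs = np.array([output_extent[a][1] for a in spatial], dtype=float)
    sizes = np.maximum(np.ceil(highs - lows - 1e-9).astype(int), 0)
    if np.any(sizes <= 0):
        raise ValueError("output extent must be positive along every spatial axis")

    # output pixel centers in the target frame, shape (d, *sizes)
    grids = np.meshgrid(
        *[lows[i] + np.arange(sizes[i]) + 0.5 for i in range(d)], indexing="ij"
    )
    centers = np.stack([g.ravel() for g in grids])  # (d, n)
    src = m_inv[:d, :d] @ centers + m_inv[:d, d:]  # intrinsic coordinates
    # intrinsic coordinate -> array index: index i covers [i, i+1), center i+0.5
    idx = src - 0.5

    data = np.asarray(element.data)

    def sample_nearest(plane: np.ndarray) -> np.ndarray:
        # nearest = the input pixel whose half-open square contains the
        # inverse-mapped point, i.e. floor of the intrinsic coordinate
        j = np.floor(src).astype(int)
        shape = np.asarray(plane.shape)
        valid = np.all((j >= 0) & (j < shape[:, None]), axis=0)
        out = np.zeros(src.shape[1], dtype=plane.dtype)
        out[valid] = plane[tuple(j[:, valid])]
        return out.reshape(sizes)

    if isinstance(element, _el.Labels):
        out = sample_nearest(data)
        return element.replace(
            pyramid=[out],
            transformations={frame: Translation(dict(zip(spatial, lows)))},
        )
    # Image: apply per channel over the leading non-spatial axes
    lead = data.shape[: data.ndim - d]
    flat = data.reshape((-1,) + data.shape[data.ndim - d:])
    if interpolation == "nearest":
        chans = [sample_nearest(c) for c in flat]
    else:
        chans = [
            ndimage.map_coordinates(
                c.astype(float), idx, order=1, mode="constant", cval=0.0
            ).reshape(sizes)
            for c in flat
        ]
    out = np.stack(chans).reshape(lead + tuple(sizes))
    return element.replace(
        pyramid=[out],
        transformations={frame: Translation(dict(zip(spatial, lows)))},
    )


def assign_transformation(
    element,
    system: str,
    t: Transformation,
    write_back: bool = False,
    store_path=None,
    kind: str | None = None,
    name: str | None = None,
):
    """Set ``element``'s transformation into coordinate system ``system``.

    With ``write_back`` the change is also persisted into the element's group
    metadata of an existing store at ``store_path`` (requires ``kind`` and
    ``name`` to locate the element group).
    """
    element.transformations[str(system)] = t
    if write_back:
        if store_path is None or kind is None or name is None:
            raise ValueError("write_back requires store_path, kind and name")
        from . import storage

        storage.write_transformation(store_path, kind, name, system, t)
    return element


# ---------------------------------------------------------------------------
# serialization (storage metadata dialect, NGFF-style vocabulary)


def transformation_to_dict(t: Transformation) -> dict:
    if isinstance(t, Identity):
        return {"type": "identity"}
    if isinstance(t, Scale):
        axes = sorted(t.factors)
        return {"type": "scale", "axes": axes, "scale": [t.factors[a] for a in axes]}
    if isinstance(t, Translation):
        axes = sorted(t.offsets)
        return {
            "type": "translation",
            "axes": axes,
            "translation": [t.offsets[a] for a in axes],
        }
    if isinstance(t, Affine):
        return {
            "type": "affine",
            "input_axes": list(t.input_axes),
            "output_axes": list(t.output_axes),
            "matrix": t.matrix.tolist(),
        }
    if isinstance(t, Sequence):
        return {
            "type": "sequence",
            "transformations": [transformation_to_dict(m) for m in t.transformations],
        }
    raise TypeError(f"cannot serialize {type(t)}")


def transformation_from_dict(d: Mapping) -> Transformation:
    kind = d["type"]
    if kind == "identity":
        return Identity()
    if kind == "scale":
        return Scale(dict(zip(d["axes"], d["scale"])))
    if kind == "translation":
        return Translation(dict(zip(d["axes"], d["translation"])))
    if kind == "affine":
        return Affine(np.asarray(d["matrix"]), d["input_axes"], d["output_axes"])
    if kind == "sequence":
        return Sequence([transformation_from_dict(m) for m in d["transformations"]])
    raise ValueError(f"unknown transformation type {kind!r}")
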