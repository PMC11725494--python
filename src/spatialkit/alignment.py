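"""Landmark-based estimation of affine/similarity transforms.

Landmarks are corresponding points picked in two datasets (e.g. the same
anatomical feature visible in two consecutive tissue sections).  The two
sets must be of equal length and order-matched: the i-th moving landmark
corresponds to the i-th reference landmark.

Two models are offered:

* ``affine`` — ordinary least squares on homogeneous coordinates,
  minimizing sum_i ||A m_i - r_i||^2.  Needs >= 3 non-collinear pairs in 2D
  (>= 4 non-coplanar in 3D); allows shear, which occurs between consecutive
  tissue sections.
* ``similarity`` — rotation + isotropic scale + translation via the
  orthogonal-Procrustes closed form (Umeyama).  Reflections are forbidden
  by default (tissue sections are not mirrored by imaging) and can be
  allowed explicitly.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence as TySequence

import numpy as np

from .elements import SpatialDataset
from .transforms import Affine, Transformation, compose

__all__ = [
    "LandmarkSet",
    "estimate_transform_from_landmarks",
    "align_elements_using_landmarks",
    "read_landmarks",
    "write_landmarks",
]

#: singular-value tolerance below which a landmark configuration is degenerate
RANK_TOL = 1e-10


class AlignmentError(ValueError):
    """Raised for degenerate, mismatched or insufficient landmark sets."""


@dataclasses.dataclass
class LandmarkSet:
    """Ordered landmark coordinates expressed in a named coordinate system."""

    points: np.ndarray  # (n, 2) or (n, 3)
    frame: str = "global"

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] not in (2, 3):
            raise AlignmentError("landmarks must be an (n, 2) or (n, 3) array")
        if self.points.shape[0] < 1:
            raise AlignmentError("need at least one landmark")
        if not np.all(np.isfinite(self.points)):
            raise AlignmentError("landmark coordinates must be finite")

    @property
    def ndim(self) -> int:
        return self.points.shape[1]

    def __len__(self) -> int:
        return self.points.shape[0]


def _check_pair(moving: LandmarkSet, reference: LandmarkSet, model: str) -> None:
    if len(moving) != len(reference):
        raise AlignmentError(
            f"landmark sets differ in size: {len(moving)} vs {len(reference)}"
        )
    if moving.ndim != reference.ndim:
        raise AlignmentError("landmark sets differ in dimensionality")
    d = moving.ndim
    minimum = d + 1 if model == "affine" else 2
    if len(moving) < minimum:
        raise AlignmentError(
            f"{model} estimation in {d}D needs at least {minimum} landmark pairs, "
            f"got {len(moving)}"
        )


def _fit_affine(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    n, d = src.shape
    design = np.hstack([src, np.ones((n, 1))])
    s = np.linalg.svd(design, compute_uv=False)
    if s[-1] < RANK_TOL * max(s[0], 1.0):
        raise AlignmentError(
            "degenerate landmark configuration (collinear/coplanar points); "
            "affine fit is rank-deficient"
        )
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    m = np.eye(d + 1)
    m[:d, :d] = coef[:d].T
    m[:d, d] = coef[d]
    return m


def _fit_similarity(src: np.ndarray, dst: np.ndarray, allow_reflection: bool) -> np.ndarray:
    # Umeyama closed form: R from the SVD of the cross-covariance, isotropic
    # scale from the trace, translation from the centroids.
    n, d = src.shape
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    xs, xd = src - mu_s, dst - mu_d
    var_s = (xs**2).sum() / n
    if var_s < RANK_TOL:
        raise AlignmentError("degenerate landmark configuration (coincident points)")
    cov = xd.T @ xs / n
    u, s, vt = np.linalg.svd(cov)
    sign = np.ones(d)
    if not allow_reflection and np.linalg.det(u @ vt) < 0:
        sign[-1] = -1.0
    rotation = u @ np.diag(sign) @ vt
    scale = float((s * sign).sum() / var_s)
    m = np.eye(d + 1)
    m[:d, :d] = scale * rotation
    m[:d, d] = mu_d - scale * rotation @ mu_s
    return m


def estimate_transform_from_landmarks(
    moving: LandmarkSet,
    reference: LandmarkSet,
    model: str = "affine",
    allow_reflection: bool = False,
) -> tuple[Transformation, float]:
    """Fit the transform mapping moving landmarks onto reference landmarks.

    Returns the fitted :class:`~spatialkit.transforms.Affine` (over axes
    ``(x, y)`` or ``(x, y, z)``) and the root-mean-square residual distance
    after fitting.
    """
    if model not in ("affine", "similarity"):
        raise AlignmentError(f"unknown model {model!r}")
    _check_pair(moving, reference, model)
    src, dst = moving.points, reference.points
    d = moving.ndim
    if model == "affine":
        m = _fit_affine(src, dst)
    else:
        m = _fit_similarity(src, dst, allow_reflection)
    axes = ("x", "y") if d == 2 else ("x", "y", "z")
    transform = Affine(m, axes, axes)
    residual = src @ m[:d, :d].T + m[:d, d] - dst
    rmsd = float(np.sqrt((residual**2).sum(axis=1).mean()))
    return transform, rmsd


def align_elements_using_landmarks(
    ds: SpatialDataset,
    moving_elements: TySequence[str],
    moving_landmarks: LandmarkSet,
    reference_landmarks: LandmarkSet,
    target_system: str = "aligned",
    model: str = "affine",
    allow_reflection: bool = False,
) -> SpatialDataset:
    """Register elements into ``target_system`` via matched landmarks.

    Each moving element must already have a transformation into the frame
    the moving landmarks are expressed in; it gains a transformation into
    ``target_system`` equal to that transformation composed with the
    estimated landmark transform.  The dataset is modified in place and
    returned.
    """
    estimated, _rmsd = estimate_transform_from_landmarks(
        moving_landmarks, reference_landmarks, model=model, allow_reflection=allow_reflection
    )
    frame = moving_landmarks.frame
    for name in moving_elements:
        element = ds.get_element(name)
        if frame not in element.transformations:
            raise AlignmentError(
                f"element {name!r} has no transformation into the landmarks' "
                f"frame {frame!r}"
            )
        element.transformations[target_system] = compose(
            element.transformations[frame], estimated
        )
    return ds


# ---------------------------------------------------------------------------
# landmark IO: delimited text (x,y[,z] per row) and GeoJSON point collections


def read_landmarks(path, frame: str = "global") -> LandmarkSet:
    """Read landmarks from CSV (columns x,y[,z]) or GeoJSON points."""
    import json
    import pathlib

    path = pathlib.Path(path)
    if path.suffix.lower() in (".json", ".geojson"):
        with open(path) as fh:
            gj = json.load(fh)
        feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
        pts = [f["geometry"]["coordinates"] for f in feats]
        return LandmarkSet(np.asarray(pts, dtype=float), frame=frame)
    import pandas as pd

    df = pd.read_csv(path)
    cols = ["x", "y"] + (["z"] if "z" in df.columns else [])
    return LandmarkSet(df[cols].to_numpy(dtype=float), frame=frame)


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    import pandas as pd

    cols = ["x", "y", "z"][: landmarks.ndim]
    pd.DataFrame(landmarks.points, columns=cols).to_csv(path, index=False)
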