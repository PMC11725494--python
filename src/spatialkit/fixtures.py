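"""Deterministic synthetic datasets for testing and demos.

:func:`generate_blobs` builds a complete toy spatial-omics dataset with the
same structure as an imaging-based transcriptomics experiment:

* an intensity image made of Gaussian "cell territory" bumps plus noise;
* a segmentation mask from thresholding the image at its 80th percentile;
* uniformly scattered points carrying a categorical feature whose spatial
  distribution follows the nearest bump (mimicking cell-type territories);
* circular capture locations on a hexagonal lattice (center-to-center
  spacing 2.4x the radius, echoing array-based capture geometry, so
  aggregation tests exercise partial overlaps) plus one bounding polygon
  per bump;
* an annotation table with per-segment mean intensity and category.

:func:`generate_aligned_pair` produces two replicas of such a dataset
related by a known invertible transform, together with matched landmark
sets — a desk-scale analog of registering two tissue sections.

All randomness flows from a single ``numpy.random.default_rng(seed)``; the
same seed reproduces every array bitwise.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

from . import elements as el
from .elements import SpatialDataset, build_element
from .transforms import Identity, Transformation, invert, transform_raster, transform_vector_element
from .alignment import LandmarkSet

__all__ = ["BlobsConfig", "generate_blobs", "generate_aligned_pair"]

#: labels are connected components above this intensity percentile
LABEL_PERCENTILE = 80.0

#: hexagonal lattice spacing as a multiple of the circle radius
LATTICE_SPACING = 2.4


@dataclasses.dataclass
class BlobsConfig:
    """Parameters of the synthetic dataset generator."""

    seed: int = 0
    image_shape: tuple[int, int] = (128, 128)
    n_blobs: int = 6
    n_points: int = 400
    n_categories: int = 3
    n_circles: int = 30
    noise_sd: float = 0.1

    def __post_init__(self):
        if min(self.image_shape) < 32:
            raise ValueError("image_shape must be >= 32 per axis")
        for field in ("n_blobs", "n_points", "n_categories", "n_circles"):
            if getattr(self, field) < 1:
                raise ValueError(f"{field} must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _blob_centers(cfg: BlobsConfig, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Jittered-grid blob centers (y, x) with guaranteed separation."""
    h, w = cfg.image_shape
    g = int(np.ceil(np.sqrt(cfg.n_blobs)))
    cell_h, cell_w = h / g, w / g
    cells = [(i, j) for i in range(g) for j in range(g)]
    chosen = rng.permutation(len(cells))[: cfg.n_blobs]
    centers = []
    for k in chosen:
        i, j = cells[k]
        cy = (i + 0.5) * cell_h + rng.uniform(-cell_h / 8, cell_h / 8)
        cx = (j + 0.5) * cell_w + rng.uniform(-cell_w / 8, cell_w / 8)
        centers.append((cy, cx))
    sigma = min(cell_h, cell_w) / 6.0
    return np.asarray(centers), sigma


def _hex_lattice(cfg: BlobsConfig) -> tuple[np.ndarray, float]:
    """First ``n_circles`` centers (x, y) of a hexagonal lattice, and radius."""
    h, w = cfg.image_shape
    # choose the radius so that roughly n_circles fit in the extent
    pitch = np.sqrt(w * h / cfg.n_circles / (np.sqrt(3) / 2))
    radius = pitch / LATTICE_SPACING
    dy = pitch * np.sqrt(3) / 2
    centers = []
    row = 0
    y = radius
    while y < h and len(centers) < cfg.n_circles:
        x0 = radius + (pitch / 2 if row % 2 else 0.0)
        x = x0
        while x < w and len(centers) < cfg.n_circles:
            centers.append((x, y))
            x += pitch
        y += dy
        row += 1
    return np.asarray(centers[: cfg.n_circles]), float(radius)


def generate_blobs(cfg: BlobsConfig | None = None, **overrides) -> SpatialDataset:
    """Build the deterministic synthetic dataset described in the module docs."""
    if cfg is None:
        cfg = BlobsConfig(**overrides)
    elif overrides:
        cfg = dataclasses.replace(cfg, **overrides)
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_shape
    centers, sigma = _blob_centers(cfg, rng)

    yy, xx = np.mgrid[0:h, 0:w]
    img = np.zeros((h, w), dtype=float)
    for cy, cx in centers:
        img += np.exp(-(((yy + 0.5) - cy) ** 2 + ((xx + 0.5) - cx) ** 2) / (2 * sigma**2))
    signal = img
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    image = build_element("image", img[np.newaxis], pyramid=True)

    from skimage import measure

    # threshold the noise-free intensity field: a segmentation mask should
    # outline the blob territories, not single-pixel noise excursions
    threshold = np.percentile(signal, LABEL_PERCENTILE)
    mask = signal > threshold
    labelled = measure.label(mask).astype(np.int32)
    labels = build_element("labels", labelled, pyramid=True)

    # points: uniform positions, category tied to the nearest blob territory
    px = rng.uniform(0, w, size=cfg.n_points)
    py = rng.uniform(0, h, size=cfg.n_points)
    d2 = (py[:, None] - centers[:, 0]) ** 2 + (px[:, None] - centers[:, 1]) ** 2
    nearest = d2.argmin(axis=1)
    cat_idx = nearest % cfg.n_categories
    if cfg.noise_sd > 0:
        flip = rng.uniform(size=cfg.n_points) < min(0.5, cfg.noise_sd)
        cat_idx = np.where(flip, rng.integers(0, cfg.n_categories, cfg.n_points), cat_idx)
    cat_names = [f"type_{chr(ord('A') + i)}" for i in range(cfg.n_categories)]
    records = pd.DataFrame(
        {
            "x": px,
            "y": py,
            "feature": pd.Categorical.from_codes(cat_idx, categories=cat_names),
        }
    )
    points = build_element("points", records)

    lattice, radius = _hex_lattice(cfg)
    circles = build_element(
        "shapes", [{"center": c, "radius": radius} for c in lattice]
    )
    half = 2.0 * sigma
    polys = []
    for cy, cx in centers:
        polys.append(
            shapely.box(
                max(cx - half, 0.0), max(cy - half, 0.0), min(cx + half, w), min(cy + half, h)
            )
        )
    blob_shapes = build_element("shapes", [{"geometry": p} for p in polys])

    ids = np.unique(labelled)
    ids = ids[ids != 0]
    mean_intensity = ndimage.mean(img, labels=labelled, index=ids)
    centroids = np.asarray(ndimage.center_of_mass(mask, labels=labelled, index=ids))
    d2c = (centroids[:, 0][:, None] - centers[:, 0]) ** 2 + (
        centroids[:, 1][:, None] - centers[:, 1]
    ) ** 2
    label_cat = d2c.argmin(axis=1) % cfg.n_categories
    obs = pd.DataFrame(
        {
            "region": pd.Categorical(["segmentation"] * len(ids)),
            "instance_id": ids.astype(int),
            "category": pd.Categorical.from_codes(label_cat, categories=cat_names),
        },
        index=[str(i) for i in ids],
    )
    var = pd.DataFrame(index=pd.Index(["mean_intensity"], name="variable"))
    table = build_element(
        "table",
        mean_intensity[:, None],
        obs=obs,
        var=var,
        region="segmentation",
        region_key="region",
        instance_key="instance_id",
    )

    return SpatialDataset(
        images={"image": image},
        labels={"segmentation": labels},
        points={"transcripts": points},
        shapes={"circles": circles, "blob_boundaries": blob_shapes},
        tables={"annotation": table},
    )


def blob_landmarks(cfg: BlobsConfig) -> np.ndarray:
    """Blob centers as (x, y) landmark coordinates, in generation order."""
    rng = np.random.default_rng(cfg.seed)
    centers, _ = _blob_centers(cfg, rng)
    return centers[:, ::-1].copy()  # (y, x) -> (x, y)


def generate_aligned_pair(
    cfg: BlobsConfig | None = None,
    true_transform: Transformation | None = None,
    **overrides,
) -> tuple[SpatialDataset, SpatialDataset, LandmarkSet, LandmarkSet]:
    """Two replicas of one ground truth related by a known transform.

    Returns ``(moving_ds, reference_ds, moving_landmarks,
    reference_landmarks)``: the reference dataset is the moving dataset with
    every vector element mapped through ``true_transform`` and rasters
    resampled through it, and the landmark sets are the blob centers
    expressed in each dataset's intrinsic frame (order-matched), so
    estimating the landmark transform recovers ``true_transform``.
    """
    if cfg is None:
        cfg = BlobsConfig(**overrides)
    elif overrides:
        cfg = dataclasses.replace(cfg, **overrides)
    if cfg.n_blobs < 3:
        raise ValueError("need >= 3 blobs to provide landmark pairs")
    if true_transform is None:
        true_transform = Identity()
    invert(true_transform)  # raises if singular

    moving = generate_blobs(cfg)
    reference = SpatialDataset()
    for kind, name, element in moving.spatial_elements():
        if kind in ("points", "shapes"):
            getattr(reference, kind)[name] = transform_vector_element(element, true_transform)
        else:
            h, w = cfg.image_shape
            m = true_transform.to_matrix(("y", "x"))
            corners = np.array([[0, 0], [0, w], [h, 0], [h, w]], dtype=float)
            mapped = corners @ m[:2, :2].T + m[:2, 2]
            extent = {
                "y": (np.floor(mapped[:, 0].min()), np.ceil(mapped[:, 0].max())),
                "x": (np.floor(mapped[:, 1].min()), np.ceil(mapped[:, 1].max())),
            }
            getattr(reference, kind)[name] = transform_raster(
                element, true_transform, extent,
                interpolation="nearest" if kind == "labels" else "linear",
            )
    for tname, table in moving.tables.items():
        reference.tables[tname] = table.subset(np.ones(table.n_obs, dtype=bool))

    lms = blob_landmarks(cfg)
    moving_landmarks = LandmarkSet(lms, frame="global")
    reference_landmarks = LandmarkSet(
        true_transform.apply(lms, ("x", "y")), frame="global"
    )
    return moving, reference, moving_landmarks, reference_landmarks
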