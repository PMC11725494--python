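# Methods

## Data model

A `SpatialDataset` is a named collection of five element kinds. Rasters
(`Image`, `Labels`) are dense arrays with explicit axis names drawn from
`(c, z, y, x)` in that fixed order; vector elements (`Points`, `Shapes`)
store coordinates as columns named `x, y[, z]`. The two conventions are
connected purely by axis *names*: every transformation is defined over
named axes, and any axis a transformation does not mention passes through
unchanged, so a 2D transform over `(y, x)` applies directly to a
`(c, y, x)` image. No operation ever matches axes positionally.

**Raster coordinate convention.** Pixel `(i, j)` occupies the half-open
square `[i, i+1) × [j, j+1)` in intrinsic `(y, x)` units; its center is
`(i + 0.5, j + 0.5)`. This makes scale transforms commute with pyramid
levels: halving the grid maps centers onto centers.

**Instance ids.** Labels use their nonzero pixel values (0 is reserved for
background, label ids are reported sorted); Shapes and Points use their row
index, preserved verbatim by every operation. These ids are what the
`(region, region_key, instance_key)` triple of an `AnnotationTable`
resolves against; `validate_dataset` returns a violation report for every
annotated id that does not exist in its target element, rather than
raising.

**Multiscale pyramids.** Optional, factor 2 per level, until the largest
spatial dimension falls below 64. Images are mean-pooled (exact block
means; trailing odd rows/columns are dropped first, so when dimensions are
powers of two the global mean is conserved exactly); label masks are
subsampled with stride 2, which can drop but never invent instance ids.

## Transformations and coordinate systems

Transformations are algebraic objects — identity, per-axis `Scale`,
per-axis `Translation`, homogeneous `Affine` with explicit input/output
axes, and `Sequence`. **Sequence members apply left to right**: the first
listed transformation acts first, `compose(f, g)(p) = g(f(p))`, and the
matrix of a sequence is the product of member matrices in reverse order.
This order is fixed by convention (nothing in the domain forces it) and is
asserted by tests.

Numerical choices: transform equality is checked at 1e-9; a linear part is
considered singular when |det| < 1e-12; inversion of `Scale`/`Translation`
is symbolic (exact), of `Affine` via `numpy.linalg.inv`.

**Circles under anisotropic maps.** The `Shapes` model has no ellipse, so a
circle mapped through a linear part L keeps its mapped center and takes
radius `r' = r · gm(σ(L))`, the geometric mean of L's singular values. This
conserves area (π r'² = |det L| π r²) and is exact for similarity
transforms. Consequence: overlap-based quantities involving circles are
exactly covariant under similarity transforms but only approximately under
shearing affines (a true circle would become an ellipse); polygon-only
aggregations are covariant under any invertible affine. The tests encode
exactly this split.

**Raster resampling** (`transform_raster`) uses inverse mapping: the output
pixel with center c takes the value at `t⁻¹(c)` in the input. "Nearest"
sampling takes the input pixel whose half-open square contains the point
(floor of the intrinsic coordinate) — implemented directly rather than with
a generic resampler, whose 0-order boundary rounding follows a different
convention. Linear interpolation uses `scipy.ndimage.map_coordinates`
(order 1); out-of-extent samples are 0 in both modes. Labels always
resample nearest.

## Landmark alignment

Landmark pairs are order-matched points picked in two datasets. The
`affine` model solves the homogeneous least-squares problem via
`numpy.linalg.lstsq`; the configuration is rejected as degenerate when the
smallest singular value of the design matrix `[x y 1]` is below 1e-10
relative (collinear points in 2D, coplanar in 3D). The `similarity` model
uses the orthogonal-Procrustes (Umeyama) closed form; the reflection branch
is disabled by default — consecutive tissue sections are not mirrored by
imaging — and can be enabled with `allow_reflection=True`. The reported
`rmsd` is the root-mean-square residual distance after the fit; for
Gaussian landmark noise of scale σ it concentrates around
σ·√(2·(1 − p/n)) with p = 3 fitted parameter columns in 2D.

`align_elements_using_landmarks` assigns, to each moving element, the
composition of its existing transformation into the landmarks' frame with
the estimated transform — the estimate is stored as a flat explicit affine.
The default model is affine (shear occurs between consecutive sections);
similarity is offered for rigid cases.

## Queries

Conventions, fixed once and globally: box membership for points and for
pixel centers is half-open per axis (`min ≤ v < max`); polygon membership
is closed (boundary points kept, even-odd rule); shapes survive on
*intersection* with the region (`mode="centroid"` switches to centroid
containment). Circle-versus-region tests use the exact center-distance
criterion (a circle meets a region iff the distance from its center to the
region is ≤ r), which is exact for both boxes and polygons.

Raster queries never interpolate. A bounding-box query inverse-transforms
the box corners, takes the axis-aligned intrinsic bounds, keeps the pixels
whose centers fall in `[lo, hi)`, and records the crop offset by composing
a translation into the element's transformation — so the crop's position in
the query frame is unchanged and the query is idempotent. Polygon queries
additionally zero pixels whose centers fall outside the polygon
(mask-after-crop; a crop-only behaviour would be indistinguishable from a
box query). A crop of a multiscale raster returns a single-level element
(the level-0 crop); pyramids are not re-derived. A fully disjoint query
returns empty-but-valid elements (0 rows / 0-sized arrays).

Dataset-level queries apply the region per element and then restrict every
linked table to the instances that survived, so the result always passes
`validate_dataset`.

## Aggregation

`aggregate_points_by_shapes` counts (or sums/averages a numeric column of)
the points contained in each target instance; containment is closed, a
point in several overlapping targets contributes to each, and with a
categorical `value_key` the output is the (targets × categories) count
matrix. The mean over a target containing no points is reported as 0.

`aggregate_shapes_by_shapes` weights source instance i on target j by

    w_ij = area(source_i ∩ target_j) / area(source_i).

The denominator is the **source** area: a cell split across two capture
spots then contributes at most 1 in total (Σ_j w_ij ≤ 1, with equality when
the targets disjointly cover the cell), and the subsequent per-target
normalization (`fractions=True`) yields the composition of the covered
surface. Normalizing by target or by total covered area instead are
plausible alternatives; the choice is isolated in one function
(`_source_area_weights`) so it can be switched. Rows with zero total
overlap stay all-zero and are flagged in the obs column `no_overlap`.

Circle areas and intersections use a 64-gon approximation (max area error
< 0.17%); when the polygonal route is taken for a circle source, the
polygonized area is also used as the denominator so that disjointly tiling
targets still sum to 1 within 1e-6. Circle–circle overlaps use the exact
lens closed form. Labels sources are aggregated by pixel counting (fraction
of a label's pixel centers covered by each target). A display helper
(`filter_low_fractions`) zeroes categories below 5% per row and
renormalizes; `store_as_layer` attaches an aggregation result as a named
layer of an existing table with matching instances.

## Storage

One Zarr store (v2 format) per dataset, with group hierarchy
`images/ labels/ points/ shapes/ tables/`, a root `format_version` marker,
and per-element metadata carrying the kind, axes and the full
`coordinate system → transformation` mapping. Raster groups carry
OME–NGFF-style `multiscales` metadata (axes, per-level scale factors) so
NGFF-aware readers can open them; affine transforms cannot be encoded in
core NGFF 0.4, so the transformation mapping lives in a separate extension
attribute that strict readers ignore. Chunks are 256 per spatial axis.
Byte compatibility with any other tool's dialect is not claimed.

Points are stored as Parquet (columnar, categorical-preserving; a CSV path
exists on the `convert` side but is lossy for categoricals). Shapes are a
Parquet geometry table: WKB for polygons/multipolygons, typed
center/radius records for circles (circles are never polygonized on disk).
Tables store X dense (zarr array) or sparse (CSR triplet group with shape
metadata), layers likewise, and obs/var as Parquet.

Reads are lazy by default: raster pyramid entries are zarr arrays and no
chunk is touched until pixel values are materialized. The contract —
`read_store(lazy=True)` plus `describe_store` perform **zero** reads of
`images/`/`labels/` chunk keys — is enforced in tests through an
instrumented store subclass that counts chunk-key reads. Writes validate
the dataset first and are atomic per element: a failure removes the
partially written element group. Nothing is rewritten in place after an
element is finalized, which keeps the layout compatible with object
storage.

## Synthetic data

`generate_blobs` emulates the structure (not the statistics) of an
imaging-based spatial transcriptomics experiment on a default 128×128
grid: Gaussian intensity bumps on a jittered grid (guaranteeing
separation), i.i.d. Gaussian pixel noise (`noise_sd`, default 0.1),
a segmentation mask from thresholding the noise-free bump field at its
80th percentile (thresholding the noisy field would segment single-pixel
noise excursions), 400 uniform points whose categorical feature follows
the nearest bump (flipped to a random category with probability
min(noise_sd, 0.5)), 30 capture circles on a hexagonal lattice with
center-to-center spacing 2.4× the radius (echoing array-capture geometry,
so aggregation exercises partial overlaps), one bounding box polygon per
bump, and a table of per-segment mean intensities. All randomness flows
from one `numpy.random.default_rng(seed)`; a fixed seed reproduces every
array bitwise.

`generate_aligned_pair` derives a second replica by mapping all vector
elements through a caller-supplied invertible transform and resampling the
rasters through it, and returns the blob centers as order-matched landmark
sets in both frames — a noiseless desk-scale analog of registering two
tissue sections. Because the second replica is a deterministic transform
of the first, recovering the transform from the landmarks is exact and the
two replicas' per-circle category fractions agree almost perfectly; these
tests therefore validate the *machinery* (registration, transformation,
aggregation), not robustness to biological replicate variation,
segmentation errors or count noise, none of which the generator simulates.

## Problem sizes

Default test and acceptance runs use 128×128 rasters, 400 points, 30
circles, 6 blobs; randomized property checks use 50–200 replicates per
property. These sizes were chosen so the full pipeline (including brute
force O(n·m) oracles) completes in seconds while still exercising
multi-level pyramids and partial overlaps.

## Known limitations

- No ellipses; anisotropic maps approximate circles (see above).
- No nonlinear/deformable registration; no automatic landmark detection.
- No transformation-graph path finding: each element stores a direct
  transform per coordinate system.
- Polygon queries on rasters support 2D only.
- A table may annotate a single element; multi-target annotation is a
  documented extension point (`region` may hold a list, joins are
  single-target).
- No remote (S3/HTTP) store access; the layout does not preclude it.
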