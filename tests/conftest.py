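import numpy as np
import pytest

from spatialkit import BlobsConfig, generate_blobs


@pytest.fixture(scope="session")
def blobs():
    """Default synthetic dataset, shared read-only across tests."""
    return generate_blobs(BlobsConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_affine_2d(rng, max_entry=2.0, min_det=0.1):
    """Random nonsingular 2D affine matrix (homogeneous 3x3)."""
    while True:
        lin = rng.uniform(-max_entry, max_entry, (2, 2))
        if abs(np.linalg.det(lin)) >= min_det:
            break
    m = np.eye(3)
    m[:2, :2] = lin
    m[:2, 2] = rng.uniform(-10, 10, 2)
    return m
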