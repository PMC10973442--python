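import numpy as np
import pytest

import bcicm as B
from bcicm.pipeline import ExperimentConfig
from bcicm.udlm import UDLMConfig

#: brute-force (row, col) offsets mirroring the package's angle convention,
#: kept independent of the implementation for oracle tests
ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_force_glcm(pixels, n_levels, distance, angle, symmetric):
    """Double-loop pair counter: the independent GLCM oracle."""
    dr, dc = ANGLE_OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    M, N = pixels.shape
    counts = np.zeros((n_levels, n_levels), dtype=int)
    for x in range(M):
        for y in range(N):
            nx, ny = x + dr, y + dc
            if 0 <= nx < M and 0 <= ny < N:
                counts[pixels[x, y], pixels[nx, ny]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts


@pytest.fixture(scope="session")
def texture_fixture_dir(tmp_path_factory):
    """The default two-class texture image fixture (50/class, 40 px)."""
    root = tmp_path_factory.mktemp("textures")
    return B.make_texture_dataset(B.TextureGenSpec(seed=11), root)


@pytest.fixture(scope="session")
def texture_features(texture_fixture_dir):
    images = B.load_image_folder(texture_fixture_dir)
    cfg = ExperimentConfig(udlm=UDLMConfig(seed=7))
    return B.extract_features(images, cfg), cfg


@pytest.fixture(scope="session")
def blob_fixture():
    spec = B.BlobGenSpec(seed=3)
    points, labels, centers = B.make_feature_blobs(spec)
    return spec, points, labels, centers
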