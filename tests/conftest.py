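import numpy as np
import pytest

from disconnmap import (
    Tractogram,
    VolumeGrid,
    aggregate_prediction,
    select_damaged,
    two_bundle_scene,
    visitation_map,
)


@pytest.fixture(scope="session")
def small_scene():
    """A small but complete study scene shared across test modules."""
    return two_bundle_scene(n_subjects=6, n_streamlines=40, seed=11)


@pytest.fixture(scope="session")
def small_prediction(small_scene):
    maps = [
        visitation_map(select_damaged(t, small_scene["lesion"]), small_scene["grid"])
        for t in small_scene["tractograms"]
    ]
    return aggregate_prediction(maps)


@pytest.fixture
def identity_grid():
    """8^3 grid with 1 mm voxels anchored at the world origin."""
    return VolumeGrid(np.zeros((8, 8, 8)), np.eye(4))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_tractogram(rng, n_streamlines, lo=-8.0, hi=8.0, n_points=6):
    """Uniformly scattered polylines for brute-force comparisons."""
    return Tractogram([
        rng.uniform(lo, hi, size=(n_points, 3)) for _ in range(n_streamlines)
    ])
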