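import numpy as np
import pytest

from atlaseval.cohort import CaseMeta, ParameterMix, make_cohort, make_phantom
from atlaseval.grid import VoxelGrid


@pytest.fixture(scope="session")
def grid64():
    """24 cm field of view at 3.75 mm — small enough for fast registration."""
    return VoxelGrid.centered((64, 64, 64), (3.75, 3.75, 3.75))


@pytest.fixture(scope="session")
def grid48():
    return VoxelGrid.centered((48, 48, 48), (5.0, 5.0, 5.0))


@pytest.fixture(scope="session")
def phantom64(grid64):
    return make_phantom(CaseMeta("ph64", grid=grid64), seed=1)


@pytest.fixture(scope="session")
def cohort48(grid48):
    """Ten-case cohort (two test cases) on the coarse grid, for study tests."""
    return make_cohort(10, ParameterMix(0.5, 0.5), seed=11, grid=grid48, n_test=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def brute_force_jaccard(a, b):
    """Independent oracle: explicit voxel loop over both masks."""
    a = np.asarray(a, bool).ravel()
    b = np.asarray(b, bool).ravel()
    inter = union = 0
    for x, y in zip(a, b):
        if x and y:
            inter += 1
        if x or y:
            union += 1
    return 1.0 if union == 0 else inter / union
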