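import numpy as np
import pandas as pd
import pytest

from vlsmkit import LesionCohort, LesionMask, VolumeGrid


@pytest.fixture
def grid8():
    return VolumeGrid.isotropic((8, 8, 8), 2.0, "test")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_mask(grid, voxels, sample_id="s"):
    arr = np.zeros(grid.shape, dtype=np.uint8)
    for v in voxels:
        arr[v] = 1
    return LesionMask(sample_id, grid, arr)


def random_cohort(grid, n, rng, p=0.3):
    """n random masks on the grid; each voxel lesioned with prob p."""
    masks = []
    for i in range(n):
        vox = (rng.uniform(size=grid.shape) < p).astype(np.uint8)
        vox.flat[rng.integers(vox.size)] = 1  # never empty
        masks.append(LesionMask(f"r{i:03d}", grid, vox))
    return LesionCohort(masks)


@pytest.fixture
def toy_expression(rng):
    """20 genes x 8 samples, standard normal."""
    genes = [f"g{i:02d}" for i in range(20)]
    cols = [f"s{i}" for i in range(8)]
    return pd.DataFrame(rng.normal(size=(20, 8)), index=genes, columns=cols)
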