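import numpy as np
import pytest

from brainshift.mask_io import BinaryMask, VoxelGrid


def make_grid(shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
              orientation=None):
    kwargs = {}
    if orientation is not None:
        kwargs["orientation"] = orientation
    return VoxelGrid(shape=shape, spacing=spacing, origin=origin, **kwargs)


def ball_mask(grid: VoxelGrid, center_mm, radius_mm) -> BinaryMask:
    """Digitized ball: voxels whose world-center lies within radius of center."""
    idx = np.indices(grid.shape, dtype=float).reshape(3, -1).T
    world = grid.index_to_world(idx)
    data = (np.linalg.norm(world - np.asarray(center_mm), axis=1) <= radius_mm)
    return BinaryMask(grid=grid, data=data.reshape(grid.shape))


def random_mask(rng: np.random.Generator, grid: VoxelGrid, max_voxels=500) -> BinaryMask:
    n = int(rng.integers(1, max_voxels + 1))
    idx = np.column_stack(
        [rng.integers(0, s, size=n) for s in grid.shape]
    )
    data = np.zeros(grid.shape, dtype=bool)
    data[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return BinaryMask(grid=grid, data=data)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def unit_grid():
    return make_grid()
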