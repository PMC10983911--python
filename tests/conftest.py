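from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

# Deterministic property tests; no on-disk example database.
settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")

from relimaps import (
    BrainMask,
    LabeledVolume,
    MeasurementStack,
    VolumeGrid,
)

#: The printed two-occasion example: occasion B = 3 x occasion A, so the
#: Pearson correlation is perfect while consistency is not.
WORKED_A = np.array([1.0, 3.0, 6.0, 9.0, 12.0])
WORKED_B = 3.0 * WORKED_A


@pytest.fixture
def worked_matrix() -> np.ndarray:
    return np.column_stack([WORKED_A, WORKED_B])


@pytest.fixture
def grid222() -> VolumeGrid:
    return VolumeGrid(shape=(2, 2, 2), affine=np.eye(4))


def make_grid(shape=(2, 2, 2)) -> VolumeGrid:
    return VolumeGrid(shape=shape, affine=np.eye(4))


def make_volume(values, shape=None, label="vol") -> LabeledVolume:
    data = np.asarray(values, dtype=float)
    if shape is not None:
        data = data.reshape(shape)
    return LabeledVolume(grid=make_grid(data.shape), data=data, label=label)


def make_mask(values, shape=None, allow_empty=False) -> BrainMask:
    data = np.asarray(values)
    if shape is not None:
        data = data.reshape(shape)
    return BrainMask(grid=make_grid(data.shape), data=data,
                     allow_empty=allow_empty)


def stack_from_array(data: np.ndarray, grid_shape=None) -> MeasurementStack:
    """Build a stack from an (n, k, V) array; V maps onto grid_shape
    (default: a V x 1 x 1 grid)."""
    n, k, v = data.shape
    shape = grid_shape or (v, 1, 1)
    grid = make_grid(shape)
    occasions = [
        [
            LabeledVolume(grid=grid, data=data[i, j].reshape(shape),
                          label=f"sub-{i}_occ-{j}")
            for i in range(n)
        ]
        for j in range(k)
    ]
    return MeasurementStack(
        occasions=occasions, subject_ids=[f"sub-{i}" for i in range(n)]
    )
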