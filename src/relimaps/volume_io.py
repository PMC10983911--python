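"""Reading, writing and masking of 3D NIfTI volumes.

Every reliability computation in this package operates on collections of
3D statistical maps (one map per subject per measurement occasion) that
share a single voxel grid.  This module defines the grid and volume
containers, enforces grid compatibility — mismatched grids are an error,
never silently resampled — and flattens masked stacks into subject x voxel
matrices with a deterministic row-major voxel ordering.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

#: Absolute tolerance (mm) for declaring two affines equal.
AFFINE_ATOL = 1e-4


@dataclass(frozen=True, eq=False)
class VolumeGrid:
    """A 3D voxel grid: array shape plus 4x4 voxel-to-world affine (mm)."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def compatible(self, other: "VolumeGrid", atol: float = AFFINE_ATOL) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol, rtol=0.0
        )

    def require_compatible(self, other: "VolumeGrid", what: str = "volume") -> None:
        if not self.compatible(other):
            raise ValueError(
                f"grid mismatch: {what} has shape {other.shape} / different affine; "
                f"expected shape {self.shape} (no resampling is performed)"
            )


@dataclass(eq=False)
class LabeledVolume:
    """A scalar 3D map on a grid with a free-text label (subject/run/contrast)."""

    grid: VolumeGrid
    data: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {data.shape} does not match grid shape {self.grid.shape}"
            )
        self.data = data


@dataclass(eq=False)
class BrainMask:
    """A binary voxel mask; at least one voxel must be set.

    Set-algebra results (e.g. a threshold partition) may legitimately be
    empty; such masks are built with ``allow_empty=True`` and propagate
    NaN through downstream summaries instead of erroring.
    """

    grid: VolumeGrid
    data: np.ndarray
    allow_empty: bool = False

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {data.shape} does not match grid shape {self.grid.shape}"
            )
        unique = np.unique(data)
        if not np.all(np.isin(unique, (0, 1))):
            raise ValueError("mask data must be binary (0/1)")
        self.data = data.astype(bool)
        if not self.data.any() and not self.allow_empty:
            raise ValueError("empty mask: at least one voxel must be nonzero")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def indices(self) -> np.ndarray:
        """Flat (row-major, C-order) indices of in-mask voxels. Deterministic."""
        return np.flatnonzero(self.data.ravel(order="C"))


@dataclass(eq=False)
class MeasurementStack:
    """Subjects x occasions collection of aligned maps.

    ``occasions`` is an ordered list (length k >= 2) of ordered lists
    (length n >= 2) of volumes; subject order must be identical across
    occasions and is recorded in ``subject_ids``.
    """

    occasions: list[list[LabeledVolume]]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.occasions) < 2:
            raise ValueError("need k >= 2 measurement occasions")
        n = len(self.occasions[0])
        if n < 2:
            raise ValueError("need n >= 2 subjects")
        if any(len(occ) != n for occ in self.occasions):
            raise ValueError("all occasions must contain the same number of subjects")
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length must equal the subject count")
        grid = self.occasions[0][0].grid
        for occ in self.occasions:
            for vol in occ:
                grid.require_compatible(vol.grid, what=f"volume {vol.label!r}")

    @property
    def grid(self) -> VolumeGrid:
        return self.occasions[0][0].grid

    @property
    def n_subjects(self) -> int:
        return len(self.occasions[0])

    @property
    def k_occasions(self) -> int:
        return len(self.occasions)


def read_volume(path: str | os.PathLike, label: str | None = None) -> LabeledVolume:
    """Read one 3D NIfTI volume.

    A 4D file with a singleton last axis is accepted and squeezed; any
    other 4D shape is rejected.  The label defaults to the file basename.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"non-3D data in {path}: shape {data.shape}")
    grid = VolumeGrid(shape=data.shape, affine=np.asarray(img.affine))
    return LabeledVolume(grid=grid, data=data, label=label or path.name)


def write_volume(volume: LabeledVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1 (.nii or .nii.gz, gzip handled by extension)."""
    img = nib.Nifti1Image(volume.data.astype(np.float64), volume.grid.affine)
    nib.save(img, str(path))


def read_mask(path: str | os.PathLike) -> BrainMask:
    vol = read_volume(path)
    return BrainMask(grid=vol.grid, data=vol.data > 0)


def write_mask(mask: BrainMask, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


def stack_to_matrix(
    stack: MeasurementStack, mask: BrainMask
) -> tuple[list[np.ndarray], np.ndarray]:
    """Flatten a stack to per-occasion ``n x V`` matrices over masked voxels.

    Column ``j`` of every matrix corresponds to the same voxel; ordering is
    row-major over array indices, a pure function of the mask.  Returns the
    list of matrices (one per occasion, subject order preserved) and the
    flat voxel index of each column.
    """
    stack.grid.require_compatible(mask.grid, what="mask")
    idx = mask.indices()
    if idx.size == 0:  # unreachable through BrainMask, kept for raw callers
        raise ValueError("empty mask")
    matrices = []
    for occ in stack.occasions:
        rows = [vol.data.ravel(order="C")[idx] for vol in occ]
        matrices.append(np.vstack(rows))
    return matrices, idx


def matrix_to_volume(
    values: np.ndarray,
    mask: BrainMask,
    fill: float = np.nan,
    label: str = "",
) -> LabeledVolume:
    """Scatter a length-V vector back onto the mask's grid (inverse of
    :func:`stack_to_matrix` column extraction)."""
    values = np.asarray(values, dtype=float)
    idx = mask.indices()
    if values.shape != (idx.size,):
        raise ValueError(f"expected {idx.size} values, got {values.shape}")
    flat = np.full(mask.grid.n_voxels, fill, dtype=float)
    flat[idx] = values
    return LabeledVolume(
        grid=mask.grid, data=flat.reshape(mask.grid.shape), label=label
    )


def partition_by_reference(
    reference: LabeledVolume, mask: BrainMask, threshold: float
) -> tuple[BrainMask, BrainMask]:
    """Split a mask into supra- and sub-threshold parts of a reference map.

    Suprathreshold voxels are those *strictly exceeding* the threshold
    (e.g. z > 3.1 on a meta-analytic task-positive reference); voxels
    strictly below form the subthreshold mask.  Voxels exactly at the
    threshold belong to neither partition.
    """
    mask.grid.require_compatible(reference.grid, what="reference")
    supra = mask.data & (reference.data > threshold)
    sub = mask.data & (reference.data < threshold)
    return (
        BrainMask(grid=mask.grid, data=supra, allow_empty=True),
        BrainMask(grid=mask.grid, data=sub, allow_empty=True),
    )
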