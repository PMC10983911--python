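"""Voxelwise and region-of-interest reliability maps.

Applies the subject x occasion variance decomposition independently at
every masked voxel of a measurement stack, producing five aligned 3D maps
(ICC estimate, lower bound, upper bound, MSBS, MSWS), spatial median
summaries restricted to a mask, and atlas-based ROI reliability tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .anova import (
    ICC_TYPES,
    bounds_stacked,
    decompose,
    icc_scalar,
    icc_stacked,
    mean_squares_stacked,
)
from .volume_io import (
    BrainMask,
    LabeledVolume,
    MeasurementStack,
    matrix_to_volume,
    stack_to_matrix,
    write_volume,
)


@dataclass(eq=False)
class ReliabilityMaps:
    """Five aligned 3D reliability maps plus the analysis metadata.

    Out-of-mask voxels are NaN; degenerate (zero-variance) voxels are NaN
    in the ICC and bound maps.
    """

    icc: LabeledVolume
    lower: LabeledVolume
    upper: LabeledVolume
    msbs: LabeledVolume
    msws: LabeledVolume
    icc_type: str
    n: int
    k: int

    def save(self, prefix: str | os.PathLike, fill: float = np.nan) -> list[Path]:
        """Write the five maps as ``<prefix>_{icc,lb,ub,msbs,msws}.nii.gz``.

        ``fill`` replaces out-of-mask NaN values on disk (0 is convenient
        for viewers that choke on NaN).
        """
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = []
        for suffix, vol in [
            ("icc", self.icc),
            ("lb", self.lower),
            ("ub", self.upper),
            ("msbs", self.msbs),
            ("msws", self.msws),
        ]:
            out = vol
            if not np.isnan(fill):
                data = np.where(np.isnan(vol.data), fill, vol.data)
                out = LabeledVolume(grid=vol.grid, data=data, label=vol.label)
            path = prefix.parent / f"{prefix.name}_{suffix}.nii.gz"
            write_volume(out, path)
            paths.append(path)
        return paths


def voxelwise_icc(
    stack: MeasurementStack,
    mask: BrainMask,
    icc_type: str = "icc_3",
    alpha: float = 0.05,
) -> ReliabilityMaps:
    """Per-voxel ICC with F-based confidence bounds and variance components.

    Every masked voxel's n x k matrix (subjects x occasions) is decomposed
    independently; the computation is vectorized over voxels but performs
    the same floating-point operations as the scalar per-voxel path, so
    the two agree exactly.
    """
    if icc_type not in ICC_TYPES:
        raise ValueError(f"icc_type must be one of {ICC_TYPES}, got {icc_type!r}")
    matrices, _ = stack_to_matrix(stack, mask)
    data = np.stack(matrices, axis=1)  # (n, k, V)
    n, k, _ = data.shape
    ms = mean_squares_stacked(data)
    est = icc_stacked(ms["msbs"], ms["msws"], ms["msc"], ms["mse"], n, k, icc_type)
    lo, up = bounds_stacked(
        ms["msbs"], ms["msws"], ms["msc"], ms["mse"], n, k, icc_type, alpha
    )
    tag = f"{icc_type} n={n} k={k}"
    return ReliabilityMaps(
        icc=matrix_to_volume(est, mask, label=f"icc {tag}"),
        lower=matrix_to_volume(lo, mask, label=f"lower {tag}"),
        upper=matrix_to_volume(up, mask, label=f"upper {tag}"),
        msbs=matrix_to_volume(ms["msbs"], mask, label=f"msbs {tag}"),
        msws=matrix_to_volume(ms["msws"], mask, label=f"msws {tag}"),
        icc_type=icc_type,
        n=n,
        k=k,
    )


def median_within_mask(volume: LabeledVolume, mask: BrainMask) -> float:
    """Median of a map over masked, finite voxels; NaN if none remain."""
    volume.grid.require_compatible(mask.grid, what="mask")
    values = volume.data[mask.data]
    values = values[np.isfinite(values)]
    if values.size == 0:
        return float("nan")
    return float(np.median(values))


def roi_icc(
    stack: MeasurementStack,
    atlas: LabeledVolume,
    icc_type: str = "icc_3",
    alpha: float = 0.05,
    mask: BrainMask | None = None,
    roi_names: dict[int, str] | None = None,
    strategy: str = "mean",
) -> pd.DataFrame:
    """Reliability per atlas region.

    ``atlas`` is an integer-labeled volume (0 = background).  With the
    default ``strategy="mean"`` the spatial mean signal within each region
    is extracted per subject and occasion and the scalar ICC is computed on
    the resulting n x k matrix.  ``strategy="voxel_median"`` instead
    aggregates the voxelwise maps by their within-region median — both
    readings of "ROI reliability" are found in practice, so the choice is
    explicit.

    Returns one row per in-mask region with columns roi_label, roi_name,
    estimate, lower, upper, msbs, msws, voxel_count.
    """
    if strategy not in ("mean", "voxel_median"):
        raise ValueError(f"unknown strategy {strategy!r}")
    stack.grid.require_compatible(atlas.grid, what="atlas")
    labels_img = np.asarray(atlas.data)
    if not np.allclose(labels_img, np.round(labels_img)):
        raise ValueError("atlas must be integer-valued")
    labels_img = labels_img.astype(int)
    in_mask = np.ones(stack.grid.shape, dtype=bool) if mask is None else mask.data

    labels = sorted(int(v) for v in np.unique(labels_img[in_mask]) if v != 0)
    roi_names = roi_names or {}

    if strategy == "voxel_median":
        full_mask = BrainMask(grid=stack.grid, data=in_mask & (labels_img != 0))
        maps = voxelwise_icc(stack, full_mask, icc_type=icc_type, alpha=alpha)

    rows = []
    for lab in labels:
        region = in_mask & (labels_img == lab)
        count = int(region.sum())
        if count == 0:
            rows.append((lab, roi_names.get(lab, ""), *([np.nan] * 5), 0))
            continue
        if strategy == "mean":
            # n x k matrix of region-mean signal
            matrix = np.array(
                [
                    [float(occ[i].data[region].mean()) for occ in stack.occasions]
                    for i in range(stack.n_subjects)
                ]
            )
            res = icc_scalar(matrix, icc_type=icc_type, alpha=alpha)
            vd = decompose(matrix)
            rows.append(
                (
                    lab,
                    roi_names.get(lab, ""),
                    res.estimate,
                    res.lower,
                    res.upper,
                    vd.ms_between_subjects,
                    vd.ms_within_subjects,
                    count,
                )
            )
        else:
            region_mask = BrainMask(grid=stack.grid, data=region)
            rows.append(
                (
                    lab,
                    roi_names.get(lab, ""),
                    median_within_mask(maps.icc, region_mask),
                    median_within_mask(maps.lower, region_mask),
                    median_within_mask(maps.upper, region_mask),
                    median_within_mask(maps.msbs, region_mask),
                    median_within_mask(maps.msws, region_mask),
                    count,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "roi_label",
            "roi_name",
            "estimate",
            "lower",
            "upper",
            "msbs",
            "msws",
            "voxel_count",
        ],
    )
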