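"""Similarity between statistical maps.

Group-level reliability between measurement occasions is summarized either
on binarized maps — Jaccard |A∩B|/|A∪B| or Dice 2|A∩B|/(|A|+|B|) after
thresholding — or on continuous maps via the Spearman rank correlation over
masked voxels.  A t-map can be rescaled to Cohen's d (d = t/sqrt(N)) so
that thresholds are comparable across group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .volume_io import BrainMask, LabeledVolume, VolumeGrid

METRICS = ("jaccard", "dice", "spearman")


@dataclass(frozen=True)
class SimilarityResult:
    image_a: str
    image_b: str
    metric: str
    threshold: float | None
    coefficient: float


@dataclass(eq=False)
class EffectSizeMap:
    """Cohen's d per voxel, converted from a group t-map of size source_n."""

    grid: VolumeGrid
    data: np.ndarray
    source_n: int


def binarize(
    volume: LabeledVolume, mask: BrainMask, threshold: float
) -> BrainMask:
    """Voxels in the mask whose value strictly exceeds the threshold."""
    volume.grid.require_compatible(mask.grid, what="mask")
    data = mask.data & (volume.data > threshold)
    return BrainMask(grid=mask.grid, data=data, allow_empty=True)


def jaccard(a: BrainMask, b: BrainMask) -> float:
    """|A∩B| / |A∪B|; NaN when both masks are empty."""
    a.grid.require_compatible(b.grid, what="second mask")
    union = int((a.data | b.data).sum())
    if union == 0:
        return float("nan")
    return float((a.data & b.data).sum() / union)


def dice(a: BrainMask, b: BrainMask) -> float:
    """2|A∩B| / (|A| + |B|); NaN when both masks are empty."""
    a.grid.require_compatible(b.grid, what="second mask")
    total = int(a.data.sum()) + int(b.data.sum())
    if total == 0:
        return float("nan")
    return float(2 * (a.data & b.data).sum() / total)


def spearman_similarity(
    a: LabeledVolume, b: LabeledVolume, mask: BrainMask
) -> float:
    """Spearman rank correlation of two maps over masked voxels.

    Ties receive average ranks (equivalent to the product-moment
    correlation of ranks, and to 1 - 6 Σd²/(n(n²-1)) when there are no
    ties).  NaN when either map has zero rank variance.
    """
    a.grid.require_compatible(b.grid, what="second image")
    a.grid.require_compatible(mask.grid, what="mask")
    x = a.data[mask.data]
    y = b.data[mask.data]
    if x.size < 3:
        raise ValueError("need at least 3 masked voxels for a rank correlation")
    import warnings

    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        # constant input: NaN is the documented contract, not a surprise
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(x, y).statistic
    return float(rho)


def image_similarity(
    a: LabeledVolume,
    b: LabeledVolume,
    mask: BrainMask,
    threshold: float | None = None,
    metric: str = "jaccard",
) -> SimilarityResult:
    """One similarity coefficient for an image pair.

    ``jaccard``/``dice`` binarize both images at the threshold first
    (threshold defaults to 0: any positive masked voxel); ``spearman``
    ignores the threshold and correlates the continuous masked values.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    if metric == "spearman":
        coef = spearman_similarity(a, b, mask)
        thr = None
    else:
        thr = 0.0 if threshold is None else float(threshold)
        ma = binarize(a, mask, thr)
        mb = binarize(b, mask, thr)
        coef = jaccard(ma, mb) if metric == "jaccard" else dice(ma, mb)
    return SimilarityResult(
        image_a=a.label, image_b=b.label, metric=metric, threshold=thr,
        coefficient=coef,
    )


def pairwise_similarity(
    images: Sequence[LabeledVolume],
    mask: BrainMask,
    threshold: float | None = None,
    metric: str = "jaccard",
) -> pd.DataFrame:
    """All C(m, 2) unordered pair similarities for a list of >= 2 images.

    Rows are ordered lexicographically by input position (i < j); labels
    come from the image labels.
    """
    if len(images) < 2:
        raise ValueError("need at least 2 images for pairwise similarity")
    rows = []
    for i, j in combinations(range(len(images)), 2):
        res = image_similarity(images[i], images[j], mask, threshold, metric)
        rows.append(
            (res.image_a, res.image_b, res.metric, res.threshold, res.coefficient)
        )
    return pd.DataFrame(
        rows, columns=["image_a", "image_b", "metric", "threshold", "coefficient"]
    )


def t_to_cohens_d(tmap: LabeledVolume, n: int) -> EffectSizeMap:
    """Convert a one-sample group t-map to Cohen's d via d = t / sqrt(n)."""
    if n < 1:
        raise ValueError(f"group size must be >= 1, got {n}")
    return EffectSizeMap(grid=tmap.grid, data=tmap.data / np.sqrt(n), source_n=int(n))
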