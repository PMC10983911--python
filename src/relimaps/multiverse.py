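"""Analytic decision grids and specification-curve summaries.

A multiverse analysis enumerates every combination of analytic decisions —
here smoothing kernel (FWHM, mm), motion-correction strategy, task model
parameterization and contrast — runs the same reliability summary under
each, and displays the ordered estimates as a specification curve.  This
module owns the bookkeeping: deterministic enumeration of the grid,
collection of per-permutation estimates across samples, ranking, and
nearest-rank percentile selection.

The package deliberately does not run first-level GLMs: it consumes
per-permutation map sets (real or synthetic) keyed by permutation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .volume_io import BrainMask, LabeledVolume
from .voxelwise import median_within_mask

#: Kernel multipliers used to scale voxel size into candidate FWHMs.
DEFAULT_MULTIPLIERS = (1.5, 2.0, 2.5, 3.0, 3.5)


@dataclass(frozen=True)
class Permutation:
    """One cell of the decision grid."""

    id: int
    fwhm: float
    motion: str
    model: str
    contrast: str


@dataclass(frozen=True)
class DecisionGrid:
    """The four analytic decision axes of the multiverse."""

    fwhm_options: tuple[float, ...]
    motion_options: tuple[str, ...]
    model_options: tuple[str, ...]
    contrast_options: tuple[str, ...]

    def __post_init__(self) -> None:
        for name in ("fwhm_options", "motion_options", "model_options",
                     "contrast_options"):
            values = tuple(getattr(self, name))
            if not values:
                raise ValueError(f"{name} must be nonempty")
            if len(set(values)) != len(values):
                raise ValueError(f"{name} entries must be unique")
            object.__setattr__(self, name, values)

    @property
    def size(self) -> int:
        return (
            len(self.fwhm_options)
            * len(self.motion_options)
            * len(self.model_options)
            * len(self.contrast_options)
        )


def build_smoothing_grid(
    voxel_mm: float,
    multipliers: Sequence[float] = DEFAULT_MULTIPLIERS,
    weight: float = 1.0,
) -> list[float]:
    """Candidate smoothing kernels: multiplier x voxel size x weight, in mm.

    The weight rescales kernels for acquisitions whose voxels carry more
    inherent smoothness (e.g. 0.5 for 4 mm anisotropic data so its kernels
    line up with those of 2.4 mm isotropic data).  Each kernel is rounded
    to one decimal.
    """
    if voxel_mm <= 0 or weight <= 0:
        raise ValueError("voxel size and weight must be positive")
    return [round(m * voxel_mm * weight, 1) for m in multipliers]


def enumerate_permutations(grid: DecisionGrid) -> list[Permutation]:
    """Cartesian product of the grid, fwhm outermost / contrast innermost,
    ids 1..R in that deterministic order."""
    perms = []
    for i, (fwhm, motion, model, contrast) in enumerate(
        product(
            grid.fwhm_options,
            grid.motion_options,
            grid.model_options,
            grid.contrast_options,
        ),
        start=1,
    ):
        perms.append(
            Permutation(id=i, fwhm=fwhm, motion=motion, model=model,
                        contrast=contrast)
        )
    return perms


def grid_from_config(config: Mapping | str | os.PathLike) -> DecisionGrid:
    """Build a grid from a config mapping or YAML file.

    Keys: voxel_mm, multipliers (optional), weight (optional, default 1),
    motion_options, model_options, contrast_options.  Unknown keys are
    rejected.
    """
    if not isinstance(config, Mapping):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    allowed = {
        "voxel_mm", "multipliers", "weight",
        "motion_options", "model_options", "contrast_options",
    }
    unknown = set(config) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    missing = {"voxel_mm", "motion_options", "model_options",
               "contrast_options"} - set(config)
    if missing:
        raise ValueError(f"missing config keys: {sorted(missing)}")
    fwhms = build_smoothing_grid(
        float(config["voxel_mm"]),
        tuple(config.get("multipliers", DEFAULT_MULTIPLIERS)),
        float(config.get("weight", 1.0)),
    )
    return DecisionGrid(
        fwhm_options=tuple(fwhms),
        motion_options=tuple(str(m) for m in config["motion_options"]),
        model_options=tuple(str(m) for m in config["model_options"]),
        contrast_options=tuple(str(c) for c in config["contrast_options"]),
    )


def collect_estimates(
    estimates: pd.DataFrame | Mapping[tuple[int, str], float],
    permutations: Sequence[Permutation],
) -> pd.DataFrame:
    """Build a specification-curve table from per-(permutation, sample)
    summary estimates.

    ``estimates`` is either a mapping {(permutation_id, sample): value} or
    a DataFrame with columns permutation_id, sample, estimate.  Per
    permutation the point estimate is the mean across samples and the 95%
    interval is mean ± 1.96 SE of the sample estimates (NaN with a single
    sample).  Rows are ranked ascending by point estimate — ties broken by
    permutation id — and annotated with percentile = rank / R.

    A permutation with no estimate is an error, never silently dropped.
    """
    if isinstance(estimates, Mapping):
        records = [
            {"permutation_id": pid, "sample": sample, "estimate": value}
            for (pid, sample), value in estimates.items()
        ]
        df = pd.DataFrame.from_records(records)
    else:
        df = estimates.copy()
    required = {"permutation_id", "sample", "estimate"}
    if not required.issubset(df.columns):
        raise ValueError(f"estimates must provide columns {sorted(required)}")

    by_perm = {p.id: p for p in permutations}
    missing = sorted(set(by_perm) - set(df["permutation_id"].astype(int)))
    if missing:
        raise ValueError(f"no estimates for permutation ids {missing}")
    extra = sorted(set(df["permutation_id"].astype(int)) - set(by_perm))
    if extra:
        raise ValueError(f"estimates for unknown permutation ids {extra}")

    grouped = df.groupby("permutation_id")["estimate"]
    mean = grouped.mean()
    count = grouped.count()
    sd = grouped.std(ddof=1)
    se = sd / np.sqrt(count)
    table = pd.DataFrame(
        {
            "permutation_id": mean.index.astype(int),
            "estimate": mean.to_numpy(),
            "n_samples": count.to_numpy(),
            "ci_lower": (mean - 1.96 * se).to_numpy(),
            "ci_upper": (mean + 1.96 * se).to_numpy(),
        }
    )
    for field in ("fwhm", "motion", "model", "contrast"):
        table[field] = [getattr(by_perm[i], field) for i in table["permutation_id"]]
    table = table.sort_values(
        ["estimate", "permutation_id"], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["percentile"] = table["rank"] / len(table)
    cols = ["permutation_id", "fwhm", "motion", "model", "contrast",
            "estimate", "n_samples", "ci_lower", "ci_upper", "rank", "percentile"]
    return table[cols]


def percentile_select(table: pd.DataFrame, q: float) -> pd.Series:
    """Nearest-rank percentile row of a ranked specification-curve table:
    the row with rank ceil(q * R) (ties already broken by permutation id)."""
    if not 0.0 < q <= 1.0:
        raise ValueError("q must lie in (0, 1]")
    r = int(np.ceil(q * len(table)))
    return table.loc[table["rank"] == r].iloc[0]


def permutation_medians(
    maps_by_permutation: Mapping[int, LabeledVolume],
    supra: BrainMask,
    sub: BrainMask,
) -> pd.DataFrame:
    """Supra- and sub-threshold in-mask medians per permutation map."""
    rows = [
        (
            pid,
            median_within_mask(vol, supra),
            median_within_mask(vol, sub),
        )
        for pid, vol in sorted(maps_by_permutation.items())
    ]
    return pd.DataFrame(
        rows, columns=["permutation_id", "median_supra", "median_sub"]
    )
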