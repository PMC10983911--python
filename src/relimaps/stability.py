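"""Bootstrap stability of reliability estimates across sample size.

How large a sample is needed before the median voxelwise ICC (and its
variance components) stops moving?  Subjects are resampled with
replacement at a grid of sample sizes (default 25 to 525 in steps of 50,
100 draws per size); each draw re-runs the voxelwise decomposition and
retains the in-mask median ICC, MSBS and MSWS.  Per-size means and
percentile intervals across draws chart how the estimates stabilize as N
grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anova import icc_stacked, mean_squares_stacked
from .volume_io import BrainMask, MeasurementStack, stack_to_matrix

#: Sample-size grid: 25 to 525 subjects in intervals of 50.
DEFAULT_N_GRID = tuple(range(25, 526, 50))
DEFAULT_ITERATIONS = 100

_METRICS = ("median_icc", "median_msbs", "median_msws")


@dataclass(eq=False)
class StabilityCurve:
    """Per-draw medians and per-sample-size summaries of the bootstrap.

    ``draws`` has one row per (n, iteration) with the three mask medians;
    ``summary`` has one row per n with the across-iteration mean and the
    2.5/97.5 percentile interval for each metric.
    """

    draws: pd.DataFrame
    summary: pd.DataFrame
    seed: int
    icc_type: str


def _subsample_medians(
    data: np.ndarray, idx: np.ndarray, icc_type: str
) -> tuple[float, float, float]:
    sub = data[idx]
    n, k, _ = sub.shape
    ms = mean_squares_stacked(sub)
    est = icc_stacked(ms["msbs"], ms["msws"], ms["msc"], ms["mse"], n, k, icc_type)
    return (
        float(np.nanmedian(est)),
        float(np.nanmedian(ms["msbs"])),
        float(np.nanmedian(ms["msws"])),
    )


def bootstrap_stability(
    stack: MeasurementStack,
    mask: BrainMask,
    n_grid: tuple[int, ...] | list[int] = DEFAULT_N_GRID,
    iterations: int = DEFAULT_ITERATIONS,
    icc_type: str = "icc_3",
    seed: int = 0,
    with_replacement: bool = True,
) -> StabilityCurve:
    """Chart median ICC/MSBS/MSWS stability across subject sample sizes.

    For each n in ``n_grid`` and each of ``iterations`` draws, n subjects
    are sampled (with replacement by default; ``with_replacement=False``
    permits exact-identity checks at n = full sample) and the voxelwise
    decomposition is re-run on the subsample.  One master seed spawns an
    independent substream per (n, iteration) cell, so results are
    reproducible and order-independent.
    """
    n_grid = [int(n) for n in n_grid]
    if not n_grid:
        raise ValueError("empty sample-size grid")
    if any(b <= a for a, b in zip(n_grid, n_grid[1:])):
        raise ValueError("n_grid values must be strictly increasing")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    matrices, _ = stack_to_matrix(stack, mask)
    data = np.stack(matrices, axis=1)  # (n, k, V)
    n_avail = data.shape[0]
    if not with_replacement and max(n_grid) > n_avail:
        raise ValueError(
            f"cannot draw {max(n_grid)} of {n_avail} subjects without replacement"
        )

    children = np.random.SeedSequence(seed).spawn(len(n_grid) * iterations)
    rows = []
    cell = 0
    for n in n_grid:
        for it in range(1, iterations + 1):
            rng = np.random.default_rng(children[cell])
            cell += 1
            if with_replacement:
                idx = rng.integers(0, n_avail, size=n)
            else:
                idx = rng.choice(n_avail, size=n, replace=False)
            med_icc, med_msbs, med_msws = _subsample_medians(data, idx, icc_type)
            rows.append((n, it, med_icc, med_msbs, med_msws))
    draws = pd.DataFrame(rows, columns=["n", "iteration", *_METRICS])

    summaries = []
    for n, group in draws.groupby("n"):
        row: dict[str, float] = {"n": int(n)}
        for metric in _METRICS:
            values = group[metric].to_numpy()
            row[f"{metric}_mean"] = float(np.mean(values))
            row[f"{metric}_ci_lower"] = float(np.percentile(values, 2.5))
            row[f"{metric}_ci_upper"] = float(np.percentile(values, 97.5))
        summaries.append(row)
    summary = pd.DataFrame(summaries).sort_values("n").reset_index(drop=True)
    return StabilityCurve(draws=draws, summary=summary, seed=int(seed),
                          icc_type=icc_type)
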