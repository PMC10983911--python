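"""Model-level helpers: fixed-effects run averaging and design efficiency.

Two small computations sit between first-level model outputs and the
reliability analyses.  Per-run effect estimates are combined into a
session-level estimate by precision weighting (inverse-variance fixed
effects), and the statistical efficiency of a contrast under a design
matrix is 1 / (c (X'X)^{-1} c').
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .volume_io import LabeledVolume


@dataclass(eq=False)
class EffectPair:
    """An effect-estimate map and its voxelwise estimation variance."""

    beta: LabeledVolume
    variance: LabeledVolume

    def __post_init__(self) -> None:
        self.beta.grid.require_compatible(self.variance.grid, what="variance map")
        var = self.variance.data
        if np.nanmin(var) < 0:
            raise ValueError("variance map must be non-negative")


def fixed_effects_combine(runs: Sequence[EffectPair]) -> EffectPair:
    """Precision-weighted fixed-effects average of >= 2 runs, voxelwise.

    beta_fx = Σ(beta_i / var_i) / Σ(1 / var_i);  var_fx = 1 / Σ(1 / var_i).
    A voxel with zero or NaN variance in any run is NaN in the output.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs to combine")
    grid = runs[0].beta.grid
    for run in runs[1:]:
        grid.require_compatible(run.beta.grid, what="run beta map")
    betas = np.stack([run.beta.data for run in runs])
    variances = np.stack([run.variance.data for run in runs])
    invalid = np.any(~np.isfinite(variances) | (variances <= 0), axis=0)
    invalid |= np.any(~np.isfinite(betas), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        weights = 1.0 / variances
        var_fx = 1.0 / weights.sum(axis=0)
        beta_fx = (betas * weights).sum(axis=0) * var_fx
    beta_fx[invalid] = np.nan
    var_fx[invalid] = np.nan
    label = " + ".join(run.beta.label for run in runs)
    return EffectPair(
        beta=LabeledVolume(grid=grid, data=beta_fx, label=f"fx({label})"),
        variance=LabeledVolume(grid=grid, data=var_fx, label=f"fx-var({label})"),
    )


def contrast_efficiency(X: np.ndarray, c: np.ndarray) -> float:
    """Efficiency of contrast c under design X: 1 / (c (X'X)^{-1} c').

    Higher is better: the value is the inverse of the (unit-noise) variance
    of the contrast estimate, so it scales quadratically with regressor
    amplitude and linearly with the number of scans.
    """
    X = np.asarray(X, dtype=float)
    c = np.asarray(c, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("design matrix must be 2D (time points x regressors)")
    t, p = X.shape
    if c.shape != (p,):
        raise ValueError(f"contrast length {c.size} does not match {p} regressors")
    if not np.any(c):
        raise ValueError("contrast vector must not be all zero")
    gram = X.T @ X
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    cvc = float(c @ np.linalg.solve(gram, c))
    return 1.0 / cvc


def read_design_matrix(path: str | os.PathLike) -> tuple[np.ndarray, list[str]]:
    """Read a design matrix from TSV (header row = regressor names)."""
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), list(df.columns)


def write_design_matrix(
    X: np.ndarray, column_names: Sequence[str], path: str | os.PathLike
) -> None:
    pd.DataFrame(np.asarray(X, dtype=float), columns=list(column_names)).to_csv(
        path, sep="\t", index=False
    )
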