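"""Synthetic multi-subject, multi-occasion contrast maps with known truth.

Voxel values follow the two-way model that underlies the ICC:

    y[i, j, v] = mu + shift_j + b_i[v] + e_ij[v]

with subject effects b ~ N(0, sigma_b^2) and residuals e ~ N(0,
sigma_e^2), so the population ICC at a voxel is sigma_b^2 / (sigma_b^2 +
sigma_e^2) — an analytic ground truth for every estimator in the package.
A spherical "task-positive" region carries its own variance components
(by default more between-subject signal, i.e. higher reliability), which
gives the supra/sub-threshold partition something real to find.  A
companion reference z-map exceeding 3.1 exactly on the region and a
two-label atlas (region vs complement) stand in for the meta-analytic
reference map and anatomical atlas a real analysis would download; both
are synthetic by construction.

All randomness flows from a single integer seed; outputs are reproducible
byte for byte.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_support import EffectPair
from .volume_io import (
    BrainMask,
    LabeledVolume,
    MeasurementStack,
    VolumeGrid,
    write_mask,
    write_volume,
)


@dataclass(frozen=True)
class SphereSpec:
    """A spherical region (voxel-index center and radius) with its own
    variance components."""

    center: tuple[int, int, int]
    radius: float
    sigma2_between: float = 3.0
    sigma2_within: float = 1.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic two-way model.

    Defaults emulate a modest single-site study: a 10x10x10 grid, 60
    subjects scanned on 2 occasions, background variance ratio 1:1
    (population ICC 0.5) and a task-positive sphere with three times the
    between-subject variance (population ICC 0.75).
    """

    shape: tuple[int, int, int] = (10, 10, 10)
    n_subjects: int = 60
    k_occasions: int = 2
    mu: float = 0.0
    sigma2_between: float = 1.0
    sigma2_within: float = 1.0
    occasion_shift: float = 0.0
    target_region: SphereSpec | str | None = "auto"
    beta_variance_scale: float = 1.0
    voxel_mm: float = 2.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_region == "auto":
            # mid-grid sphere covering roughly 30% of the smallest axis
            object.__setattr__(
                self,
                "target_region",
                SphereSpec(
                    center=tuple(s // 2 for s in self.shape),
                    radius=0.3 * min(self.shape),
                ),
            )
        if self.n_subjects < 2 or self.k_occasions < 2:
            raise ValueError("need n_subjects >= 2 and k_occasions >= 2")
        if min(self.sigma2_between, self.sigma2_within) < 0:
            raise ValueError("variances must be non-negative")
        if self.beta_variance_scale <= 0:
            raise ValueError("beta_variance_scale must be positive")
        region = self.target_region
        if region is not None:
            if region.radius < 0:
                raise ValueError("region radius must be non-negative")
            if any(
                not 0 <= c < s for c, s in zip(region.center, self.shape)
            ):
                raise ValueError("target region center must lie inside the grid")
            if min(region.sigma2_between, region.sigma2_within) < 0:
                raise ValueError("region variances must be non-negative")


@dataclass(eq=False)
class GroundTruth:
    """Population ICC map and the task-positive region mask."""

    icc_map: LabeledVolume
    region_mask: BrainMask


def _grid(config: SimulationConfig) -> VolumeGrid:
    affine = np.diag([config.voxel_mm] * 3 + [1.0])
    return VolumeGrid(shape=config.shape, affine=affine)


def _region_indicator(config: SimulationConfig) -> np.ndarray:
    region = np.zeros(config.shape, dtype=bool)
    spec = config.target_region
    if spec is not None:
        grids = np.ogrid[tuple(slice(0, s) for s in config.shape)]
        dist2 = sum((g - c) ** 2 for g, c in zip(grids, spec.center))
        region = dist2 <= spec.radius**2
    return region


def _sigma_maps(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel (sigma_b, sigma_e) std-dev maps and the region indicator."""
    region = _region_indicator(config)
    sigma_b = np.full(config.shape, np.sqrt(config.sigma2_between))
    sigma_e = np.full(config.shape, np.sqrt(config.sigma2_within))
    if config.target_region is not None:
        sigma_b[region] = np.sqrt(config.target_region.sigma2_between)
        sigma_e[region] = np.sqrt(config.target_region.sigma2_within)
    return sigma_b, sigma_e, region


def ground_truth_icc(config: SimulationConfig) -> LabeledVolume:
    """Population ICC per voxel: sigma_b^2 / (sigma_b^2 + sigma_e^2)."""
    sigma_b, sigma_e, _ = _sigma_maps(config)
    var_b, var_e = sigma_b**2, sigma_e**2
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = var_b / (var_b + var_e)
    return LabeledVolume(grid=_grid(config), data=icc, label="ground-truth icc")


def simulate_stack(
    config: SimulationConfig,
) -> tuple[MeasurementStack, GroundTruth, BrainMask]:
    """Draw a subjects x occasions stack from the two-way model.

    Subject effects are drawn independently per voxel; the occasion shift
    adds ``occasion_shift * j`` to occasion j (0-based), which perturbs
    agreement (ICC(2,1)) but, by construction, not consistency (ICC(3,1)).
    Draw order is fixed so identical seeds give identical stacks
    regardless of the shift.
    """
    grid = _grid(config)
    sigma_b, sigma_e, region = _sigma_maps(config)
    n, k = config.n_subjects, config.k_occasions
    rng = np.random.default_rng(config.seed)
    b = rng.standard_normal((n,) + config.shape) * sigma_b
    e = rng.standard_normal((n, k) + config.shape) * sigma_e

    occasions = []
    for j in range(k):
        vols = []
        for i in range(n):
            data = config.mu + config.occasion_shift * j + b[i] + e[i, j]
            vols.append(
                LabeledVolume(
                    grid=grid, data=data, label=f"sub-{i + 1:03d}_occ-{j + 1}"
                )
            )
        occasions.append(vols)
    stack = MeasurementStack(
        occasions=occasions,
        subject_ids=[f"sub-{i + 1:03d}" for i in range(n)],
    )
    mask = BrainMask(grid=grid, data=np.ones(config.shape, dtype=bool))
    region_mask = BrainMask(grid=grid, data=region, allow_empty=True)
    truth = GroundTruth(icc_map=ground_truth_icc(config), region_mask=region_mask)
    return stack, truth, mask


def simulate_effect_pairs(
    config: SimulationConfig, n_runs: int = 2
) -> list[list[EffectPair]]:
    """Per-subject per-run effect/variance map pairs for fixed-effects
    combination: betas from the two-way model (runs as occasions), variance
    maps constant at sigma_e^2 * beta_variance_scale."""
    run_config = SimulationConfig(
        shape=config.shape,
        n_subjects=config.n_subjects,
        k_occasions=max(n_runs, 2),
        mu=config.mu,
        sigma2_between=config.sigma2_between,
        sigma2_within=config.sigma2_within,
        occasion_shift=config.occasion_shift,
        target_region=config.target_region,
        beta_variance_scale=config.beta_variance_scale,
        voxel_mm=config.voxel_mm,
        seed=config.seed,
    )
    stack, _, _ = simulate_stack(run_config)
    grid = stack.grid
    _, sigma_e, _ = _sigma_maps(config)
    var_map = sigma_e**2 * config.beta_variance_scale
    pairs: list[list[EffectPair]] = []
    for i in range(config.n_subjects):
        runs = []
        for j in range(n_runs):
            beta = stack.occasions[j][i]
            variance = LabeledVolume(
                grid=grid, data=var_map.copy(), label=f"{beta.label}_var"
            )
            runs.append(EffectPair(beta=beta, variance=variance))
        pairs.append(runs)
    return pairs


def simulate_group_tmaps(
    config: SimulationConfig, effect_d: float = 1.0
) -> list[LabeledVolume]:
    """One-sample group t-maps, one per occasion.

    Inside the target region the true subject-level mean is
    ``effect_d * sqrt(sigma_b^2 + sigma_e^2)`` (so effect_d is the
    population Cohen's d there); elsewhere it is zero.  Each occasion's
    map is the one-sample t over subjects.
    """
    grid = _grid(config)
    sigma_b, sigma_e, region = _sigma_maps(config)
    mean_map = np.zeros(config.shape)
    if config.target_region is not None:
        spec = config.target_region
        sd_region = np.sqrt(spec.sigma2_between + spec.sigma2_within)
        mean_map[region] = effect_d * sd_region
    n, k = config.n_subjects, config.k_occasions
    rng = np.random.default_rng(config.seed)
    b = rng.standard_normal((n,) + config.shape) * sigma_b
    e = rng.standard_normal((n, k) + config.shape) * sigma_e

    tmaps = []
    for j in range(k):
        y = mean_map + b + e[:, j]  # (n,) + shape
        mean = y.mean(axis=0)
        sd = y.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
        tmaps.append(
            LabeledVolume(grid=grid, data=t, label=f"group-t_occ-{j + 1}")
        )
    return tmaps


def make_reference_and_atlas(
    config: SimulationConfig, z_high: float = 5.0
) -> tuple[LabeledVolume, LabeledVolume]:
    """A reference z-map exceeding 3.1 exactly on the target region, and a
    two-label integer atlas (1 = region, 2 = complement; 0 reserved for
    background)."""
    grid = _grid(config)
    region = _region_indicator(config)
    reference = np.zeros(config.shape)
    reference[region] = z_high
    atlas = np.full(config.shape, 2, dtype=float)
    atlas[region] = 1
    return (
        LabeledVolume(grid=grid, data=reference, label="synthetic-reference-z"),
        LabeledVolume(grid=grid, data=atlas, label="synthetic-atlas"),
    )


def write_fixture_tree(
    config: SimulationConfig, outdir: str | os.PathLike
) -> pd.DataFrame:
    """Write a complete on-disk fixture: per-subject per-occasion NIfTI
    maps under sub-XXX/ses-Y/, the brain mask, reference z-map, atlas,
    ground-truth ICC map and a manifest TSV (subject_id, occasion, path).

    Returns the manifest.  Deterministic given the config seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack, truth, mask = simulate_stack(config)
    reference, atlas = make_reference_and_atlas(config)

    records = []
    for j, occ in enumerate(stack.occasions, start=1):
        for sid, vol in zip(stack.subject_ids, occ):
            path = outdir / sid / f"ses-{j}" / f"{sid}_ses-{j}_contrast.nii.gz"
            path.parent.mkdir(parents=True, exist_ok=True)
            write_volume(vol, path)
            records.append({"subject_id": sid, "occasion": j, "path": str(path)})
    write_mask(mask, outdir / "brain_mask.nii.gz")
    write_volume(reference, outdir / "reference_z.nii.gz")
    write_volume(atlas, outdir / "atlas.nii.gz")
    write_volume(truth.icc_map, outdir / "ground_truth_icc.nii.gz")
    manifest = pd.DataFrame.from_records(records)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest
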