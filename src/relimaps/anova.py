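"""Variance decomposition and intraclass correlation for repeated measures.

The data unit is an ``n x k`` matrix of one measurement per subject (rows)
per occasion (columns).  A two-way crossed ANOVA with subjects random and
occasions fixed decomposes the total sum of squares into between-subject,
occasion (column) and residual components; the one-way pooled
within-subject mean square is carried alongside.  Three single-measure ICC
estimators are derived from the mean squares:

* ``icc_1``   — one-way random model, ICC(1):
  (MSBS - MSWS) / (MSBS + (k-1) MSWS)
* ``icc_2``   — two-way random, absolute agreement, ICC(2,1):
  (MSBS - MSE) / (MSBS + (k-1) MSE + k (MSC - MSE) / n)
* ``icc_3``   — two-way mixed, consistency, ICC(3,1):
  (MSBS - MSE) / (MSBS + (k-1) MSE)

Confidence bounds use F-statistic intervals: the exact F interval for
ICC(1)/ICC(3,1) and the Shrout-Fleiss approximation for ICC(2,1).
Zero-variance (degenerate) units yield NaN estimates and bounds — "no
signal" is deliberately distinct from "no consistency", and NaN values are
excluded from spatial medians downstream.

All estimators are implemented once, vectorized over a trailing unit axis,
so the scalar path and the voxelwise path share every floating-point
operation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

ICC_TYPES = ("icc_1", "icc_2", "icc_3")


@dataclass(frozen=True)
class VarianceDecomposition:
    """Mean squares of a two-way subject x occasion ANOVA on an n x k unit.

    ``ms_within_subjects`` is the one-way pooled within-subject mean square
    (occasion + residual variation); ``ms_error`` is the two-way residual.
    """

    n: int
    k: int
    ms_between_subjects: float
    ms_within_subjects: float
    ms_columns: float
    ms_error: float
    grand_mean: float


@dataclass(frozen=True)
class ICCEstimate:
    icc_type: str
    estimate: float
    lower: float
    upper: float
    alpha: float


def _validate_matrix(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError(f"expected an n x k matrix, got shape {data.shape}")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError(f"degenerate input: need n >= 2 and k >= 2, got {n} x {k}")
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite entries in data")
    return data


def mean_squares_stacked(data: np.ndarray) -> dict[str, np.ndarray]:
    """Two-way ANOVA mean squares for a batch of units.

    ``data`` has shape ``(n, k, V)``: V independent n x k units sharing the
    subject/occasion layout (V = voxels in the voxelwise application).
    Returns arrays of shape ``(V,)`` for msbs, msws, msc, mse, grand_mean.
    """
    n, k, _ = data.shape
    grand = data.mean(axis=(0, 1))
    subj_means = data.mean(axis=1)  # (n, V)
    occ_means = data.mean(axis=0)  # (k, V)
    ss_total = ((data - grand) ** 2).sum(axis=(0, 1))
    ss_subj = k * ((subj_means - grand) ** 2).sum(axis=0)
    ss_col = n * ((occ_means - grand) ** 2).sum(axis=0)
    # Residual by subtraction; clamp the tiny negatives of cancellation.
    ss_err = np.maximum(ss_total - ss_subj - ss_col, 0.0)
    ss_within = np.maximum(ss_total - ss_subj, 0.0)
    return {
        "msbs": ss_subj / (n - 1),
        "msws": ss_within / (n * (k - 1)),
        "msc": ss_col / (k - 1),
        "mse": ss_err / ((n - 1) * (k - 1)),
        "grand_mean": grand,
    }


def decompose(data: np.ndarray) -> VarianceDecomposition:
    """Two-way subject x occasion variance decomposition of one n x k unit."""
    data = _validate_matrix(data)
    n, k = data.shape
    ms = mean_squares_stacked(data[:, :, np.newaxis])
    return VarianceDecomposition(
        n=n,
        k=k,
        ms_between_subjects=float(ms["msbs"][0]),
        ms_within_subjects=float(ms["msws"][0]),
        ms_columns=float(ms["msc"][0]),
        ms_error=float(ms["mse"][0]),
        grand_mean=float(ms["grand_mean"][0]),
    )


def _check_icc_type(icc_type: str) -> None:
    if icc_type not in ICC_TYPES:
        raise ValueError(f"icc_type must be one of {ICC_TYPES}, got {icc_type!r}")


def icc_stacked(
    msbs: np.ndarray,
    msws: np.ndarray,
    msc: np.ndarray,
    mse: np.ndarray,
    n: int,
    k: int,
    icc_type: str,
) -> np.ndarray:
    """Vectorized ICC point estimates from mean squares; 0/0 yields NaN."""
    _check_icc_type(icc_type)
    with np.errstate(divide="ignore", invalid="ignore"):
        if icc_type == "icc_3":
            out = (msbs - mse) / (msbs + (k - 1) * mse)
        elif icc_type == "icc_2":
            out = (msbs - mse) / (msbs + (k - 1) * mse + k * (msc - mse) / n)
        else:  # icc_1
            out = (msbs - msws) / (msbs + (k - 1) * msws)
    return np.asarray(out, dtype=float)


def icc_from_decomposition(vd: VarianceDecomposition, icc_type: str = "icc_3") -> float:
    """Single-measure ICC point estimate from a variance decomposition."""
    value = icc_stacked(
        np.array([vd.ms_between_subjects]),
        np.array([vd.ms_within_subjects]),
        np.array([vd.ms_columns]),
        np.array([vd.ms_error]),
        vd.n,
        vd.k,
        icc_type,
    )
    return float(value[0])


def bounds_stacked(
    msbs: np.ndarray,
    msws: np.ndarray,
    msc: np.ndarray,
    mse: np.ndarray,
    n: int,
    k: int,
    icc_type: str,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized F-statistic confidence bounds on the ICC.

    icc_3: exact interval from F = MSBS/MSE on (n-1, (n-1)(k-1)) df.
    icc_1: exact interval from F = MSBS/MSWS on (n-1, n(k-1)) df.
    icc_2: Shrout-Fleiss agreement interval with Satterthwaite-style
    effective df for the occasion term.
    Degenerate units (zero error mean square) return (NaN, NaN).
    """
    _check_icc_type(icc_type)
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    q = 1.0 - alpha / 2.0

    with np.errstate(divide="ignore", invalid="ignore"):
        if icc_type in ("icc_1", "icc_3"):
            if icc_type == "icc_3":
                denom, df2 = mse, (n - 1) * (k - 1)
            else:
                denom, df2 = msws, n * (k - 1)
            df1 = n - 1
            fobs = msbs / denom
            f_l = fobs / stats.f.ppf(q, df1, df2)
            f_u = fobs * stats.f.ppf(q, df2, df1)
            lower = (f_l - 1.0) / (f_l + k - 1.0)
            upper = (f_u - 1.0) / (f_u + k - 1.0)
            bad = ~np.isfinite(fobs)
        else:
            est = icc_stacked(msbs, msws, msc, mse, n, k, "icc_2")
            fj = msc / mse
            a = k * est * fj + n * (1.0 + (k - 1.0) * est) - k * est
            vn = (k - 1.0) * (n - 1.0) * a**2
            vd_ = (n - 1.0) * k**2 * est**2 * fj**2 + (
                n * (1.0 + (k - 1.0) * est) - k * est
            ) ** 2
            v = vn / vd_
            f2u = stats.f.ppf(q, n - 1, v)
            f2l = stats.f.ppf(q, v, n - 1)
            lower = (
                n * (msbs - f2u * mse)
                / (f2u * (k * msc + (k * n - k - n) * mse) + n * msbs)
            )
            upper = (
                n * (f2l * msbs - mse)
                / (k * msc + (k * n - k - n) * mse + n * f2l * msbs)
            )
            bad = ~np.isfinite(est) | ~np.isfinite(v)

    lower = np.where(bad, np.nan, lower)
    upper = np.where(bad, np.nan, upper)
    return np.asarray(lower, dtype=float), np.asarray(upper, dtype=float)


def confidence_bounds(
    vd: VarianceDecomposition, icc_type: str = "icc_3", alpha: float = 0.05
) -> tuple[float, float]:
    """F-statistic confidence interval for a single ICC estimate."""
    lower, upper = bounds_stacked(
        np.array([vd.ms_between_subjects]),
        np.array([vd.ms_within_subjects]),
        np.array([vd.ms_columns]),
        np.array([vd.ms_error]),
        vd.n,
        vd.k,
        icc_type,
        alpha,
    )
    return float(lower[0]), float(upper[0])


def icc_scalar(
    data: np.ndarray, icc_type: str = "icc_3", alpha: float = 0.05
) -> ICCEstimate:
    """Decompose an n x k matrix and return the ICC with its F-based CI."""
    vd = decompose(data)
    estimate = icc_from_decomposition(vd, icc_type)
    lower, upper = confidence_bounds(vd, icc_type, alpha)
    return ICCEstimate(
        icc_type=icc_type, estimate=estimate, lower=lower, upper=upper, alpha=alpha
    )
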