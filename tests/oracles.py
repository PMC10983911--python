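"""Independent brute-force oracles used to check the vectorized paths.

Everything here is written with explicit loops and scalar formulas,
deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import f as f_dist
from scipy.stats import rankdata


def anova_oracle(x: np.ndarray) -> dict[str, float]:
    """Two-way crossed ANOVA mean squares by explicit cell-mean loops."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = 0.0
    for i in range(n):
        for j in range(k):
            grand += x[i, j]
    grand /= n * k
    row_means = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    ss_total = sum(
        (x[i, j] - grand) ** 2 for i in range(n) for j in range(k)
    )
    ss_subj = k * sum((m - grand) ** 2 for m in row_means)
    ss_col = n * sum((m - grand) ** 2 for m in col_means)
    ss_err = sum(
        (x[i, j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    return {
        "msbs": ss_subj / (n - 1),
        "msws": (ss_total - ss_subj) / (n * (k - 1)),
        "msc": ss_col / (k - 1),
        "mse": ss_err / ((n - 1) * (k - 1)),
        "grand_mean": grand,
        "n": n,
        "k": k,
    }


def icc_oracle(x: np.ndarray, icc_type: str) -> float:
    ms = anova_oracle(x)
    n, k = ms["n"], ms["k"]
    msbs, msws, msc, mse = ms["msbs"], ms["msws"], ms["msc"], ms["mse"]
    if icc_type == "icc_3":
        num, den = msbs - mse, msbs + (k - 1) * mse
    elif icc_type == "icc_2":
        num, den = msbs - mse, msbs + (k - 1) * mse + k * (msc - mse) / n
    elif icc_type == "icc_1":
        num, den = msbs - msws, msbs + (k - 1) * msws
    else:
        raise ValueError(icc_type)
    if den == 0:
        return float("nan")
    return num / den


def bounds_oracle(x: np.ndarray, icc_type: str, alpha: float = 0.05):
    """Scalar F-statistic confidence bounds (Shrout-Fleiss conventions)."""
    ms = anova_oracle(x)
    n, k = ms["n"], ms["k"]
    msbs, msws, msc, mse = ms["msbs"], ms["msws"], ms["msc"], ms["mse"]
    q = 1 - alpha / 2
    if icc_type in ("icc_1", "icc_3"):
        denom = mse if icc_type == "icc_3" else msws
        df2 = (n - 1) * (k - 1) if icc_type == "icc_3" else n * (k - 1)
        if denom == 0:
            return float("nan"), float("nan")
        fobs = msbs / denom
        fl = fobs / f_dist.ppf(q, n - 1, df2)
        fu = fobs * f_dist.ppf(q, df2, n - 1)
        return (fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1)
    if mse == 0 or msc == 0:
        return float("nan"), float("nan")
    icc2 = icc_oracle(x, "icc_2")
    fj = msc / mse
    a = k * icc2 * fj + n * (1 + (k - 1) * icc2) - k * icc2
    vn = (k - 1) * (n - 1) * a**2
    vd = (n - 1) * k**2 * icc2**2 * fj**2 + (
        n * (1 + (k - 1) * icc2) - k * icc2
    ) ** 2
    v = vn / vd
    f2u = f_dist.ppf(q, n - 1, v)
    f2l = f_dist.ppf(q, v, n - 1)
    lower = n * (msbs - f2u * mse) / (
        f2u * (k * msc + (k * n - k - n) * mse) + n * msbs
    )
    upper = n * (f2l * msbs - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2l * msbs
    )
    return lower, upper


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Rank correlation as Pearson correlation of average ranks."""
    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])
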