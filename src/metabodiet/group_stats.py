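"""Nonparametric inference layer: Skillings-Mack and Kruskal-Wallis omnibus
tests, Wilcoxon post-hocs, Hommel multiplicity adjustment, IQR outliers.

The Skillings-Mack test is the rank-based omnibus test for treatment
differences in (possibly incomplete) block designs; with complete balanced
data it reduces exactly to the Friedman test.  It is implemented here from
the 1981 construction: within each block the observed treatments receive
mid-ranks, the centred ranks are scaled by sqrt(12/(k_i + 1)), summed per
treatment into the vector A, and the statistic is A' Sigma^- A with the
block-structure covariance Sigma (generalised inverse; chi-square with
k - 1 degrees of freedom).  Heavily tied data can instead use the
within-block permutation null via ``method="permutation"``.

Kruskal-Wallis and the Wilcoxon tests delegate to scipy.stats behind a
uniform :class:`TestResult` surface; the Hommel adjustment delegates to
statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "BlockData",
    "skillings_mack",
    "kruskal_wallis",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "hommel_adjust",
    "iqr_outliers",
]


@dataclass
class TestResult:
    statistic: float
    df: int | None
    p: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


@dataclass
class BlockData:
    """Long-format block design: one score per (block, treatment) pair."""

    blocks: list
    treatments: list
    values: np.ndarray

    def to_table(self) -> pd.DataFrame:
        """Blocks x treatments table with NaN for missing cells."""
        df = pd.DataFrame(
            {"block": self.blocks, "treatment": self.treatments,
             "value": np.asarray(self.values, dtype=float)}
        )
        if df.duplicated(["block", "treatment"]).any():
            raise ValueError("duplicate (block, treatment) observations")
        return df.pivot(index="block", columns="treatment", values="value")


def _sm_components(table: np.ndarray):
    """Centred scaled within-block ranks (A) and covariance Sigma."""
    n_blocks, k = table.shape
    A = np.zeros(k)
    sigma = np.zeros((k, k))
    used_blocks = 0
    for i in range(n_blocks):
        observed = np.nonzero(~np.isnan(table[i]))[0]
        k_i = observed.size
        if k_i < 2:
            continue
        used_blocks += 1
        ranks = sps.rankdata(table[i, observed])  # mid-ranks
        scale = np.sqrt(12.0 / (k_i + 1))
        A[observed] += scale * (ranks - (k_i + 1) / 2.0)
        # centred scaled ranks have var k_i - 1 and pairwise cov -1
        for a_idx, j in enumerate(observed):
            sigma[j, j] += k_i - 1
            for jj in observed[a_idx + 1:]:
                sigma[j, jj] -= 1
                sigma[jj, j] -= 1
    return A, sigma, used_blocks


def skillings_mack(
    data: BlockData | pd.DataFrame | np.ndarray,
    method: str = "chi2",
    n_permutations: int = 10000,
    seed: int = 0,
) -> TestResult:
    """Skillings-Mack omnibus test for treatment effects in block designs.

    ``data`` may be a :class:`BlockData`, a blocks x treatments DataFrame,
    or a 2-D array with NaN marking missing cells.  Blocks with fewer than
    two observations are dropped with a warning.  Tie handling uses
    mid-ranks with the untied variance formula; ``method="permutation"``
    replaces the chi-square reference by a within-block permutation null.
    """
    if isinstance(data, BlockData):
        table = data.to_table().to_numpy(dtype=float)
    elif isinstance(data, pd.DataFrame):
        table = data.to_numpy(dtype=float)
    else:
        table = np.asarray(data, dtype=float)
    if table.ndim != 2 or table.shape[1] < 2:
        raise ValueError("need a blocks x treatments table with >= 2 treatments")
    incomplete = np.sum(~np.isnan(table), axis=1) < 2
    if incomplete.any():
        warnings.warn(
            f"dropping {int(incomplete.sum())} block(s) with < 2 observations"
        )
        table = table[~incomplete]
    if table.shape[0] < 2:
        raise ValueError("need >= 2 blocks with at least 2 observations each")

    k = table.shape[1]
    A, sigma, _ = _sm_components(table)
    sigma_pinv = np.linalg.pinv(sigma)
    statistic = float(A @ sigma_pinv @ A)
    statistic = max(statistic, 0.0)
    df = k - 1

    if method == "chi2":
        p = float(sps.chi2.sf(statistic, df)) if statistic > 0 else 1.0
        return TestResult(statistic, df, p, "Skillings-Mack (chi-square)")
    if method == "permutation":
        # permute scaled centred ranks within each block, vectorised over
        # draws; the covariance depends only on the missingness pattern
        rng = np.random.default_rng(seed)
        A_perm = np.zeros((n_permutations, k))
        for i in range(table.shape[0]):
            observed = np.nonzero(~np.isnan(table[i]))[0]
            k_i = observed.size
            ranks = sps.rankdata(table[i, observed])
            scaled = np.sqrt(12.0 / (k_i + 1)) * (ranks - (k_i + 1) / 2.0)
            perms = np.argsort(rng.random((n_permutations, k_i)), axis=1)
            A_perm[:, observed] += scaled[perms]
        stats_perm = np.einsum("nk,kl,nl->n", A_perm, sigma_pinv, A_perm)
        count = int(np.sum(stats_perm >= statistic - 1e-12))
        p = (count + 1) / (n_permutations + 1)
        return TestResult(statistic, df, float(p), "Skillings-Mack (permutation)")
    raise ValueError(f"unknown method: {method}")


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test across independent groups (mid-rank ties)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, df, 1.0, "Kruskal-Wallis")
    stat, p = sps.kruskal(*groups)
    return TestResult(float(stat), df, float(p), "Kruskal-Wallis")


def wilcoxon_signed_rank(differences, exact_max_n: int = 25) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Exact null distribution for n <= ``exact_max_n`` without zeros or tied
    magnitudes; normal approximation with continuity correction otherwise.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    no_ties = np.unique(np.abs(d)).size == d.size
    if d.size <= exact_max_n and no_ties:
        res = sps.wilcoxon(d, alternative="two-sided", method="exact")
        method = "Wilcoxon signed-rank (exact)"
    else:
        res = sps.wilcoxon(d, alternative="two-sided", method="approx",
                           correction=True)
        method = "Wilcoxon signed-rank (normal approximation)"
    return TestResult(float(res.statistic), None, float(res.pvalue), method)


def wilcoxon_rank_sum(a, b, exact_max_n: int = 20) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact for m + n <= ``exact_max_n`` without ties; normal approximation
    with continuity correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if a.size + b.size <= exact_max_n and no_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "Wilcoxon rank-sum (exact)"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        method = "Wilcoxon rank-sum (normal approximation)"
    return TestResult(float(res.statistic), None, float(res.pvalue), method)


def hommel_adjust(p) -> np.ndarray:
    """Hommel (1988) closed-testing adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="hommel")[1]


def iqr_outliers(values) -> np.ndarray:
    """Flag values outside 1.5 x IQR beyond the quartiles (Tukey fences).

    Quartiles use linear interpolation of order statistics (type 7); values
    exactly on a fence are not outliers.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values for IQR outlier detection")
    q1, q3 = np.quantile(v, [0.25, 0.75])  # numpy default = type 7
    iqr = q3 - q1
    return (v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)
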