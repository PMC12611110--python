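"""Mann-Kendall trend inference and the two-sample rank test.

The Mann-Kendall statistic for a series x_1..x_n is the signed concordance
sum S = sum_{i<j} sgn(x_j - x_i).  Its null variance with tie correction is

    Var(S) = [ n(n-1)(2n+5) - sum_g t_g (t_g - 1)(2 t_g + 5) ] / 18

over tie groups g of size t_g.  The standardized statistic uses a continuity
correction: Z = (S - 1)/sqrt(Var S) for S > 0, 0 for S = 0, (S + 1)/sqrt(Var S)
for S < 0.  tau is Kendall's tau-b (tie-adjusted).  For short tie-free series
(n <= 10) the p-value comes from the exact null distribution of S; otherwise
from the normal approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .errors import InsufficientDataError

EXACT_N_MAX = 10


@dataclass
class MannKendallResult:
    S: int
    var_S: float
    Z: float
    tau: float
    p: float
    n: int
    method: str                 # "exact" | "normal"
    degenerate: bool = False    # constant series (Var S = 0)


@dataclass
class RankSumResult:
    U: float
    Z: float
    p: float
    n1: int
    n2: int


def _s_and_ties(x: np.ndarray) -> tuple[int, np.ndarray]:
    diffs = np.sign(x[None, :] - x[:, None])
    S = int(np.triu(diffs, 1).sum())
    _, counts = np.unique(x, return_counts=True)
    return S, counts


def _var_s(n: int, ties: np.ndarray) -> float:
    tie_term = np.sum(ties * (ties - 1) * (2 * ties + 5))
    return (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0


def _tau_b(S: int, n: int, ties: np.ndarray) -> float:
    n0 = n * (n - 1) / 2
    nt = np.sum(ties * (ties - 1) / 2)
    denom = math.sqrt((n0 - nt) * n0)   # series index has no ties
    return S / denom if denom > 0 else 0.0


@lru_cache(maxsize=None)
def _exact_null(n: int) -> tuple[tuple[int, ...], tuple[float, ...]]:
    """Exact null pmf of S for a tie-free series of length n.

    S = n(n-1)/2 - 2 * (number of inversions); the inversion count of a
    random permutation is the convolution of uniform{0..k} for k = 1..n-1
    (the standard recursion), so the pmf follows without enumerating n!.
    """
    counts = np.array([1.0])
    for k in range(1, n):
        counts = np.convolve(counts, np.ones(k + 1))
    probs = counts / counts.sum()
    smax = n * (n - 1) // 2
    s_vals = smax - 2 * np.arange(len(counts))
    return tuple(int(s) for s in s_vals), tuple(float(p) for p in probs)


def mk_exact_null(n: int) -> dict[int, float]:
    """Exact null distribution of S (tie-free) as a dict S -> probability."""
    if not 3 <= n <= EXACT_N_MAX:
        raise InsufficientDataError(f"exact null requires 3 <= n <= {EXACT_N_MAX}")
    s_vals, probs = _exact_null(n)
    return dict(zip(s_vals, probs))


def _exact_p(S: int, n: int) -> float:
    s_vals, probs = _exact_null(n)
    if S == 0:
        return 1.0
    tail = sum(p for s, p in zip(s_vals, probs) if s >= abs(S))
    return min(1.0, 2.0 * tail)


def mann_kendall(x, method: str = "auto") -> MannKendallResult:
    """Mann-Kendall trend test on an ordered series.

    ``method``: "auto" (exact when n <= 10 and tie-free), "exact", "normal".
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 observations, got {n}")
    if np.isnan(x).any():
        raise InsufficientDataError("series contains missing values")
    S, ties = _s_and_ties(x)
    var_S = _var_s(n, ties)
    tau = _tau_b(S, n, ties)
    if var_S <= 0:      # constant series
        return MannKendallResult(S=S, var_S=0.0, Z=0.0, tau=0.0, p=1.0,
                                 n=n, method="normal", degenerate=True)
    if S > 0:
        Z = (S - 1) / math.sqrt(var_S)
    elif S < 0:
        Z = (S + 1) / math.sqrt(var_S)
    else:
        Z = 0.0
    tie_free = len(ties) == n
    if method == "auto":
        method = "exact" if (tie_free and n <= EXACT_N_MAX) else "normal"
    if method == "exact":
        if not tie_free:
            raise InsufficientDataError("exact method requires a tie-free series")
        if n > EXACT_N_MAX:
            raise InsufficientDataError(f"exact method limited to n <= {EXACT_N_MAX}")
        p = _exact_p(S, n)
    else:
        p = 2.0 * (1.0 - stats.norm.cdf(abs(Z)))
    return MannKendallResult(S=S, var_S=var_S, Z=Z, tau=tau, p=p, n=n,
                             method=method)


def wilcoxon_rank_sum(a, b) -> RankSumResult:
    """Wilcoxon-Mann-Whitney two-sample test (midranks, tie and continuity
    corrected normal approximation, two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise InsufficientDataError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    U = float(res.statistic)
    # z recomputed from U with midrank tie correction for the result fields
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    mean_U = n1 * n2 / 2.0
    if sigma2 <= 0:
        return RankSumResult(U=U, Z=0.0, p=1.0, n1=n1, n2=n2)
    num = U - mean_U
    num -= math.copysign(0.5, num) if num != 0 else 0.0
    Z = num / math.sqrt(sigma2)
    return RankSumResult(U=U, Z=Z, p=float(res.pvalue), n1=n1, n2=n2)


def regional_trend_table(rates, lattice, value: str = "smoothed_rate",
                         method: str = "auto"):
    """Mann-Kendall per admin_block and indicator on yearly block-mean rates.

    ``rates`` is a RatePanel frame; the series for each (block, indicator)
    is the yearly mean of ``value`` across the block's regions.  Returns a
    tidy frame: admin_block, indicator, n_regions, tau, S, Z, p, method.
    """
    import pandas as pd
    import warnings

    block_of = dict(zip(lattice.region_ids, lattice.admin_blocks))
    df = rates.copy()
    df["admin_block"] = df["region_id"].map(block_of)
    if df["admin_block"].isna().any():
        missing = df.loc[df["admin_block"].isna(), "region_id"].iloc[0]
        raise InsufficientDataError(f"region {missing} not in lattice")
    rows = []
    for (block, ind), grp in df.groupby(["admin_block", "indicator"]):
        series = grp.groupby("year")[value].mean().sort_index()
        if len(series) < 3:
            warnings.warn(f"block {block}: fewer than 3 years, skipped",
                          stacklevel=2)
            continue
        res = mann_kendall(series.to_numpy(), method=method)
        rows.append({"admin_block": block, "indicator": ind,
                     "n_regions": grp["region_id"].nunique(),
                     "tau": res.tau, "S": res.S, "Z": res.Z, "p": res.p,
                     "method": res.method})
    return pd.DataFrame(rows)
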