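"""Nonparametric statistics for small ablation series.

Group comparisons follow the study protocol: two-sided Mann–Whitney U for
two groups, Kruskal–Wallis for more, and a Bonferroni-corrected
significance level of alpha = 0.05/6 ≈ 0.008 with p in (0.008, 0.05]
read as a trend. At the study's n = 6 per group the Mann–Whitney test is
computed *exactly* — the null distribution of U is enumerated over all
C(n+m, n) group assignments of the pooled midranks (ties handled by
midranks), not approximated. A small LOESS smoother (tricube weights,
local degree 1 or 2) fits cooling-type profiles on an explicit grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.stats as sps

from .errors import DataError, FittingError, ParameterError

__all__ = [
    "StatResult",
    "LoessFit",
    "bonferroni_verdict",
    "mann_whitney_u",
    "kruskal_wallis",
    "loess_fit",
]

TREND_ALPHA = 0.05
DEFAULT_N_COMPARISONS = 6  # each perfused flow rate vs 0 ml/min within one distance


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    group_labels: tuple[str, ...]
    n_per_group: tuple[int, ...]
    verdict: str
    method: str = ""


@dataclass
class LoessFit:
    x_grid: np.ndarray
    fitted: np.ndarray
    span: float
    degree: int
    kernel: str = "tricube"


def bonferroni_verdict(p: float, n_comparisons: int = DEFAULT_N_COMPARISONS) -> str:
    """Classify a p-value as significant / trend / not_significant.

    ``alpha_sig = 0.05 / n_comparisons``; with the default divisor 6 this
    is ≈ 0.0083, so a printed p = 0.008 is significant and p = 0.05 is a
    trend.
    """
    if not (0.0 <= p <= 1.0):
        raise DataError(f"p-value {p!r} outside [0, 1]")
    if n_comparisons < 1:
        raise ParameterError("n_comparisons must be >= 1")
    alpha_sig = TREND_ALPHA / n_comparisons
    if p <= alpha_sig:
        return "significant"
    if p <= TREND_ALPHA:
        return "trend"
    return "not_significant"


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def _exact_u_distribution(ranks2: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of 2*R_x over all size-n subsets of the pooled midranks.

    ``ranks2`` are doubled midranks (integers). Returns (support, counts)
    via subset-sum dynamic programming; counts are exact (< 2^53 for the
    sample sizes where the exact method is selected).
    """
    total = int(ranks2.sum())
    # dp[k, s] = number of k-subsets with doubled-rank sum s
    dp = np.zeros((n + 1, total + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for k in range(n, 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    support = np.nonzero(dp[n] > 0)[0]
    return support, dp[n][support]


def _two_sided_p(support: np.ndarray, counts: np.ndarray, u2_obs: float, nm2: int) -> float:
    """Two-sided tail probability of U (doubled units), symmetric about nm/2."""
    u2_lo = min(u2_obs, nm2 - u2_obs)
    u2_hi = max(u2_obs, nm2 - u2_obs)
    total = counts.sum()
    p = (counts[support <= u2_lo + 1e-9].sum() + counts[support >= u2_hi - 1e-9].sum()) / total
    return float(min(1.0, p))


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
    n_comparisons: int = DEFAULT_N_COMPARISONS,
    labels: tuple[str, str] = ("x", "y"),
) -> StatResult:
    """Two-sided Mann–Whitney U test.

    ``method`` is ``"exact"`` (full enumeration of the tied-rank null
    distribution), ``"normal-approx"`` (tie-corrected normal
    approximation with continuity correction, via scipy), or ``"auto"``
    (exact when min(n, m) <= 8).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise DataError("mann_whitney_u: both samples must be non-empty")
    if method not in ("auto", "exact", "normal-approx"):
        raise ParameterError(f"unknown method {method!r}")
    n, m = xa.size, ya.size
    use_exact = method == "exact" or (method == "auto" and min(n, m) <= 8)
    ranks = _midranks(np.concatenate([xa, ya]))
    r_x = float(ranks[:n].sum())
    u_obs = r_x - n * (n + 1) / 2.0
    if use_exact:
        ranks2 = np.rint(2.0 * ranks).astype(int)  # doubled midranks are integers
        support, counts = _exact_u_distribution(ranks2, n)
        # convert doubled rank-sum support to doubled-U support
        u2_support = support - n * (n + 1)
        p = _two_sided_p(u2_support, counts, 2.0 * u_obs, 2 * n * m)
        how = "exact"
    else:
        res = sps.mannwhitneyu(xa, ya, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        how = "normal-approx"
    return StatResult(
        test_name="mann_whitney_u",
        statistic=float(u_obs),
        p_value=p,
        group_labels=labels,
        n_per_group=(n, m),
        verdict=bonferroni_verdict(p, n_comparisons),
        method=how,
    )


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    labels: Optional[tuple[str, ...]] = None,
    n_comparisons: int = 1,
) -> StatResult:
    """Kruskal–Wallis H test (tie-corrected), p from chi-square with k-1 df."""
    if len(groups) < 2:
        raise DataError("kruskal_wallis: need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise DataError("kruskal_wallis: empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0  # complete ties: no evidence against homogeneity
    else:
        h, p = sps.kruskal(*arrays)
    if labels is None:
        labels = tuple(f"group{i}" for i in range(len(arrays)))
    return StatResult(
        test_name="kruskal_wallis",
        statistic=float(h),
        p_value=float(p),
        group_labels=labels,
        n_per_group=tuple(a.size for a in arrays),
        verdict=bonferroni_verdict(float(p), n_comparisons),
        method="chi2",
    )


def loess_fit(
    x: Sequence[float],
    y: Sequence[float],
    span: float = 0.5,
    degree: int = 1,
    grid: Optional[Sequence[float]] = None,
    n_grid: int = 100,
) -> LoessFit:
    """Locally weighted polynomial regression (LOESS) on an explicit grid.

    At each grid point the ``ceil(span * n)`` nearest observations are
    fitted with a degree-``degree`` polynomial under tricube weights
    ``(1 - (d/dmax)^3)^3``.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or xa.shape != ya.shape:
        raise DataError("loess_fit: x and y must be 1-D arrays of equal length")
    if xa.size < degree + 2:
        raise DataError(f"loess_fit: need at least degree + 2 = {degree + 2} points")
    if not (0.0 < span <= 1.0):
        raise ParameterError("loess_fit: span must lie in (0, 1]")
    if degree not in (1, 2):
        raise ParameterError("loess_fit: degree must be 1 or 2")
    if grid is None:
        grid = np.linspace(xa.min(), xa.max(), n_grid)
    else:
        grid = np.asarray(grid, dtype=float)
    k = max(degree + 1, int(math.ceil(span * xa.size)))
    k = min(k, xa.size)
    fitted = np.empty_like(grid)
    for i, x0 in enumerate(grid):
        d = np.abs(xa - x0)
        idx = np.argpartition(d, k - 1)[:k]
        dloc = d[idx]
        dmax = dloc.max()
        if dmax == 0:
            fitted[i] = float(ya[idx].mean())
            continue
        w = np.clip(1.0 - (dloc / dmax) ** 3, 0.0, None) ** 3
        # boundary points carry weight 0; keep a vestigial weight if the
        # window would otherwise be rank-deficient
        if np.count_nonzero(w) < degree + 1:
            w = np.maximum(w, 1e-9)
        xs = xa[idx] - x0
        design = np.vander(xs, degree + 1, increasing=True)
        sw = np.sqrt(w)
        beta, _, rank, _ = np.linalg.lstsq(design * sw[:, None], ya[idx] * sw, rcond=None)
        if rank < degree + 1:
            raise FittingError(f"loess_fit: degenerate window at grid point {x0:g}")
        fitted[i] = float(beta[0])
    return LoessFit(x_grid=np.asarray(grid), fitted=fitted, span=span, degree=degree)
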