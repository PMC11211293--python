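"""Agreement and comparison statistics for cohort volumetry reports.

Implements the statistical toolkit used to compare segmentation methods and
volumetry settings: Bland–Altman analysis with 95% limits of agreement,
the exact (binomial) McNemar test for paired binary decisions, the
Mann–Whitney U test (exact permutation enumeration for small samples,
tie/continuity-corrected normal approximation otherwise), the
Kruskal–Wallis omnibus test for subgroup comparisons, and Wald confidence
intervals for classification-accuracy proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 95% limits of agreement for paired measurements."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    p_bias: float
    n: int


@dataclass(frozen=True)
class McNemarResult:
    """Exact McNemar test on the discordant counts of a paired 2x2 table."""

    b: int
    c: int
    p: float


@dataclass(frozen=True)
class RankTestResult:
    """Outcome of a rank-based test (Mann–Whitney U or Kruskal–Wallis H)."""

    statistic: float
    p: float
    group_sizes: tuple[int, ...]

    @property
    def n1(self) -> int:
        return self.group_sizes[0]

    @property
    def n2(self) -> int:
        return self.group_sizes[1]


_LOA_Z = 1.96  # conventional 95% limits-of-agreement multiplier


def bland_altman(pairs: Iterable[tuple[float, float]]) -> BlandAltmanResult:
    """Bland–Altman agreement between two measurement methods.

    ``pairs`` holds (a, m) measurements of the same quantity; differences are
    d = a − m.  Bias is the mean difference, the limits of agreement are
    bias ± 1.96·SD(d) with the sample (n−1) standard deviation, and the bias
    p-value comes from a two-sided one-sample t-test of d against zero.  A
    zero-variance difference set returns p_bias = 1 (no evidence of bias
    beyond the constant offset itself being reported as the bias).
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (a, m) tuples")
    n = arr.shape[0]
    if n < 3:
        raise ValueError(f"Bland-Altman needs at least 3 pairs, got {n}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("pairs must be finite")
    d = arr[:, 0] - arr[:, 1]
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        p = 1.0
    else:
        p = float(sps.ttest_1samp(d, 0.0).pvalue)
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - _LOA_Z * sd,
        loa_high=bias + _LOA_Z * sd,
        p_bias=p,
        n=n,
    )


def mcnemar_exact(b: int, c: int) -> McNemarResult:
    """Exact two-sided McNemar test from the discordant counts b, c.

    Under the null the smaller discordant count is Binomial(b+c, 1/2);
    p = min(1, 2·P(X ≤ min(b, c))).  With no discordant pairs p = 1.
    """
    b, c = int(b), int(c)
    if b < 0 or c < 0:
        raise ValueError(f"discordant counts must be non-negative, got ({b}, {c})")
    n = b + c
    if n == 0:
        return McNemarResult(b=b, c=c, p=1.0)
    p = min(1.0, 2.0 * float(sps.binom.cdf(min(b, c), n, 0.5)))
    return McNemarResult(b=b, c=c, p=p)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x against y with midrank ties."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[: len(x)].sum())
    return r1 - len(x) * (len(x) + 1) / 2.0


_EXACT_LIMIT = 20  # pooled size up to which the permutation null is enumerated


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> RankTestResult:
    """Two-sided Mann–Whitney U test.

    For pooled sample sizes up to 20 the permutation null is enumerated
    exactly (all group-1 index subsets; midranks handle ties, so the
    enumeration remains exact in their presence), with a two-sided p-value
    P(|U' − n1·n2/2| ≥ |U − n1·n2/2|).  Larger samples use the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(x, y)
    if n1 + n2 <= _EXACT_LIMIT:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        offset = n1 * (n1 + 1) / 2.0
        center = n1 * n2 / 2.0
        observed = abs(u - center)
        hits = total = 0
        for idx in combinations(range(n1 + n2), n1):
            u_perm = ranks[list(idx)].sum() - offset
            total += 1
            if abs(u_perm - center) >= observed - 1e-12:
                hits += 1
        p = hits / total
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return RankTestResult(statistic=float(u), p=min(1.0, float(p)), group_sizes=(n1, n2))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> RankTestResult:
    """Kruskal–Wallis H test with tie correction and chi-square p-value.

    Degenerate input in which every observation is identical yields H = 0 and
    p = 1 rather than an error.
    """
    arrs = [np.asarray(list(g), dtype=float) for g in groups]
    arrs = [a for a in arrs if len(a)]
    if len(arrs) < 2:
        raise ValueError("need at least 2 non-empty groups")
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return RankTestResult(statistic=0.0, p=1.0, group_sizes=tuple(len(a) for a in arrs))
    h, p = sps.kruskal(*arrs)
    return RankTestResult(statistic=float(h), p=float(p), group_sizes=tuple(len(a) for a in arrs))


def wald_ci(k: int, n: int) -> tuple[float, float]:
    """Wald 95% confidence interval for a proportion, in percent, clipped to [0, 100].

    Degenerate at the boundaries (k = 0 or k = n gives a zero-width interval),
    which is the known Wald pathology; kept because accuracy tables in this
    domain are conventionally reported with Wald intervals.
    """
    k, n = int(k), int(n)
    if n < 1 or k < 0 or k > n:
        raise ValueError(f"invalid counts k={k}, n={n}")
    phat = k / n
    half = _LOA_Z * math.sqrt(phat * (1.0 - phat) / n)
    low = max(0.0, 100.0 * (phat - half))
    high = min(100.0, 100.0 * (phat + half))
    return (low, high)
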