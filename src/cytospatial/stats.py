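"""Exact nonparametric tests shared across the pipeline.

All group comparisons in the pipeline are rank-based: the two-sample
Wilcoxon rank-sum test (patient-level IE1 vs IE2 comparisons, LR-score
enrichment), the paired Wilcoxon signed-rank test (paired per-patient
fractions), and Spearman rank correlation (signature-score agreement).
For the small patient cohorts this pipeline targets, exact null
distributions are used; large inputs fall back to the standard
asymptotic approximations.

Two-sided p-values are defined as the null probability of a statistic at
least as far from its null mean as the observed one (with a small
tolerance on the comparison so mid-rank ties do not flip counts through
floating-point noise).
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
from scipy import stats as sps

from .core import DomainError

_TIE_TOL = 1e-9


def rank_sum_test(x, y, exact_limit: int = 10, max_enum: int = 250_000) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two independent samples.

    Exact by enumeration of all label assignments when both group sizes are
    ≤ ``exact_limit`` (mid-ranks for ties); otherwise the normal
    approximation with tie correction via :func:`scipy.stats.mannwhitneyu`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DomainError("rank_sum_test requires non-empty groups")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n, N = x.size, pooled.size
    obs = ranks[:n].sum()
    mu = n * (N + 1) / 2.0
    dev = abs(obs - mu)
    if min(n, N - n) <= exact_limit and math.comb(N, n) <= max_enum:
        idx = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(N), n)),
            dtype=np.intp,
        ).reshape(-1, n)
        sums = ranks[idx].sum(axis=1)
        p = float(np.mean(np.abs(sums - mu) >= dev - _TIE_TOL))
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(
                sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            )
    return min(p, 1.0)


def signed_rank_test(diffs, exact_limit: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired differences.

    Zero differences are dropped (Wilcoxon convention). If every
    difference is zero the test is undefined and ``1.0`` is returned with
    a warning. Exact for ``n ≤ exact_limit`` via dynamic programming over
    the distribution of the signed-rank sum (equivalent to enumerating all
    2^n sign assignments); normal approximation beyond.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; signed-rank p undefined, reporting 1")
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    # doubled ranks are integers even with mid-rank ties
    r2 = np.rint(2 * ranks).astype(np.int64)
    obs2 = int(np.rint(2 * ranks[d > 0].sum()))
    total = int(r2.sum())
    if n <= exact_limit:
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for w in r2:
            shifted = np.zeros_like(dist)
            shifted[w:] = dist[: dist.size - w]
            dist = 0.5 * (dist + shifted)
        mu = total / 2.0
        dev = abs(obs2 - mu)
        support = np.arange(total + 1)
        p = float(dist[np.abs(support - mu) >= dev - _TIE_TOL].sum())
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(sps.wilcoxon(d, alternative="two-sided", method="approx").pvalue)
    return min(p, 1.0)


def spearman_corr(x, y, exact_limit: int = 9) -> tuple[float, float]:
    """Spearman rank correlation with a two-tailed p-value.

    Exact p by full enumeration of rank permutations for ``n ≤
    exact_limit``; t-approximation otherwise. Constant input yields
    ``(nan, nan)`` (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    n = x.size
    if n < 3:
        return (float("nan"), float("nan"))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    rho = float(sps.spearmanr(x, y).statistic)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if n <= exact_limit:
        obs = float(rx @ ry)
        mu = n * ((n + 1) / 2.0) ** 2
        perms = np.array(list(itertools.permutations(ry)))
        sums = perms @ rx
        p = float(np.mean(np.abs(sums - mu) >= abs(obs - mu) - _TIE_TOL))
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return rho, min(p, 1.0)
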