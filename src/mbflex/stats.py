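"""Rank-based hypothesis tests and Bonferroni-Holm multiple-comparison
correction, matching the conventions of the figure-level statistics: paired
comparisons use the Wilcoxon signed-rank test, independent groups the
Wilcoxon rank-sum (Mann-Whitney) test, all two-sided, with exact small-sample
nulls where feasible and Holm correction within an explicit comparison
family.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "holm_correction",
    "paired_signed_rank",
    "independent_rank_sum",
    "apply_family_correction",
]


@dataclass
class StatResult:
    test: str
    n1: int
    n2: int
    statistic: float
    p: float
    p_adjusted: float | None = None
    family: str | None = None


def holm_correction(p_values) -> np.ndarray:
    """Step-down Bonferroni-Holm adjustment, order-preserving.

    The i-th smallest raw p is multiplied by (m - i) and a running maximum
    enforces monotonicity; results are capped at 1 and returned in the input
    order. Guarantees raw <= adjusted <= min(1, m * raw).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be a 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adjusted[idx] = running
    return adjusted


def _warn_small(n: int) -> None:
    if n < 5:
        warnings.warn(f"small sample (n={n}); rank-test p-values are coarse")


def paired_signed_rank(x, y) -> StatResult:
    """Two-sided paired-sample Wilcoxon signed-rank test.

    Uses the exact null for n <= 8 pairs (no ties or zero differences),
    otherwise the normal approximation with continuity correction. Identical
    samples carry no signal and return p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired test requires equal-length samples")
    n = x.size
    _warn_small(n)
    d = x - y
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; no signal, p = 1")
        return StatResult("signed-rank", n, n, 0.0, 1.0)
    nz = d[d != 0]
    exact_ok = (
        nz.size <= 8
        and np.unique(np.abs(nz)).size == nz.size
        and nz.size == n
    )
    if exact_ok:
        res = sps.wilcoxon(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.wilcoxon(
            x, y, alternative="two-sided", method="approx", correction=True
        )
    return StatResult("signed-rank", n, n, float(res.statistic), float(res.pvalue))


def independent_rank_sum(x, y) -> StatResult:
    """Two-sided independent-sample Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact null when both groups have n <= 8 and there are no ties, otherwise
    the continuity-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _warn_small(min(x.size, y.size))
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (max(x.size, y.size) <= 8 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return StatResult(
        "rank-sum", x.size, y.size, float(res.statistic), float(res.pvalue)
    )


def apply_family_correction(results: list[StatResult], family: str) -> list[StatResult]:
    """Holm-adjust the raw p-values of one comparison family in place."""
    adjusted = holm_correction([r.p for r in results])
    for r, a in zip(results, adjusted):
        r.p_adjusted = float(a)
        r.family = family
    return results
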