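"""Nonparametric statistical toolkit shared by the three analyses.

Wilcoxon rank-sum and matched-pair signed-rank tests, the Kruskal-Wallis
test, Cohen's d, Benjamini-Hochberg step-up FDR control, and a seeded
percentile bootstrap for Pearson's correlation.  Rank-test p-values are
exact (full enumeration) for small tie-free samples and switch to the
tie-corrected, continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "FDRResult",
    "rank_sum_test",
    "signed_rank_test",
    "kruskal_wallis",
    "cohens_d",
    "bh_fdr",
    "bootstrap_pearson",
]

log = logging.getLogger(__name__)

#: largest per-group size for which the rank-sum p is computed exactly
EXACT_RANKSUM_MAX_N = 10
#: largest number of non-zero pairs for which the signed-rank p is exact
EXACT_SIGNEDRANK_MAX_N = 12


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # "ranksum" | "signedrank" | "kruskal"
    n_per_group: tuple[int, ...]
    exact: bool = False


@dataclass(frozen=True)
class FDRResult:
    q: float
    p_values: np.ndarray
    rejected: np.ndarray
    threshold_p: float


def _check_sample(x: np.ndarray, name: str, min_n: int = 2) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < min_n:
        raise ValueError(f"sample {name} needs at least {min_n} values")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"sample {name} contains non-finite values")
    return x


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both groups have <= 10 observations and there
    are no ties; otherwise the normal approximation with tie correction
    and continuity correction.
    """
    x = _check_sample(x, "x")
    y = _check_sample(y, "y")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    exact = (
        x.size <= EXACT_RANKSUM_MAX_N and y.size <= EXACT_RANKSUM_MAX_N and not ties
    )
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="ranksum",
        n_per_group=(x.size, y.size),
        exact=exact,
    )


def signed_rank_test(
    paired_a: Sequence[float], paired_b: Sequence[float]
) -> TestResult:
    """Two-sided Wilcoxon matched-pair signed-rank test.

    Zero differences are dropped; exact enumeration of sign patterns for
    <= 12 non-zero pairs without tied absolute differences, else the
    continuity-corrected normal approximation.
    """
    a = _check_sample(paired_a, "a")
    b = _check_sample(paired_b, "b")
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences zero")
    abs_ties = np.unique(np.abs(d)).size < d.size
    exact = d.size <= EXACT_SIGNEDRANK_MAX_N and not abs_ties
    res = sps.wilcoxon(
        d, alternative="two-sided",
        method="exact" if exact else "approx",
        correction=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="signedrank",
        n_per_group=(d.size,),
        exact=exact,
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected, chi-squared p, g-1 df)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [_check_sample(g, f"group {i}") for i, g in enumerate(groups)]
    res = sps.kruskal(*arrays)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="kruskal",
        n_per_group=tuple(a.size for a in arrays),
        exact=False,
    )


def cohens_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Cohen's d with the pooled (n1 + n2 - 2)-denominator standard deviation."""
    x = _check_sample(x, "x")
    y = _check_sample(y, "y")
    n1, n2 = x.size, y.size
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if s2 <= 0:
        raise ValueError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / np.sqrt(s2))


def bh_fdr(p_values: Sequence[float], q: float = 0.05) -> FDRResult:
    """Benjamini-Hochberg step-up procedure at level q.

    Rejects all hypotheses with p <= p_(i*), i* = max{i : p_(i) <= i q / m};
    the empty set when no i qualifies.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    order = np.sort(p)
    ok = order <= (np.arange(1, m + 1) * q / m)
    if ok.any():
        threshold = float(order[np.flatnonzero(ok).max()])
        rejected = p <= threshold
    else:
        threshold = 0.0
        rejected = np.zeros(m, dtype=bool)
    return FDRResult(q=q, p_values=p, rejected=rejected, threshold_p=threshold)


def bootstrap_pearson(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Sample Pearson r with a seeded percentile bootstrap 95% interval.

    Pairs are resampled with replacement ``n_boot`` times; resamples where
    either vector is constant (r undefined) are skipped and logged.
    """
    x = _check_sample(x, "x", min_n=3)
    y = _check_sample(y, "y", min_n=3)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector: correlation undefined")
    rng = np.random.default_rng(seed)
    n = x.size
    r = float(np.corrcoef(x, y)[0, 1])
    idx = rng.integers(0, n, size=(n_boot, n))
    bx, by = x[idx], y[idx]
    sx = bx.std(axis=1)
    sy = by.std(axis=1)
    valid = (sx > 0) & (sy > 0)
    if (~valid).any():
        log.info("bootstrap_pearson: skipped %d degenerate resamples",
                 int((~valid).sum()))
    if not valid.any():
        raise ValueError("all bootstrap resamples degenerate")
    cov = ((bx - bx.mean(axis=1, keepdims=True))
           * (by - by.mean(axis=1, keepdims=True))).mean(axis=1)
    rs = cov[valid] / (sx[valid] * sy[valid])
    lo, hi = np.percentile(rs, [2.5, 97.5])
    return r, float(lo), float(hi)
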