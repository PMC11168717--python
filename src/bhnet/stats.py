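"""Nonparametric group comparisons with Monte Carlo confirmation.

Wilcoxon signed-rank (paired) and rank-sum (unpaired) tests report a
signed, tie-corrected normal-approximation Z statistic (Z > 0 means
Condition 2 > Condition 1) together with a two-sided p-value; the p-value
is exact (full enumeration) for small tie-free samples and uses the normal
approximation otherwise. Spearman correlations report the rank-Pearson
coefficient with the Student-t approximation p-value (n - 2 degrees of
freedom). Any significant analytic result can be confirmed by a Monte
Carlo permutation test: p_mc is the proportion of permuted effect
magnitudes at least as large as the observed one, out of ``n_perm``
(default 1,000) random permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as st

from .errors import InsufficientDataError

__all__ = [
    "ComparisonResult",
    "CorrelationResult",
    "wilcoxon_paired",
    "wilcoxon_unpaired",
    "spearman",
    "monte_carlo_confirm",
    "benjamini_hochberg",
]

#: Largest tie-free sample size at which signed-rank p is computed exactly.
EXACT_N_MAX = 25


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sample comparison; Z > 0 indicates Condition 2 > Condition 1."""

    statistic_Z: float
    p: float
    n1: int
    n2: int
    paired: bool
    p_mc: float = None
    n_perm: int = 0


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int
    p_mc: float = None
    n_perm: int = 0


def _signed_rank_z(d: np.ndarray) -> float:
    """Tie-corrected normal-approximation Z of the signed-rank statistic."""
    n = d.size
    ranks = st.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    tie_counts = np.bincount(st.rankdata(np.abs(d), method="dense").astype(int))
    tie_term = np.sum(tie_counts**3 - tie_counts) / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    if sigma == 0:
        return 0.0
    return (w_plus - mu) / sigma


def wilcoxon_paired(a, b) -> ComparisonResult:
    """Wilcoxon signed-rank test of paired samples (b vs. a).

    Zero differences are dropped. Z is signed so that Z > 0 indicates
    b > a.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 5:
        raise InsufficientDataError("need >= 5 pairs")
    d = b - a
    d = d[d != 0]
    if d.size == 0:
        raise InsufficientDataError("all paired differences are zero")
    z = _signed_rank_z(d)
    has_ties = np.unique(np.abs(d)).size < d.size
    if d.size <= EXACT_N_MAX and not has_ties:
        p = float(st.wilcoxon(d, method="exact", alternative="two-sided").pvalue)
    else:
        p = float(2 * st.norm.sf(abs(z)))
    return ComparisonResult(
        statistic_Z=float(z), p=min(p, 1.0), n1=a.size, n2=b.size, paired=True
    )


def _rank_sum_z(a: np.ndarray, b: np.ndarray) -> float:
    """Tie-corrected normal-approximation Z of b's rank sum vs. a."""
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = st.rankdata(pooled)
    w = float(ranks[n1:].sum())  # rank sum of sample b
    mu = n2 * (n1 + n2 + 1) / 2.0
    n = n1 + n2
    tie_counts = np.bincount(st.rankdata(pooled, method="dense").astype(int))
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((n) * (n - 1))
    sigma = np.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
    if sigma == 0:
        return 0.0
    return (w - mu) / sigma


def wilcoxon_unpaired(a, b) -> ComparisonResult:
    """Wilcoxon rank-sum (Mann-Whitney) test of independent samples.

    Z > 0 indicates sample b stochastically larger than sample a.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 4 or b.size < 4:
        raise InsufficientDataError("need >= 4 observations per group")
    z = _rank_sum_z(a, b)
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and a.size + b.size <= 30:
        p = float(
            st.mannwhitneyu(b, a, method="exact", alternative="two-sided").pvalue
        )
    else:
        p = float(2 * st.norm.sf(abs(z)))
    return ComparisonResult(
        statistic_Z=float(z), p=min(p, 1.0), n1=a.size, n2=b.size, paired=False
    )


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with the t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 5:
        raise InsufficientDataError("need >= 5 observations")
    rx = st.rankdata(x)
    ry = st.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2 * st.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho=rho, p=p, n=n)


def _paired_effect(a, b):
    return abs(_signed_rank_z(np.asarray(b) - np.asarray(a)))


def _unpaired_effect(a, b):
    return abs(_rank_sum_z(np.asarray(a), np.asarray(b)))


def _correlation_effect(x, y):
    return abs(spearman(x, y).rho)


def monte_carlo_confirm(
    scheme: str,
    a,
    b,
    n_perm: int = 1000,
    seed: int = 0,
    effect_fn=None,
) -> float:
    """Permutation p-value for the magnitude of a test effect.

    ``scheme`` selects the exchangeability structure: ``'paired'`` flips
    the sign of each paired difference, ``'unpaired'`` shuffles the group
    labels, ``'correlation'`` shuffles one member of each (x, y) pair.
    p_mc = #{permuted |effect| >= observed |effect|} / n_perm; significance
    is confirmed when p_mc < 0.05, and p_mc = 0 is conventionally reported
    as p < 0.001 at the default 1,000 permutations.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    rng = np.random.default_rng(seed)
    if scheme == "paired":
        effect = effect_fn or (lambda d: abs(_signed_rank_z(d)))
        d = b - a
        d = d[d != 0]
        obs = effect(d)
        count = 0
        for _ in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=d.size)
            if effect(d * signs) >= obs - 1e-12:
                count += 1
    elif scheme == "unpaired":
        effect = effect_fn or _unpaired_effect
        obs = effect(a, b)
        pooled = np.concatenate([a, b])
        n1 = a.size
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if effect(perm[:n1], perm[n1:]) >= obs - 1e-12:
                count += 1
    elif scheme == "correlation":
        effect = effect_fn or _correlation_effect
        obs = effect(a, b)
        count = 0
        for _ in range(n_perm):
            if effect(a, rng.permutation(b)) >= obs - 1e-12:
                count += 1
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    return count / n_perm


def benjamini_hochberg(p_values, alpha: float = 0.05) -> np.ndarray:
    """BH step-up rejection mask (optional; the default analysis reports
    uncorrected p-values for the 24 couplings, with confirmation left to
    the permutation test)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if passed.any():
        kmax = np.max(np.flatnonzero(passed))
        reject[order[: kmax + 1]] = True
    return reject
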