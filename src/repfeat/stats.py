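"""Rank-based group comparison and PCA, from the defining formulas.

The inferential toolkit of the repertoire comparison: the Kruskal–Wallis
omnibus test on three cohorts, Dunn's pairwise post-hoc z-tests with
Benjamini–Hochberg FDR adjustment, the Wilcoxon rank-sum test for two-group
contrasts, and PCA over the repertoire feature matrix.  The rank statistics
are implemented directly (midranks, tie corrections, exact small-sample
Wilcoxon enumeration); only chi-square and normal tail probabilities come
from standard special-function routines.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import chdtrc, ndtr

__all__ = [
    "midranks",
    "kruskal_wallis",
    "dunn_pairwise",
    "benjamini_hochberg",
    "wilcoxon_rank_sum",
    "pca",
    "GroupTestResult",
    "PairwiseResult",
    "PCAResult",
    "compare_groups",
]


def midranks(x: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with ties sharing their average (mid) rank."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    t = counts.astype(float)
    return float(np.sum(t**3 - t))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction and chi-square p-value.

    H = [12/(N(N+1))] * sum n_i (Rbar_i - (N+1)/2)^2, divided by the tie
    correction 1 - sum(t^3 - t)/(N^3 - N); p from the chi-square upper tail
    with k-1 degrees of freedom.
    """
    if any(len(g) == 0 for g in groups):
        raise ValueError("kruskal_wallis: empty group")
    if len(groups) < 2:
        raise ValueError("kruskal_wallis: need at least 2 groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(pooled)
    ranks = midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        ni = len(g)
        rbar = ranks[start : start + ni].mean()
        h += ni * (rbar - (n + 1) / 2.0) ** 2
        start += ni
    h *= 12.0 / (n * (n + 1))
    correction = 1.0 - _tie_term(pooled) / (n**3 - n)
    if correction <= 0:  # all values identical
        return 0.0, 1.0
    h /= correction
    df = len(groups) - 1
    return float(h), float(chdtrc(df, h))


@dataclass(slots=True)
class PairwiseResult:
    group_i: int
    group_j: int
    z: float
    p_raw: float
    p_adj: Optional[float] = None


def dunn_pairwise(groups: Sequence[Sequence[float]]) -> list[PairwiseResult]:
    """Dunn's post-hoc z-statistics on the pooled midranks.

    z_ij = (Rbar_i - Rbar_j) / sqrt([N(N+1)/12 - sum(t^3-t)/(12(N-1))]
    * (1/n_i + 1/n_j)); two-sided p from the standard normal.
    """
    if any(len(g) == 0 for g in groups):
        raise ValueError("dunn_pairwise: empty group")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(pooled)
    ranks = midranks(pooled)
    rbars = []
    sizes = []
    start = 0
    for g in groups:
        ni = len(g)
        rbars.append(ranks[start : start + ni].mean())
        sizes.append(ni)
        start += ni
    var_term = n * (n + 1) / 12.0 - _tie_term(pooled) / (12.0 * (n - 1))
    results = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(var_term * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            z = 0.0
        else:
            z = (rbars[i] - rbars[j]) / se
        p = 2.0 * (1.0 - ndtr(abs(z)))
        results.append(PairwiseResult(i, j, float(z), float(min(p, 1.0))))
    return results


def benjamini_hochberg(p_raw: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adjusted p_(i) = min over j >= i of (m * p_(j) / j), capped at 1.
    Rejecting adjusted p <= alpha reproduces the classic step-up rule.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted_sorted = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(adjusted_sorted[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out.tolist()


def _wilcoxon_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum p by enumerating rank assignments (no ties)."""
    pooled = np.concatenate([a, b])
    ranks = midranks(pooled)
    w_obs = ranks[: len(a)].sum()
    n = len(pooled)
    total = 0
    le = 0
    ge = 0
    all_ranks = np.arange(1, n + 1)
    for comb in itertools.combinations(range(n), len(a)):
        w = all_ranks[list(comb)].sum()
        total += 1
        if w <= w_obs:
            le += 1
        if w >= w_obs:
            ge += 1
    p = 2.0 * min(le, ge) / total
    return float(w_obs), float(min(p, 1.0))


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon (Mann–Whitney) rank-sum test.

    ``method='auto'`` uses exact enumeration of the null when
    n_a + n_b <= 12 and there are no ties, otherwise the normal
    approximation with tie-corrected variance and continuity correction.
    Returns (rank sum of ``a``, p-value).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("wilcoxon_rank_sum: empty sample")
    if method not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown method {method!r}")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if method == "exact" or (
        method == "auto" and a.size + b.size <= 12 and not has_ties
    ):
        if has_ties:
            raise ValueError("exact method requires tie-free data")
        return _wilcoxon_exact(a, b)
    n = pooled.size
    ranks = midranks(pooled)
    w = ranks[: a.size].sum()
    mean = a.size * (n + 1) / 2.0
    tie = _tie_term(pooled)
    var = a.size * b.size / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:  # all pooled values identical
        return float(w), 1.0
    diff = w - mean
    # continuity correction toward the mean
    cc = 0.5 if diff != 0 else 0.0
    z = (abs(diff) - cc) / np.sqrt(var)
    p = 2.0 * (1.0 - ndtr(z))
    return float(w), float(min(max(p, 0.0), 1.0))


@dataclass(slots=True)
class GroupTestResult:
    """Kruskal–Wallis omnibus plus Dunn/BH pairwise results for one feature."""

    feature: str
    groups: list[tuple[str, int]]
    kw_statistic: float
    kw_pvalue: float
    pairwise: list[tuple[str, str, float, float, float]]  # (i, j, z, p_raw, p_adj)


def compare_groups(
    feature: str,
    named_groups: dict[str, Sequence[float]],
) -> GroupTestResult:
    """KW omnibus across cohorts, then Dunn pairwise with BH adjustment.

    BH is applied within this feature's family of pairwise comparisons.
    """
    names = list(named_groups)
    values = [np.asarray(named_groups[k], dtype=float) for k in names]
    h, p = kruskal_wallis(values)
    pairs = dunn_pairwise(values)
    adj = benjamini_hochberg([pr.p_raw for pr in pairs])
    pairwise = [
        (names[pr.group_i], names[pr.group_j], pr.z, pr.p_raw, a)
        for pr, a in zip(pairs, adj)
    ]
    return GroupTestResult(
        feature=feature,
        groups=[(k, len(named_groups[k])) for k in names],
        kw_statistic=h,
        kw_pvalue=p,
        pairwise=pairwise,
    )


@dataclass(slots=True)
class PCAResult:
    feature_names: list[str]
    sample_ids: list[str]
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # features x components, columns orthonormal
    explained_variance_ratio: np.ndarray


def pca(
    matrix: np.ndarray,
    feature_names: Sequence[str],
    sample_ids: Sequence[str],
    standardize: bool = True,
) -> PCAResult:
    """PCA of a samples-by-characteristics matrix via SVD.

    Columns are centered (and unit-scaled when ``standardize``; constant
    columns stay at zero).  Sign convention: each loading column's
    largest-magnitude entry is positive.  Explained-variance fractions sum
    to 1 over the returned components.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("pca needs a 2D matrix with >= 2 samples and >= 2 features")
    if np.isnan(x).any():
        raise ValueError("pca input contains missing values")
    x = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=0)
        nonzero = sd > 0
        x[:, nonzero] /= sd[nonzero]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    if not np.any(s > 1e-12):
        raise ValueError("pca: matrix has rank 0 after centering")
    # sign convention for deterministic output
    for k in range(vt.shape[0]):
        idx = np.argmax(np.abs(vt[k]))
        if vt[k, idx] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    scores = u * s
    var = s**2
    return PCAResult(
        feature_names=list(feature_names),
        sample_ids=list(sample_ids),
        scores=scores,
        loadings=vt.T,
        explained_variance_ratio=var / var.sum(),
    )
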