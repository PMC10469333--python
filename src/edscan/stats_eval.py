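"""Shared statistics: ROC/PR areas, rank tests, exact tail tests, BH-FDR,
and covariate-matched enrichment with bootstrap standard errors.

The heavy distributional lifting is delegated to scipy.stats; this module
fixes the package-wide conventions (midrank tie handling, exact-vs-normal
Wilcoxon switch, bootstrap resampling unit) behind a stable surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class EnrichmentResult:
    fold: float
    se: float
    n_test: int
    n_background: int
    bin_label: str = ""

    def __post_init__(self) -> None:
        if self.fold < 0 or self.se < 0:
            raise ValueError("fold and SE must be non-negative")


# ---------------------------------------------------------------------------
# Classification metrics
# ---------------------------------------------------------------------------

def auroc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) auROC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auroc requires both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve (step interpolation)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("auprc requires both classes present")
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order]
    s = scores[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # evaluate at distinct thresholds only (last index of each tied block)
    distinct = np.nonzero(np.append(np.diff(s) != 0, True))[0]
    precision = tp[distinct] / (tp[distinct] + fp[distinct])
    recall = tp[distinct] / labels.sum()
    prev_recall = 0.0
    area = 0.0
    for p, r in zip(precision, recall):
        area += p * (r - prev_recall)
        prev_recall = r
    return float(area)


# ---------------------------------------------------------------------------
# Rank and tail tests
# ---------------------------------------------------------------------------

_EXACT_WILCOXON_MAX = 12


def wilcoxon_rank_sum(a, b, alternative: str = "two-sided"):
    """Mann-Whitney/Wilcoxon rank-sum test.

    Exact null distribution when min(n, m) <= 12 and there are no ties;
    normal approximation with tie correction otherwise.
    Returns (U statistic for sample a, p-value).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if min(len(a), len(b)) <= _EXACT_WILCOXON_MAX and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def hypergeom_test(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric p: P[X >= k] drawing n from N with K successes."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(f"invalid hypergeometric margins N={N} K={K} n={n} k={k}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def binomial_test(k: int, n: int, p: float, alternative: str = "greater") -> float:
    if not (0 <= k <= n) or not (0 <= p <= 1):
        raise ValueError("invalid binomial arguments")
    return float(stats.binomtest(k, n, p, alternative=alternative).pvalue)


def fisher_exact(table, alternative: str = "two-sided"):
    table = np.asarray(table)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("fisher_exact requires a non-negative 2x2 table")
    odds, p = stats.fisher_exact(table, alternative=alternative)
    return float(odds), float(p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg q-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Matched-background enrichment
# ---------------------------------------------------------------------------

def _strata(covariates: np.ndarray, edges: list[np.ndarray]) -> np.ndarray:
    """Cross-binned stratum index per row given per-covariate decile edges."""
    idx = np.zeros(len(covariates), dtype=np.int64)
    for j, e in enumerate(edges):
        b = np.clip(np.searchsorted(e, covariates[:, j], side="right") - 1, 0, len(e) - 2)
        idx = idx * (len(e) - 1) + b
    return idx


def matched_enrichment(
    test_overlap,
    background_overlap,
    test_covariates,
    background_covariates,
    n_boot: int = 200,
    seed: int = 0,
    n_quantiles: int = 10,
    bin_label: str = "",
) -> EnrichmentResult:
    """Fold enrichment of test-set feature overlap against a background
    resampled within covariate strata to match the test profile.

    ``*_overlap`` are boolean arrays (SNP overlaps feature); covariates are
    (n, c) arrays. Strata are cross-binned quantile bins of each covariate
    computed on the pooled data. Bootstrap resamples SNPs of the test set
    (strata re-weighted per resample) for the SE.
    """
    t_ov = np.asarray(test_overlap, dtype=bool)
    b_ov = np.asarray(background_overlap, dtype=bool)
    t_cov = np.atleast_2d(np.asarray(test_covariates, dtype=float))
    b_cov = np.atleast_2d(np.asarray(background_covariates, dtype=float))
    if t_cov.shape[0] != len(t_ov):
        t_cov = t_cov.T
    if b_cov.shape[0] != len(b_ov):
        b_cov = b_cov.T
    pooled = np.vstack([t_cov, b_cov])
    edges = []
    for j in range(pooled.shape[1]):
        qs = np.quantile(pooled[:, j], np.linspace(0, 1, n_quantiles + 1))
        qs = np.unique(qs)
        qs[0], qs[-1] = -np.inf, np.inf
        edges.append(qs)
    t_str = _strata(t_cov, edges)
    b_str = _strata(b_cov, edges)

    bg_rate_by_stratum: dict[int, float] = {}
    for s in np.unique(t_str):
        in_s = b_str == s
        if not in_s.any():
            raise ValueError(f"no background SNPs in required stratum {s}")
        bg_rate_by_stratum[int(s)] = float(b_ov[in_s].mean())

    def fold_of(strata_idx: np.ndarray, overlaps: np.ndarray) -> float:
        test_rate = float(overlaps.mean())
        matched_bg = float(
            np.mean([bg_rate_by_stratum[int(s)] for s in strata_idx])
        )
        if matched_bg == 0:
            return np.inf
        return test_rate / matched_bg

    point = fold_of(t_str, t_ov)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n = len(t_ov)
    for i in range(n_boot):
        take = rng.integers(0, n, n)
        boots[i] = fold_of(t_str[take], t_ov[take])
    finite = boots[np.isfinite(boots)]
    se = float(finite.std(ddof=1)) if len(finite) > 1 else 0.0
    return EnrichmentResult(
        fold=float(point), se=se, n_test=len(t_ov), n_background=len(b_ov),
        bin_label=bin_label,
    )


def compare_enrichments_ztest(e1: EnrichmentResult, e2: EnrichmentResult):
    """Two-sided z-test comparing two fold enrichments via their SEs."""
    if e1.se <= 0 or e2.se <= 0:
        raise ValueError("both enrichments need positive SEs")
    z = (e1.fold - e2.fold) / np.sqrt(e1.se**2 + e2.se**2)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def spearman(a, b) -> float:
    rho = stats.spearmanr(a, b).statistic
    return float(rho)
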