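"""Group-level inference: pooled t-tests, max-statistic permutation
thresholds, Benjamini-Hochberg FDR, and summary-statistic ANOVA/chi-square.

The permutation scheme is the standard nonparametric mapping construction:
group labels are shuffled, the pooled-variance t statistic is recomputed
for every feature, and the maximum |t| over features per shuffle forms the
null distribution. The (1 - alpha) quantile of that distribution is the
family-wise critical threshold; a feature is significant iff its observed
|t| exceeds it. When the number of distinct label assignments is at most
the requested permutation count the test enumerates all assignments
exactly instead of sampling.

Pooled-variance (not Welch) t is used throughout, so two groups of sizes
n1 and n2 give df = n1 + n2 - 2 (e.g. 40 vs 42 -> df = 80).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupComparisonResult:
    """Per-feature t statistics with a permutation family-wise threshold."""

    t: np.ndarray
    df: int
    crit_t: float
    sig_mask: np.ndarray
    p_perm: np.ndarray
    alpha: float
    n_permutations: int
    exhaustive: bool
    seed: int | None
    method: str = "permutation_max"

    def provenance(self) -> dict:
        return {
            "method": self.method,
            "alpha": self.alpha,
            "n_permutations": self.n_permutations,
            "exhaustive": self.exhaustive,
            "seed": self.seed,
            "df": self.df,
            "crit_t": self.crit_t,
        }


def ttest_ind(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Pooled-variance two-sample t and its degrees of freedom.

    Returns ``(nan, df)`` when the pooled variance is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in t-test input")
    df = x.size + y.size - 2
    res = stats.ttest_ind(x, y, equal_var=True)
    t = float(res.statistic)
    return (t if math.isfinite(t) else float("nan")), df


def _t_matrix(X: np.ndarray, idx1: np.ndarray, idx2: np.ndarray) -> np.ndarray:
    """Vectorized pooled t for many label assignments at once.

    ``idx1``/``idx2``: (n_assignments, n1/n2) integer subject indices.
    Returns (n_assignments, n_features). Zero-variance features yield NaN.
    """
    n1, n2 = idx1.shape[1], idx2.shape[1]
    g1 = X[idx1]  # (n_assign, n1, n_feat)
    g2 = X[idx2]
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    v1 = g1.var(axis=1, ddof=1)
    v2 = g2.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, (m1 - m2) / np.where(denom > 0, denom, 1.0), np.nan)


def permutation_threshold(X: np.ndarray, labels: np.ndarray, n_perm: int = 5000,
                          alpha: float = 0.05, seed: int | None = 0) -> GroupComparisonResult:
    """Max-|t| permutation test over features with family-wise control.

    ``X``: subjects x features; ``labels``: two distinct group labels.
    The observed assignment is always included in the null set. If the
    number of distinct assignments is <= ``n_perm`` all are enumerated.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"expected exactly 2 groups, got {uniq.size}")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    n = X.shape[0]
    obs1 = np.flatnonzero(labels == uniq[0])
    obs2 = np.flatnonzero(labels == uniq[1])
    n1 = obs1.size
    df = n - 2

    t_obs = _t_matrix(X, obs1[None], obs2[None])[0]

    n_distinct = math.comb(n, n1)
    exhaustive = n_distinct <= n_perm
    if exhaustive:
        combos = np.array(list(itertools.combinations(range(n), n1)))
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm - 1)])
        combos = np.vstack([obs1[None], perms[:, :n1]])
    all_idx = np.arange(n)
    idx2 = np.array([np.setdiff1d(all_idx, c, assume_unique=False) for c in combos])
    t_null = _t_matrix(X, combos, idx2)
    max_null = np.nanmax(np.abs(t_null), axis=1)
    max_null = max_null[np.isfinite(max_null)]
    if max_null.size == 0:
        raise ValueError("all permutation statistics undefined (zero variance)")

    crit_t = float(np.quantile(max_null, 1.0 - alpha, method="higher")) \
        if alpha < 1 else -np.inf
    abs_obs = np.abs(t_obs)
    sig = abs_obs > crit_t
    sig = np.where(np.isfinite(t_obs), sig, False)
    p_perm = np.array([
        float(np.mean(max_null >= a)) if math.isfinite(a) else float("nan")
        for a in abs_obs
    ])
    return GroupComparisonResult(
        t=t_obs, df=df, crit_t=crit_t, sig_mask=sig, p_perm=p_perm,
        alpha=alpha, n_permutations=int(max_null.size), exhaustive=exhaustive,
        seed=seed,
    )


def fdr_bh(p: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def anova_from_summary(means, sds, ns) -> tuple[float, int, int]:
    """One-way ANOVA F reconstructed from per-group mean, SD and n.

    Between-group and within-group sums of squares are rebuilt from the
    summaries: SSB = sum n_g (m_g - grand)^2, SSW = sum (n_g - 1) s_g^2.
    """
    m = np.asarray(means, dtype=float)
    s = np.asarray(sds, dtype=float)
    n = np.asarray(ns, dtype=int)
    if not (m.shape == s.shape == n.shape) or m.size < 2:
        raise ValueError("need matching mean/sd/n for at least 2 groups")
    if np.any(n < 2):
        raise ValueError("every group needs n >= 2")
    grand = float((n * m).sum() / n.sum())
    ssb = float((n * (m - grand) ** 2).sum())
    ssw = float(((n - 1) * s**2).sum())
    df1 = m.size - 1
    df2 = int(n.sum() - m.size)
    if ssw == 0:
        return (float("inf") if ssb > 0 else 0.0), df1, df2
    F = (ssb / df1) / (ssw / df2)
    return float(F), df1, df2


def chisq_from_counts(table) -> tuple[float, int]:
    """Pearson chi-square of independence (no continuity correction)."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or min(tab.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(tab < 0) or np.any(tab != np.round(tab)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("zero row/column margin")
    res = stats.chi2_contingency(tab, correction=False)
    return float(res[0]), int(res[2])
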