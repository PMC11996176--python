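"""Statistical machinery for within-unit and population comparisons.

The per-unit omnibus test follows a Shapiro-Wilk normality gate: if every
condition passes (p > 0.05) a one-way repeated-measures ANOVA with Tukey
HSD pairwise comparisons is used; otherwise the Friedman chi-square test
(mid-rank ties) with Nemenyi pairwise comparisons.  Population folded
modulations are compared with a Mann-Whitney U test, exact by enumeration
for small samples and tie-corrected normal otherwise.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM

__all__ = [
    "shapiro_all_normal",
    "rm_anova",
    "tukey_pairwise",
    "friedman",
    "nemenyi_pairwise",
    "mann_whitney_u",
]


def shapiro_all_normal(matrix: np.ndarray, alpha: float = 0.05) -> bool:
    """Shapiro-Wilk gate applied per condition column.

    Returns True only if every column is consistent with normality
    (p > alpha).  Constant columns (zero variance) fail the gate.
    """
    m = np.asarray(matrix, dtype=float)
    for col in m.T:
        if np.ptp(col) == 0:
            return False
        if sps.shapiro(col).pvalue <= alpha:
            return False
    return True


def _long_format(matrix: np.ndarray) -> pd.DataFrame:
    n, k = matrix.shape
    return pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "condition": np.tile(np.arange(k), n),
            "value": matrix.ravel(),
        }
    )


def rm_anova(matrix: np.ndarray) -> tuple[float, int, int, float]:
    """One-way repeated-measures ANOVA on a trials x conditions matrix.

    Returns (F, df_condition, df_error, p).
    """
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 trials and >= 2 conditions")
    res = AnovaRM(_long_format(m), "value", "subject", within=["condition"]).fit()
    row = res.anova_table.iloc[0]
    return (
        float(row["F Value"]),
        int(row["Num DF"]),
        int(row["Den DF"]),
        float(row["Pr > F"]),
    )


def _rm_anova_mse(m: np.ndarray) -> float:
    """Error mean square of the one-way RM decomposition (for Tukey HSD)."""
    n, k = m.shape
    grand = m.mean()
    ss_total = np.sum((m - grand) ** 2)
    ss_cond = n * np.sum((m.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((m.mean(axis=1) - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    return ss_err / ((n - 1) * (k - 1))


def tukey_pairwise(matrix: np.ndarray) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons after a repeated-measures ANOVA.

    Uses the RM error mean square and its (n-1)(k-1) degrees of freedom;
    p-values from the studentized range distribution.
    """
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    mse = _rm_anova_mse(m)
    df_err = (n - 1) * (k - 1)
    means = m.mean(axis=0)
    rows = []
    for a, b in combinations(range(k), 2):
        diff = means[a] - means[b]
        se = np.sqrt(mse / n)
        q = np.abs(diff) / se if se > 0 else np.inf
        p = float(sps.studentized_range.sf(q, k, df_err)) if np.isfinite(q) else 0.0
        rows.append({"pair": (a, b), "diff": diff, "statistic": q, "p": p})
    return pd.DataFrame(rows)


def friedman(matrix: np.ndarray) -> tuple[float, int, float]:
    """Friedman chi-square test (mid-rank ties) on trials x conditions.

    Returns (chi2, df, p).  A matrix whose rows are all internally
    constant carries no rank information: statistic 0, p 1.
    """
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    if k < 3:
        raise ValueError("Friedman test requires >= 3 conditions")
    if n < 2:
        raise ValueError("Friedman test requires >= 2 trials")
    if np.all(np.ptp(m, axis=1) == 0):
        return 0.0, k - 1, 1.0
    chi2, p = sps.friedmanchisquare(*m.T)
    return float(chi2), k - 1, float(p)


def nemenyi_pairwise(matrix: np.ndarray) -> pd.DataFrame:
    """Nemenyi all-pairs post hoc test after a Friedman test.

    The statistic for conditions (a, b) is the mean-rank difference over
    sqrt(k(k+1) / (12 n)), referred to the studentized range distribution
    with infinite error degrees of freedom.
    """
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    ranks = sps.rankdata(m, axis=1)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    rows = []
    for a, b in combinations(range(k), 2):
        q = np.abs(mean_ranks[a] - mean_ranks[b]) / se
        p = float(np.clip(sps.studentized_range.sf(q, k, np.inf), 0.0, 1.0))
        rows.append({"pair": (a, b), "diff": mean_ranks[a] - mean_ranks[b],
                     "statistic": q, "p": p})
    return pd.DataFrame(rows)


def _u_from_ranksum(r1: float, n1: int) -> float:
    return r1 - n1 * (n1 + 1) / 2.0


def mann_whitney_u(
    x: np.ndarray, y: np.ndarray, exact_max_n: int = 20
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    For combined sample sizes up to ``exact_max_n`` the null distribution
    of U is enumerated over all rank assignments (mid-ranks for ties) and
    the two-sided p is twice the smaller tail probability, capped at 1.
    Larger samples use the tie-corrected normal approximation (no
    continuity correction).  Returns (U1, p) with U1 the statistic of the
    first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u1 = _u_from_ranksum(float(ranks[:n1].sum()), n1)

    if n1 + n2 <= exact_max_n:
        us = _enumerate_u(ranks, n1)
        p_le = np.mean(us <= u1 + 1e-12)
        p_ge = np.mean(us >= u1 - 1e-12)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return u1, float(p)

    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / ((n1 + n2) * (n1 + n2 - 1.0))
    sigma2 = n1 * n2 / 12.0 * ((n1 + n2 + 1.0) - tie_term)
    if sigma2 <= 0:
        return u1, 1.0
    z = (u1 - mu) / np.sqrt(sigma2)
    return u1, float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def _enumerate_u(ranks: np.ndarray, n1: int) -> np.ndarray:
    """U statistics of the first group over all rank assignments."""
    n = len(ranks)
    total = comb(n, n1)
    us = np.empty(total)
    for idx, sel in enumerate(combinations(range(n), n1)):
        us[idx] = _u_from_ranksum(ranks[list(sel)].sum(), n1)
    return us
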