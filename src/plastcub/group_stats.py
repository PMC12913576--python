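"""Shared statistical kernel for group comparisons.

Thin, consistently-typed wrappers around scipy for the tests used
throughout the pipeline (Kruskal-Wallis, Wilcoxon rank-sum, one-sample t,
Pearson correlation) plus the pieces scipy does not ship directly (Dunn's
post-hoc z on mean ranks with tie correction, Cohen's d, Bonferroni).

All p-values are two-sided.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupTestResult:
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    posthoc: list[tuple[tuple[int, int], float, float, float]] | None = None


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> GroupTestResult:
    """Kruskal-Wallis H with tie correction; p from chi-square (k-1 df).

    All values identical across groups yields H = 0, p = 1 rather than an
    error.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return GroupTestResult(0.0, 1.0, tuple(len(g) for g in groups))
    h, p = stats.kruskal(*groups)
    return GroupTestResult(float(h), float(p), tuple(len(g) for g in groups))


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
) -> list[tuple[tuple[int, int], float, float, float]]:
    """Dunn's pairwise post-hoc comparisons on mean ranks.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with
    tie correction T = sum(t^3 - t) / (12 (N - 1)); p two-sided normal,
    Bonferroni-adjusted over the k(k-1)/2 pairs.  Returns a list of
    ((i, j), z, p_raw, p_adj) tuples indexed by group position.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(range(len(groups)), 2))
    m = len(pairs)
    out = []
    for i, j in pairs:
        se = math.sqrt(variance_base * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        out.append(((i, j), float(z), float(p_raw), min(1.0, m * p_raw)))
    return out


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration for small tie-free samples (both n < 8), otherwise
    the normal approximation with continuity and tie correction.  Returns
    (U statistic of the first sample, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        return (len(a) * len(b) / 2.0, 1.0)
    method = "exact" if (max(len(a), len(b)) < 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return (float(res.statistic), float(res.pvalue))


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float | None:
    """Cohen's d with pooled SD weighted by n-1; missing when SD is zero."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    pooled_var = (
        (len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)
    ) / (len(a) + len(b) - 2)
    if pooled_var == 0:
        return None
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


def one_sample_t(values: Sequence[float], mu: float) -> tuple[float | None, float | None]:
    """One-sample t test against mu; missing on zero variance."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need n >= 2")
    if values.var(ddof=1) == 0:
        return (None, None)
    t, p = stats.ttest_1samp(values, mu)
    return (float(t), float(p))


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: p * m capped at 1 (m defaults to len(ps))."""
    ps = list(p_values)
    m = m if m is not None else len(ps)
    return [min(1.0, p * m) for p in ps]


def pearson_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-tailed t-test p over the table's columns.

    Each pair uses its complete observations; pairs with fewer than three
    complete rows or a constant variable are missing (NaN).
    """
    cols = list(table.columns)
    r_mat = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=float)
    p_mat = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=float)
    for i, ci in enumerate(cols):
        for cj in cols[i:]:
            sub = table[[ci, cj]].dropna()
            n = len(sub)
            if n < 3:
                continue
            x, y = sub[ci].to_numpy(float), sub[cj].to_numpy(float)
            if ci == cj:
                r, p = (1.0, 0.0) if np.std(x) > 0 else (np.nan, np.nan)
            elif np.std(x) == 0 or np.std(y) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x, y)
            r_mat.loc[ci, cj] = r_mat.loc[cj, ci] = r
            p_mat.loc[ci, cj] = p_mat.loc[cj, ci] = p
    return r_mat, p_mat
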