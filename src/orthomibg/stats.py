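"""Two-group comparison statistics for cohort description tables.

Pooled and Welch two-sample t-tests, the Mann-Whitney U test (exact
enumeration for small samples, tie-corrected normal approximation with
continuity correction otherwise), Fisher's exact test with the
probability-at-most-observed two-sided rule, and helpers for the usual
"mean (SD) / median (IQR) / n (%)" descriptive layout.

The choice between t and Mann-Whitney is left to the caller; a
Shapiro-Wilk helper is provided but never auto-invoked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class GroupComparison:
    """Named test statistic with p-value and per-group summaries."""

    test: str
    statistic: float
    df: float | None
    p: float
    summaries: dict = field(default_factory=dict)


def _summary(group) -> tuple[int, float, float]:
    """(n, mean, sd) from raw values or an (n, mean, sd) triple."""
    if isinstance(group, tuple) and len(group) == 3:
        n, mean, sd = group
        if n < 2:
            raise ValueError(f"group size must be >= 2, got {n}")
        return int(n), float(mean), float(sd)
    x = np.asarray(group, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        raise ValueError(f"group size must be >= 2, got {len(x)}")
    return len(x), float(x.mean()), float(x.std(ddof=1))


def pooled_t(group1, group2) -> GroupComparison:
    """Pooled-variance two-sample t-test, df = n1 + n2 - 2.

    Each group may be raw values or an ``(n, mean, sd)`` summary triple, so
    published tables are directly testable.
    """
    n1, m1, s1 = _summary(group1)
    n2, m2, s2 = _summary(group2)
    t, p = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return GroupComparison(
        test="pooled t", statistic=float(t), df=float(n1 + n2 - 2), p=float(p),
        summaries={"group1": (n1, m1, s1), "group2": (n2, m2, s2)},
    )


def welch_t(group1, group2) -> GroupComparison:
    """Welch's unequal-variance t-test with Satterthwaite df."""
    n1, m1, s1 = _summary(group1)
    n2, m2, s2 = _summary(group2)
    t, p = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
    v1, v2 = s1**2 / n1, s2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return GroupComparison(
        test="Welch t", statistic=float(t), df=float(df), p=float(p),
        summaries={"group1": (n1, m1, s1), "group2": (n2, m2, s2)},
    )


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def _u_from_ranks(ranks: np.ndarray, idx1, n1: int) -> float:
    return float(np.sum(ranks[list(idx1)]) - n1 * (n1 + 1) / 2)


def mann_whitney_u(
    values1, values2, *, continuity: bool = True, exact_limit: int = 12
) -> GroupComparison:
    """Mann-Whitney U test from midranks.

    For ``n1 + n2 <= exact_limit`` the two-sided p is computed by exact
    enumeration over all assignments of pooled ranks to group 1 (ties
    allowed, handled through midranks); larger samples use the normal
    approximation with tie-corrected variance and, by default, a continuity
    correction.  The reported U is that of group 1.
    """
    x1 = np.asarray(values1, dtype=float)
    x2 = np.asarray(values2, dtype=float)
    x1, x2 = x1[~np.isnan(x1)], x2[~np.isnan(x2)]
    n1, n2 = len(x1), len(x2)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x1, x2])
    ranks = _midranks(pooled)
    u_obs = _u_from_ranks(ranks, range(n1), n1)
    mu = n1 * n2 / 2

    if n1 + n2 <= exact_limit:
        dev_obs = abs(u_obs - mu)
        count = 0
        for idx in combinations(range(n1 + n2), n1):
            if abs(_u_from_ranks(ranks, idx, n1) - mu) >= dev_obs - 1e-12:
                count += 1
        p = count / comb(n1 + n2, n1)
        return GroupComparison(
            test="Mann-Whitney U (exact)", statistic=u_obs, df=None, p=float(p),
            summaries={"n1": n1, "n2": n2},
        )
    res = sps.mannwhitneyu(
        x1, x2, alternative="two-sided", method="asymptotic",
        use_continuity=continuity,
    )
    return GroupComparison(
        test="Mann-Whitney U", statistic=float(res.statistic), df=None,
        p=float(res.pvalue), summaries={"n1": n1, "n2": n2},
    )


def fisher_exact(table) -> GroupComparison:
    """Two-sided Fisher's exact test on a 2x2 count table.

    The two-sided p sums hypergeometric probabilities of all tables with the
    same margins whose probability does not exceed the observed table's
    (the convention of most statistical software).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("both margins must be positive")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return GroupComparison(
        test="Fisher exact", statistic=float(odds), df=None, p=float(p),
        summaries={"table": t.tolist()},
    )


def shapiro_wilk(values) -> GroupComparison:
    """Shapiro-Wilk normality test (helper only; never auto-invoked)."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    w, p = sps.shapiro(x)
    return GroupComparison(test="Shapiro-Wilk", statistic=float(w), df=None,
                           p=float(p), summaries={"n": len(x)})


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """Display percentage, e.g. ``percentage(158, 227) == 69.6``."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)


def _describe_continuous(x: np.ndarray) -> str:
    return f"{np.nanmean(x):.1f} ({np.nanstd(x, ddof=1):.1f})"


def _describe_median(x: np.ndarray) -> str:
    q1, med, q3 = np.nanpercentile(x, [25, 50, 75])
    return f"{med:.1f} ({q3 - q1:.1f})"


def _describe_binary(x: np.ndarray) -> str:
    n = int(np.nansum(x))
    total = int(np.sum(~np.isnan(x)))
    return f"{n} ({percentage(n, total)})"


def compare_groups(
    df: pd.DataFrame,
    group_col: str,
    variables: Sequence[str],
    tests: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Two-group descriptive table in the mean (SD) / n (%) layout.

    ``tests`` maps variable -> one of ``pooled_t``, ``welch_t``,
    ``mannwhitney``, ``fisher``; unlisted numeric variables default to the
    pooled t, binary (0/1 or boolean) variables to Fisher's exact test.
    """
    levels = sorted(df[group_col].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"{group_col} must have exactly 2 levels, got {levels}")
    g1 = df[df[group_col] == levels[0]]
    g2 = df[df[group_col] == levels[1]]
    tests = dict(tests or {})
    rows = []
    for var in variables:
        x1 = g1[var].astype(float).to_numpy()
        x2 = g2[var].astype(float).to_numpy()
        all_x = df[var].astype(float).to_numpy()
        is_binary = set(np.unique(all_x[~np.isnan(all_x)])) <= {0.0, 1.0}
        kind = tests.get(var, "fisher" if is_binary else "pooled_t")
        if kind == "fisher":
            tab = [
                [int(np.nansum(x1)), int(np.sum(x1 == 0))],
                [int(np.nansum(x2)), int(np.sum(x2 == 0))],
            ]
            cmp_ = fisher_exact(tab)
            d1, d2 = _describe_binary(x1), _describe_binary(x2)
            dall = _describe_binary(all_x)
        elif kind == "mannwhitney":
            cmp_ = mann_whitney_u(x1, x2)
            d1, d2 = _describe_median(x1), _describe_median(x2)
            dall = _describe_median(all_x)
        elif kind == "welch_t":
            cmp_ = welch_t(x1, x2)
            d1, d2 = _describe_continuous(x1), _describe_continuous(x2)
            dall = _describe_continuous(all_x)
        elif kind == "pooled_t":
            cmp_ = pooled_t(x1, x2)
            d1, d2 = _describe_continuous(x1), _describe_continuous(x2)
            dall = _describe_continuous(all_x)
        else:
            raise ValueError(f"unknown test kind {kind!r} for variable {var!r}")
        rows.append({
            "variable": var,
            "overall": dall,
            str(levels[0]): d1,
            str(levels[1]): d2,
            "test": cmp_.test,
            "statistic": round(cmp_.statistic, 3),
            "p": round(cmp_.p, 3),
        })
    return pd.DataFrame(rows)
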