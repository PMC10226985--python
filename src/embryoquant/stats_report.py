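"""Normality-routed group comparisons and summary tables.

Mirrors a common reporting workflow in quantitative embryology: each group
is screened with the D'Agostino-Pearson omnibus normality test; if every
group is consistent with normality (α = 0.05), parametric tests are used
(unpaired two-tailed t-test for two groups, one-way ANOVA with Dunnett's
multiple comparisons against the first group for more), otherwise
non-parametric ones (two-tailed Mann-Whitney U for two groups,
Kruskal-Wallis with Dunn's multiple comparisons for more).  Groups too
small for the omnibus test (n < 8) route directly to the non-parametric
branch, flagged.

Group summaries report n, median, interquartile range (linear-interpolation
quartiles), mean and SD — matching dot plots annotated with median and IQR.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GroupComparison", "route_and_test", "mann_whitney_u", "dunn_posthoc", "summarize_groups"]

NORMALITY_ALPHA = 0.05
MIN_N_NORMALITY = 8  # scipy's D'Agostino-Pearson requires n >= 8


@dataclass
class GroupComparison:
    """Outcome of a routed group comparison."""

    group_names: list[str]
    group_sizes: list[int]
    normality_p: dict[str, float | None]
    test_used: str
    statistic: float
    p_value: float
    posthoc: pd.DataFrame | None = None
    flags: tuple[str, ...] = ()


def _exact_u_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-tailed exact Mann-Whitney p by enumerating rank assignments.

    Uses mid-ranks for ties; enumerates all C(n1+n2, n1) splits of the
    pooled mid-rank multiset, so it is valid with ties (a conditional exact
    test).  Returns (U of x, p).
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    dev_obs = abs(u_obs - mu)
    total = 0
    extreme = 0
    for comb in itertools.combinations(range(n1 + n2), n1):
        u = float(ranks[list(comb)].sum() - n1 * (n1 + 1) / 2.0)
        total += 1
        if abs(u - mu) >= dev_obs - 1e-12:
            extreme += 1
    return u_obs, extreme / total


def mann_whitney_u(x, y, exact_max_n: int = 10) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U with mid-rank tie handling.

    Exact enumeration (tie-safe) when both samples have at most
    ``exact_max_n`` observations; otherwise the normal approximation with
    tie correction and continuity correction (scipy's asymptotic method).
    Returns ``(U, p)`` with U the statistic of the first sample.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) <= exact_max_n and len(y) <= exact_max_n:
        return _exact_u_pvalue(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def dunn_posthoc(groups: dict[str, np.ndarray], control: str | None = None) -> pd.DataFrame:
    """Dunn's multiple-comparison z-tests on pooled ranks after Kruskal-Wallis.

    Pairwise z statistics use the pooled mid-ranks with the standard tie
    correction; p-values are Bonferroni-adjusted over the tested pairs
    (all pairs, or each group against ``control``).
    """
    names = list(groups)
    values = [np.asarray(groups[g], float) for g in names]
    pooled = np.concatenate(values)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (N - 1)) if N > 1 else 0.0
    mean_ranks = {}
    i = 0
    for g, v in zip(names, values):
        mean_ranks[g] = ranks[i : i + len(v)].mean()
        i += len(v)
    if control is not None:
        pairs = [(control, g) for g in names if g != control]
    else:
        pairs = list(itertools.combinations(names, 2))
    rows = []
    m = len(pairs)
    for a, b in pairs:
        na, nb = len(groups[a]), len(groups[b])
        se = np.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_adjusted": min(1.0, m * p)})
    return pd.DataFrame(rows)


def route_and_test(groups: dict[str, "np.ndarray | list"]) -> GroupComparison:
    """Compare ≥ 2 groups with normality-routed test selection.

    All groups pass D'Agostino-Pearson at α = 0.05 → t-test (2 groups) or
    ANOVA + Dunnett against the first group (> 2); any failure (or any
    group with n < 8, where the omnibus test is undefined) → Mann-Whitney U
    (2) or Kruskal-Wallis + Dunn (> 2).  All tests two-tailed.
    """
    names = list(groups)
    values = [np.asarray(groups[g], float) for g in names]
    if len(values) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(v) < 3 for v in values):
        raise ValueError("every group needs n >= 3")

    flags: list[str] = []
    normality_p: dict[str, float | None] = {}
    too_small = False
    for g, v in zip(names, values):
        if len(v) < MIN_N_NORMALITY:
            normality_p[g] = None
            too_small = True
        else:
            normality_p[g] = float(stats.normaltest(v).pvalue)
    if too_small:
        flags.append("group_below_normality_n_routed_nonparametric")
    all_normal = (not too_small) and all(
        p is not None and p > NORMALITY_ALPHA for p in normality_p.values()
    )

    posthoc = None
    if all_normal:
        if len(values) == 2:
            res = stats.ttest_ind(values[0], values[1])
            test_used, statistic, p = "t-test", float(res.statistic), float(res.pvalue)
        else:
            res = stats.f_oneway(*values)
            test_used, statistic, p = "anova", float(res.statistic), float(res.pvalue)
            dn = stats.dunnett(*values[1:], control=values[0])
            posthoc = pd.DataFrame(
                {
                    "group_a": [names[0]] * (len(names) - 1),
                    "group_b": names[1:],
                    "statistic": np.atleast_1d(dn.statistic),
                    "p_adjusted": np.atleast_1d(dn.pvalue),
                }
            )
            test_used = "anova+dunnett"
    else:
        if len(values) == 2:
            statistic, p = mann_whitney_u(values[0], values[1])
            test_used = "mann-whitney"
        else:
            res = stats.kruskal(*values)
            test_used, statistic, p = "kruskal-wallis", float(res.statistic), float(res.pvalue)
            posthoc = dunn_posthoc(dict(zip(names, values)))
            test_used = "kruskal-wallis+dunn"

    return GroupComparison(
        group_names=names,
        group_sizes=[len(v) for v in values],
        normality_p=normality_p,
        test_used=test_used,
        statistic=statistic,
        p_value=float(p),
        posthoc=posthoc,
        flags=tuple(flags),
    )


def summarize_groups(
    records: pd.DataFrame, by: str = "position_class", metrics: list[str] | None = None
) -> pd.DataFrame:
    """Per-group n, median, IQR, mean and SD for each metric column.

    Quartiles use linear interpolation (numpy default).  Groups that are
    empty for a metric are dropped with a warning flag in the table.
    """
    if records.empty:
        raise ValueError("no records to summarize")
    if metrics is None:
        metrics = [
            c for c in records.columns if c != by and pd.api.types.is_numeric_dtype(records[c])
        ]
    unknown = [m for m in metrics if m not in records.columns]
    if unknown:
        raise KeyError(f"unknown metric(s): {unknown}")
    rows = []
    for group, sub in records.groupby(by, sort=True):
        for m in metrics:
            v = sub[m].dropna().to_numpy(float)
            if len(v) == 0:
                continue
            q1, q3 = np.percentile(v, [25, 75])
            rows.append(
                {
                    "group": group,
                    "metric": m,
                    "n": len(v),
                    "median": float(np.median(v)),
                    "iqr": float(q3 - q1),
                    "q1": float(q1),
                    "q3": float(q3),
                    "mean": float(v.mean()),
                    "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)
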