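"""Rank-based association tests with mean-rank reporting, correlation, and
intraclass correlation for visual-vs-automated agreement.

Mann-Whitney uses mid-ranks with tie-corrected variance; the two-sided
p-value comes from a normal approximation with continuity correction, and
from exhaustive enumeration of rank assignments when the pooled sample is
small (N <= 10 by default).  Kruskal-Wallis uses the tie-corrected H with a
chi-square reference; two groups delegate to Mann-Whitney.  All p-values
are two-sided and no multiple-testing correction is applied (noted in
reports).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationResult",
    "AgreementResult",
    "mann_whitney",
    "kruskal_wallis",
    "correlation",
    "icc_agreement",
    "association_battery",
]

EXACT_MAX_N = 10


@dataclass
class GroupSummary:
    label: str
    n: int
    mean_rank: float


@dataclass
class AssociationResult:
    """One feature x grouping association: per-group mean ranks, the test
    statistic and its two-sided p-value."""

    feature_name: str
    grouping_name: str
    groups: list[GroupSummary]
    statistic: float
    p_value: float
    test: Literal["mann_whitney", "kruskal_wallis"]
    method_note: str = ""


@dataclass
class AgreementResult:
    icc: float
    model: str
    n_subjects: int
    n_raters: int


def _mid_ranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def _mw_u_from_ranks(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def _mw_exact_p(pooled_ranks: np.ndarray, n_a: int, u_obs: float) -> float:
    """Two-sided p by exhaustive enumeration of which pooled positions form
    group A, using the observed mid-ranks (so ties are respected)."""
    n = len(pooled_ranks)
    mu = n_a * (n - n_a) / 2.0
    dev = abs(u_obs - mu)
    hits = 0
    for idx in combinations(range(n), n_a):
        u = sum(pooled_ranks[list(idx)]) - n_a * (n_a + 1) / 2.0
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
    return hits / comb(n, n_a)


def mann_whitney(
    values_a: Sequence[float],
    values_b: Sequence[float],
    feature_name: str = "feature",
    grouping_name: str = "group",
    labels: tuple[str, str] = ("a", "b"),
    continuity: bool = True,
    exact_max_n: int = EXACT_MAX_N,
) -> AssociationResult:
    """Mann-Whitney U with mean-rank reporting.

    The statistic is U for the first group (computed from pooled
    mid-ranks).  The p-value is exact (enumeration over rank assignments)
    when the pooled N is at most ``exact_max_n``, else the tie-corrected
    normal approximation with optional continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = _mid_ranks(pooled)
    ranks_a, ranks_b = ranks[:n_a], ranks[n_a:]
    u = _mw_u_from_ranks(ranks_a, n_a)
    mu = n_a * n_b / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))

    if var <= 0:
        p = 1.0
        note = "all values tied; variance zero"
    elif n <= exact_max_n:
        p = _mw_exact_p(ranks, n_a, u)
        note = "exact enumeration"
    else:
        cc = 0.5 if continuity else 0.0
        z = (u - mu - np.sign(u - mu) * cc) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
        note = "normal approximation, tie-corrected" + (
            ", continuity-corrected" if continuity else ""
        )
    return AssociationResult(
        feature_name=feature_name,
        grouping_name=grouping_name,
        groups=[
            GroupSummary(labels[0], n_a, float(ranks_a.mean())),
            GroupSummary(labels[1], n_b, float(ranks_b.mean())),
        ],
        statistic=u,
        p_value=p,
        test="mann_whitney",
        method_note=note,
    )


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    feature_name: str = "feature",
    grouping_name: str = "group",
    labels: Sequence[str] | None = None,
) -> AssociationResult:
    """Kruskal-Wallis H (tie-corrected, chi-square with k-1 df).

    Exactly two groups delegate to :func:`mann_whitney`.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be nonempty")
    labels = list(labels) if labels is not None else [str(i) for i in range(len(groups))]
    if len(groups) == 2:
        return mann_whitney(
            groups[0], groups[1], feature_name, grouping_name, labels=(labels[0], labels[1])
        )
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    ranks = _mid_ranks(pooled)
    sizes = [a.size for a in arrays]
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(float(ranks[start : start + sz].mean()))
        start += sz
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)
    return AssociationResult(
        feature_name=feature_name,
        grouping_name=grouping_name,
        groups=[GroupSummary(l, s, m) for l, s, m in zip(labels, sizes, mean_ranks)],
        statistic=float(h),
        p_value=float(p),
        test="kruskal_wallis",
        method_note="tie-corrected H, chi-square reference",
    )


def correlation(
    x: Sequence[float], y: Sequence[float], method: Literal["pearson", "spearman"] = "pearson"
) -> tuple[float, float]:
    """Two-sided correlation (r, p); raises on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in an input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def icc_agreement(rater1: Sequence[float], rater2: Sequence[float]) -> AgreementResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Computed from the standard mean-squares decomposition of the
    subjects x raters table:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR the between-subject, MSC the between-rater and MSE the
    residual mean square.  Raises on zero between-subject variance.
    """
    y = np.column_stack([np.asarray(rater1, dtype=float), np.asarray(rater2, dtype=float)])
    n, k = y.shape
    if n < 3:
        raise ValueError("need at least 3 paired subjects")
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((y - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if msr == 0:
        raise ValueError("ICC undefined: zero between-subject variance")
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return AgreementResult(
        icc=float(icc),
        model="two-way random, absolute agreement, single measures (ICC(2,1))",
        n_subjects=n,
        n_raters=k,
    )


def association_battery(
    cohort: pd.DataFrame,
    features: Sequence[str],
    groupings: dict[str, Sequence[str] | None] | None = None,
) -> pd.DataFrame:
    """Run every feature against every clinicopathological grouping.

    ``groupings`` maps a cohort column to an optional explicit level order;
    binary columns go through Mann-Whitney, >=3 levels through
    Kruskal-Wallis.  Returns a long-format frame (feature, variable, group,
    n, mean_rank, statistic, p_value, test), one row per group level.
    """
    if groupings is None:
        groupings = {
            "age_lt_50": None,
            "size_ge_2cm": None,
            "grade": None,
            "npi_group": ["good", "moderate", "poor"],
            "ln_positive": None,
            "lvi": None,
            "pr_positive": None,
            "ki67_high": None,
        }
    df = cohort.copy()
    if "age_lt_50" in groupings and "age_lt_50" not in df.columns:
        df["age_lt_50"] = df["age_years"] < 50
    if "size_ge_2cm" in groupings and "size_ge_2cm" not in df.columns:
        df["size_ge_2cm"] = df["size_cm"] >= 2.0
    rows = []
    for feat in features:
        vals = df[feat]
        for var, order in groupings.items():
            levels = order if order is not None else sorted(df[var].dropna().unique(), key=str)
            ok = df[var].notna() & vals.notna()
            samples = [vals[ok & (df[var] == lev)].to_numpy() for lev in levels]
            keep = [(lev, s) for lev, s in zip(levels, samples) if s.size > 0]
            if len(keep) < 2:
                continue
            res = kruskal_wallis(
                [s for _, s in keep],
                feature_name=feat,
                grouping_name=var,
                labels=[str(lev) for lev, _ in keep],
            )
            for g in res.groups:
                rows.append(
                    {
                        "feature": feat,
                        "variable": var,
                        "group": g.label,
                        "n": g.n,
                        "mean_rank": g.mean_rank,
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                        "test": res.test,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["feature", "variable", "group", "n", "mean_rank", "statistic", "p_value", "test"],
    )
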