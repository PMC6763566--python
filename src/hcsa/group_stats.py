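"""Nonparametric group comparisons of per-embryo metrics.

Cohorts are compared metric-by-metric with the two-sided Mann-Whitney U
test: exactly (full enumeration of arrangements) for small tie-free samples,
otherwise with the tie-corrected, continuity-corrected normal
approximation.  Group summaries are the median with a distribution-free
order-statistic 95% confidence interval.  No multiple-testing correction is
applied: each metric is judged at the per-comparison level alpha, and the
output records that choice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, EmptyResultsError

#: canonical ordering of metric columns in comparison output
CANONICAL_METRICS = ["tEDA", "tESA", "delta_pct_tA", "EDBA", "ESBA", "SA", "EF", "MMI"]

#: largest per-group size for which the exact null distribution is enumerated
EXACT_MAX_N = 8


@dataclass
class GroupComparison:
    metric_name: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    U: float
    p_two_sided: float
    method: str
    median_a: float
    median_b: float
    ci95_a: tuple[float, float]
    ci95_b: tuple[float, float]
    significant: bool


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: number of (a_i, b_j) pairs with a_i > b_j, ties 1/2."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _exact_two_sided_p(u: float, n_a: int, n_b: int) -> float:
    """Exact two-sided p by enumerating all C(n_a+n_b, n_a) rank assignments.

    Assumes no ties, so U is determined by which pooled ranks belong to
    sample a.  The null distribution of U is symmetric about n_a*n_b/2;
    p = 2 * P(U' <= min(U, n_a*n_b - U)), capped at 1.
    """
    n = n_a + n_b
    u_lo = min(u, n_a * n_b - u)
    count = 0
    total = math.comb(n, n_a)
    base = n_a * (n_a - 1) // 2
    for combo in combinations(range(n), n_a):
        # positions are 0-based pooled ranks; U = sum(pos) - n_a*(n_a-1)/2
        u_prime = sum(combo) - base
        if u_prime <= u_lo + 1e-12:
            count += 1
    return min(1.0, 2.0 * count / total)


def _normal_approx_p(u: float, a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided p from the normal approximation with tie correction and
    a 0.5 continuity correction."""
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    mean = n_a * n_b / 2.0
    _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = max(abs(u - mean) - 0.5, 0.0) / math.sqrt(var)
    return min(1.0, 2.0 * stats.norm.sf(z))


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    method_policy: str = "auto",
    alpha: float = 0.05,
    metric_name: str = "",
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two independent samples.

    ``method_policy``: "auto" enumerates the exact null when both samples
    have at most 8 observations and the pooled data is tie-free, and falls
    back to the normal approximation otherwise; "exact" / "normal_approx"
    force a method (exact requires tie-free data).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise EmptyResultsError("both samples must be nonempty")
    if method_policy not in ("auto", "exact", "normal_approx"):
        raise ConfigError(f"unknown method_policy {method_policy!r}")
    u = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    use_exact = (
        method_policy == "exact"
        or (
            method_policy == "auto"
            and tie_free
            and len(a) <= EXACT_MAX_N
            and len(b) <= EXACT_MAX_N
        )
    )
    if method_policy == "exact" and not tie_free:
        raise ConfigError("exact method requires tie-free data")
    if use_exact:
        p = _exact_two_sided_p(u, len(a), len(b))
        method = "exact"
    else:
        p = _normal_approx_p(u, a, b)
        method = "normal_approx"
    med_a, lo_a, hi_a = median_with_ci(a)
    med_b, lo_b, hi_b = median_with_ci(b)
    return GroupComparison(
        metric_name=metric_name,
        group_a=group_a,
        group_b=group_b,
        n_a=len(a),
        n_b=len(b),
        U=u,
        p_two_sided=p,
        method=method,
        median_a=med_a,
        median_b=med_b,
        ci95_a=(lo_a, hi_a),
        ci95_b=(lo_b, hi_b),
        significant=p < alpha,
    )


def median_with_ci(sample, level: float = 0.95) -> tuple[float, float, float]:
    """Sample median with a distribution-free order-statistic CI.

    The interval is (x_(l), x_(n+1-l)) for the largest symmetric rank l whose
    binomial(n, 1/2) coverage reaches ``level``.  For n too small for any
    such interval (n < 6 at the 95% level) the sample range is returned with
    a coverage warning.
    """
    x = np.sort(np.asarray(sample, dtype=np.float64))
    n = x.size
    if n == 0:
        raise EmptyResultsError("cannot summarize an empty sample")
    med = float(np.median(x))
    if n == 1:
        warnings.warn("single observation: CI degenerates to the point itself")
        return med, med, med
    best_l = None
    for l in range(1, n // 2 + 1):
        u = n + 1 - l
        # coverage of (x_(l), x_(u)): P(l <= #below-median <= u-1)
        cover = stats.binom.cdf(u - 1, n, 0.5) - stats.binom.cdf(l - 1, n, 0.5)
        if cover >= level:
            best_l = l
        else:
            break
    if best_l is None:
        warnings.warn(
            f"n={n} too small for a {level:.0%} distribution-free CI; "
            "reporting the sample range"
        )
        return med, float(x[0]), float(x[-1])
    return med, float(x[best_l - 1]), float(x[n - best_l])


def compare_cohorts(
    results_table: pd.DataFrame,
    group_pairs: Sequence[tuple[str, str]],
    alpha: float = 0.05,
    metrics: Sequence[str] | None = None,
    method_policy: str = "auto",
) -> list[GroupComparison]:
    """One Mann-Whitney comparison per (metric, group pair).

    Comparisons are ordered metrics-major (canonical metric order, pairs as
    given), so output is deterministic for identical inputs.
    """
    metrics = list(metrics) if metrics is not None else CANONICAL_METRICS
    missing = [m for m in metrics if m not in results_table.columns]
    if missing:
        raise ConfigError(f"results table lacks metric columns {missing}")
    groups = results_table["group"].astype(str)
    known = set(groups)
    out: list[GroupComparison] = []
    for metric in metrics:
        for ga, gb in group_pairs:
            for g in (ga, gb):
                if g not in known:
                    raise ConfigError(f"unknown group label {g!r}")
            a = results_table.loc[groups == ga, metric].to_numpy(dtype=float)
            b = results_table.loc[groups == gb, metric].to_numpy(dtype=float)
            out.append(
                mann_whitney_u(
                    a,
                    b,
                    method_policy=method_policy,
                    alpha=alpha,
                    metric_name=metric,
                    group_a=ga,
                    group_b=gb,
                )
            )
    return out


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Tabulate comparisons with the standard column set."""
    rows = []
    for c in comparisons:
        rows.append(
            {
                "metric": c.metric_name,
                "group_a": c.group_a,
                "group_b": c.group_b,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "U": c.U,
                "p": c.p_two_sided,
                "method": c.method,
                "median_a": c.median_a,
                "ci_a_low": c.ci95_a[0],
                "ci_a_high": c.ci95_a[1],
                "median_b": c.median_b,
                "ci_b_low": c.ci95_b[0],
                "ci_b_high": c.ci95_b[1],
                "significant": c.significant,
            }
        )
    return pd.DataFrame(rows)
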