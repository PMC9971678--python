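"""Cohort group-comparison statistics.

Implements the analysis routine used for biomarker median-split cohorts:
binarize at the median, route each continuous variable to a pooled t test
or Mann-Whitney U according to Shapiro-Wilk normality in both groups,
compare dichotomous variables by Pearson chi-square or Fisher's exact
test according to the minimum expected cell count, Spearman-correlate the
biomarker with ordinal outcomes, and compute the analytic power of the
two-sample t test from the noncentral t distribution.

No multiplicity correction is applied; the comparison table records how
many tests were run and which route each variable took.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "binarize_by_median",
    "normality_route",
    "student_t",
    "mann_whitney_u",
    "dichotomous_test",
    "spearman",
    "PowerSpec",
    "t_test_power",
    "GroupComparisonResult",
    "build_comparison_table",
    "format_percent",
    "comparison_table_to_frame",
]

logger = logging.getLogger(__name__)

# combined-sample-size bound below which the Mann-Whitney p is exact
# (permutation enumeration); above it, or in the presence of ties, the
# tie-corrected normal approximation with continuity correction is used
MANN_WHITNEY_EXACT_MAX_N = 12


def binarize_by_median(values: Sequence[float]) -> tuple[np.ndarray, float]:
    """Split values into "low"/"high" groups at the sample median.

    The cutoff is the sample median; "low" means strictly below the
    cutoff, ties at the median go to "high" (a "< cutoff" convention).

    Returns ``(labels, cutoff)`` where labels is an array of "low"/"high".

    Raises
    ------
    ValueError : fewer than 2 finite values, or all values identical
        (degenerate split).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2 or not np.all(np.isfinite(x)):
        raise ValueError("need >= 2 finite values to binarize")
    if np.all(x == x[0]):
        raise ValueError("all values identical: median split is degenerate")
    cutoff = float(np.median(x))
    labels = np.where(x < cutoff, "low", "high")
    return labels, cutoff


def normality_route(x, y, alpha: float = 0.05) -> str:
    """Choose "t" vs "mannwhitney" by Shapiro-Wilk in both groups.

    Returns "t" iff the Shapiro-Wilk p-value exceeds ``alpha`` in *both*
    groups (no evidence against normality), else "mannwhitney".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3 in each group")
    for g in (x, y):
        if np.ptp(g) == 0:
            return "mannwhitney"  # constant sample: certainly not normal
    px = sps.shapiro(x).pvalue
    py = sps.shapiro(y).pvalue
    return "t" if (px > alpha and py > alpha) else "mannwhitney"


def student_t(x, y) -> tuple[float, int, float]:
    """Unpaired pooled-variance (Student) two-sample t test.

    Returns ``(t, df, p)`` with df = n1 + n2 - 2 and a two-sided p.
    Zero pooled variance with equal means gives (0, df, 1); with unequal
    means it is an error (infinite t).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need n >= 2 in each group")
    df = len(x) + len(y) - 2
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x[0] == y[0]:
            return 0.0, df, 1.0
        raise ValueError("zero pooled variance with unequal means: t undefined")
    res = sps.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), df, float(res.pvalue)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U test; returns ``(U, p)`` with U = min(U1, U2).

    The p-value is exact (full enumeration) when the combined sample size
    is at most 12 and there are no ties; otherwise the normal
    approximation with tie-corrected variance and continuity correction
    is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    use_exact = (len(x) + len(y) <= MANN_WHITNEY_EXACT_MAX_N) and not ties
    method = "exact" if use_exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u2 = len(x) * len(y) - u1
    return min(u1, u2), float(res.pvalue)


def dichotomous_test(table) -> tuple[str, float, float, float]:
    """Compare a dichotomous variable between two groups (2x2 table).

    Uses Pearson chi-square (no continuity correction) when the minimum
    *expected* cell count exceeds 5, otherwise Fisher's exact test
    (two-sided, summing tables at most as probable as the observed one).

    Returns ``(test_name, statistic, odds_ratio, p)`` where statistic is
    the chi-square value (NaN for Fisher).  The sample odds ratio uses
    the Haldane 0.5 correction only when a zero cell occurs.

    Raises
    ------
    ValueError : if any row or column margin is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin: association test undefined")
    a, b, c, d = t.ravel()
    if min(a, b, c, d) == 0:
        oratio = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        oratio = (a * d) / (b * c)
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if expected.min() > 5:
        chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
        return "chi2", float(chi2), float(oratio), float(p)
    _, p = sps.fisher_exact(t.astype(int), alternative="two-sided")
    return "fisher", float("nan"), float(oratio), float(p)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    Returns ``(rho, p)`` with p from the t approximation on n - 2 df.

    Raises
    ------
    ValueError : n < 4 or constant input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for the analytic two-sample t-test power computation."""

    cohens_d: float
    n_per_group: int
    alpha: float = 0.05

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


def t_test_power(spec: PowerSpec) -> float:
    """Power of the two-sided pooled two-sample t test.

    Computed from the noncentral t distribution with noncentrality
    ``d * sqrt(n/2)`` and ``2n - 2`` degrees of freedom, where n is the
    per-group sample size.  At d = 0 the power equals alpha.
    """
    n = spec.n_per_group
    df = 2 * n - 2
    nc = spec.cohens_d * math.sqrt(n / 2.0)
    tcrit = sps.t.ppf(1.0 - spec.alpha / 2.0, df)
    power = sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc)
    return float(power)


def format_percent(count: int, total: int) -> str:
    """Render a count as "count (pct%)" with the percentage rounded
    half-away-from-zero to an integer, e.g. 24/33 -> "24 (73%)"."""
    if total <= 0:
        raise ValueError("total must be > 0")
    pct = int(math.floor(100.0 * count / total + 0.5))
    return f"{count} ({pct}%)"


@dataclass(frozen=True)
class GroupComparisonResult:
    """One row of a two-group comparison table."""

    variable: str
    kind: str                      # "continuous" or "dichotomous"
    test: str                      # "t" / "mannwhitney" / "chi2" / "fisher"
    statistic: float
    p_value: float
    summary_a: str                 # mean +/- SD, or count (%)
    summary_b: str
    n_a: int
    n_b: int
    odds_ratio: Optional[float] = None


def _mean_sd(v: np.ndarray) -> str:
    return f"{np.mean(v):.1f} ± {np.std(v, ddof=1):.1f}"


def build_comparison_table(
    cohort: pd.DataFrame,
    grouping: str | Sequence[str],
    continuous: Sequence[str] = (),
    dichotomous: Sequence[str] = (),
    alpha: float = 0.05,
    group_order: Optional[tuple[str, str]] = None,
) -> list[GroupComparisonResult]:
    """Compare every listed variable between the two grouping levels.

    ``grouping`` is a column name in ``cohort`` or an explicit label
    sequence with exactly two levels.  Continuous variables are routed by
    :func:`normality_route`; dichotomous ones go through
    :func:`dichotomous_test`.  Variables with fewer than 2 observations
    in a group are skipped with a logged warning.  Group labels are
    reported explicitly in ``group_order`` order (default: sorted, so
    "high" before "low").
    """
    labels = cohort[grouping] if isinstance(grouping, str) else pd.Series(grouping)
    labels = np.asarray(labels)
    levels = group_order or tuple(sorted(pd.unique(labels)))
    if len(pd.unique(labels)) != 2 or len(levels) != 2:
        raise ValueError("grouping must have exactly two levels")
    ga, gb = (labels == levels[0]), (labels == levels[1])

    results: list[GroupComparisonResult] = []
    for var in continuous:
        va = pd.to_numeric(cohort.loc[ga, var], errors="coerce").dropna().to_numpy()
        vb = pd.to_numeric(cohort.loc[gb, var], errors="coerce").dropna().to_numpy()
        if len(va) < 2 or len(vb) < 2:
            logger.warning("skipping %s: fewer than 2 observations in a group", var)
            continue
        try:
            route = normality_route(va, vb, alpha=alpha)
        except ValueError:
            route = "mannwhitney"
        if route == "t":
            stat, _, p = student_t(va, vb)
        else:
            stat, p = mann_whitney_u(va, vb)
        logger.info("variable %s routed to %s (p=%.4g)", var, route, p)
        results.append(
            GroupComparisonResult(
                variable=var, kind="continuous", test=route, statistic=stat,
                p_value=p, summary_a=_mean_sd(va), summary_b=_mean_sd(vb),
                n_a=len(va), n_b=len(vb),
            )
        )
    for var in dichotomous:
        va = cohort.loc[ga, var].dropna().astype(int).to_numpy()
        vb = cohort.loc[gb, var].dropna().astype(int).to_numpy()
        if len(va) < 2 or len(vb) < 2:
            logger.warning("skipping %s: fewer than 2 observations in a group", var)
            continue
        table = [[int(va.sum()), int(len(va) - va.sum())],
                 [int(vb.sum()), int(len(vb) - vb.sum())]]
        try:
            test, stat, oratio, p = dichotomous_test(table)
        except ValueError as exc:
            logger.warning("skipping %s: %s", var, exc)
            continue
        logger.info("variable %s tested by %s (p=%.4g)", var, test, p)
        results.append(
            GroupComparisonResult(
                variable=var, kind="dichotomous", test=test, statistic=stat,
                p_value=p,
                summary_a=format_percent(int(va.sum()), len(va)),
                summary_b=format_percent(int(vb.sum()), len(vb)),
                n_a=len(va), n_b=len(vb), odds_ratio=oratio,
            )
        )
    logger.info("comparison table: %d tests performed, no multiplicity correction",
                len(results))
    return results


def comparison_table_to_frame(
    results: Sequence[GroupComparisonResult], group_names: tuple[str, str]
) -> pd.DataFrame:
    """Comparison rows as a DataFrame with explicit group-label columns."""
    return pd.DataFrame(
        {
            "variable": [r.variable for r in results],
            "kind": [r.kind for r in results],
            "test": [r.test for r in results],
            f"group_{group_names[0]}": [r.summary_a for r in results],
            f"group_{group_names[1]}": [r.summary_b for r in results],
            "statistic": [r.statistic for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "p_value": [r.p_value for r in results],
            f"n_{group_names[0]}": [r.n_a for r in results],
            f"n_{group_names[1]}": [r.n_b for r in results],
        }
    )
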