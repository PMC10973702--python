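"""Parametric feature-selection path.

Each feature is first tested for normality (Shapiro-Wilk); normal features
get a two-sample t-test, non-normal ones a Mann-Whitney U test, and features
are ranked by the resulting p-value.  A Pearson chi-square on 2x2 counts is
included for categorical demographics (e.g. sex by diagnosis).

Statistic sign convention for the t-test: control minus case, so a positive
statistic means the control group mean is larger.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .table import FeatureTable

__all__ = [
    "UnivariateResult",
    "route_by_normality",
    "two_sample_t",
    "mann_whitney_u",
    "chi_square_2x2",
    "run_univariate",
    "rank_features",
]


@dataclass
class UnivariateResult:
    feature_name: str
    normality_p: float
    routed_test: str  # "t-test" | "mann-whitney"
    statistic: float
    p_value: float


def route_by_normality(table: FeatureTable, alpha: float = 0.05) -> dict[str, str]:
    """Assign each feature to "t-test" (Shapiro-Wilk p >= alpha) or "mann-whitney"."""
    if table.na_mask.any():
        raise ValueError("routing expects an NA-free table")
    if table.n_subjects < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 subjects")
    routing = {}
    for j, name in enumerate(table.feature_names):
        p = stats.shapiro(table.values[:, j]).pvalue
        routing[name] = "t-test" if p >= alpha else "mann-whitney"
    return routing


def two_sample_t(
    x_case: np.ndarray, x_control: np.ndarray, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided two-sample t-test, statistic oriented control - case.

    Pooled variance by default; ``equal_var=False`` gives the Welch variant.
    """
    x_case = np.asarray(x_case, dtype=float)
    x_control = np.asarray(x_control, dtype=float)
    if len(x_case) < 2 or len(x_control) < 2:
        raise ValueError("each group needs at least 2 observations")
    if equal_var:
        n1, n0 = len(x_case), len(x_control)
        sp2 = (
            (n1 - 1) * x_case.var(ddof=1) + (n0 - 1) * x_control.var(ddof=1)
        ) / (n1 + n0 - 2)
        if sp2 == 0:
            raise ValueError("zero pooled variance")
    res = stats.ttest_ind(x_control, x_case, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(x_case: np.ndarray, x_control: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (case vs control).

    Exact null enumeration for small tie-free samples (both groups < 20);
    normal approximation with tie correction otherwise.
    """
    x_case = np.asarray(x_case, dtype=float)
    x_control = np.asarray(x_control, dtype=float)
    if len(x_case) < 1 or len(x_control) < 1:
        raise ValueError("each group needs at least 1 observation")
    small = max(len(x_case), len(x_control)) < 20
    ties = len(np.unique(np.concatenate([x_case, x_control]))) < len(x_case) + len(x_control)
    method = "exact" if (small and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x_case, x_control, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(counts) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, _, expected = stats.chi2_contingency(counts, correction=False)
    if (expected <= 0).any():
        raise ValueError("expected count <= 0")
    return float(chi2), float(p)


def run_univariate(
    table: FeatureTable,
    routing_alpha: float = 0.05,
    equal_var: bool = True,
) -> list[UnivariateResult]:
    """Route every feature by normality and run the routed two-sample test."""
    if not (table.labels == 1).any() or not (table.labels == 0).any():
        raise ValueError("both classes must be present")
    case = table.labels == 1
    results = []
    for j, name in enumerate(table.feature_names):
        col = table.values[:, j]
        normality_p = float(stats.shapiro(col).pvalue)
        if routing_alpha == 0 or normality_p >= routing_alpha:
            routed = "t-test"
            stat, p = two_sample_t(col[case], col[~case], equal_var=equal_var)
        else:
            routed = "mann-whitney"
            stat, p = mann_whitney_u(col[case], col[~case])
        results.append(UnivariateResult(name, normality_p, routed, stat, p))
    return results


def rank_features(
    results: list[UnivariateResult], threshold: float = 0.05
) -> list[UnivariateResult]:
    """Features with p < threshold, ascending p, ties broken by name."""
    if not results:
        raise ValueError("no results to rank")
    sig = [r for r in results if r.p_value < threshold]
    return sorted(sig, key=lambda r: (r.p_value, r.feature_name))
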