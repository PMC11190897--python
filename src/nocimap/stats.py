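"""Assumption-gated group comparisons.

Two-group and k-group comparisons where the test is chosen by explicit
gates: Shapiro-Wilk normality per group and an F-test (two groups) or
Levene-free variance-ratio logic for homogeneity. Normal + homoscedastic
data get the parametric test; normal but heteroscedastic two-group data
get Welch's correction; anything else falls back to the rank-based
alternative (Mann-Whitney U, or Kruskal-Wallis with Dunn post-tests).
The gate diagnostics are always reported alongside the chosen test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as ss

__all__ = ["GroupComparisonResult", "compare_groups"]


@dataclass
class GroupComparisonResult:
    test: str
    statistic: float
    pvalue: float
    diagnostics: dict = field(default_factory=dict)
    posthoc: list[dict] | None = None


def _variance_ratio_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F-test of equal variances."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    p = ss.f.sf(f, dfa, dfb) if f >= 1 else ss.f.cdf(f, dfa, dfb)
    return float(min(2 * p, 1.0))


def _shapiro_p(x: np.ndarray) -> float:
    if len(np.unique(x)) == 1:
        return 0.0  # degenerate: not plausibly normal
    return float(ss.shapiro(x).pvalue)


def _dunn_posthoc(groups: dict[str, np.ndarray]) -> list[dict]:
    """Dunn's rank-sum post-tests with Bonferroni adjustment."""
    names = list(groups)
    all_vals = np.concatenate([groups[g] for g in names])
    n = len(all_vals)
    ranks = ss.rankdata(all_vals)
    # tie correction term
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12 * (n - 1)) if n > 1 else 0.0
    mean_ranks = {}
    i = 0
    for g in names:
        k = len(groups[g])
        mean_ranks[g] = ranks[i : i + k].mean()
        i += k
    m = len(list(combinations(names, 2)))
    out = []
    for a, b in combinations(names, 2):
        na, nb = len(groups[a]), len(groups[b])
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = min(2 * ss.norm.sf(abs(z)) * m, 1.0)
        out.append({"a": a, "b": b, "statistic": float(z), "pvalue": float(p)})
    return out


def _bonferroni_ttests(groups: dict[str, np.ndarray]) -> list[dict]:
    names = list(groups)
    m = len(list(combinations(names, 2)))
    out = []
    for a, b in combinations(names, 2):
        t, p = ss.ttest_ind(groups[a], groups[b], equal_var=True)
        out.append({"a": a, "b": b, "statistic": float(t), "pvalue": float(min(p * m, 1.0))})
    return out


def compare_groups(
    samples: dict[str, "np.ndarray | list[float]"],
    alpha_gate: float = 0.05,
    alternative: str = "two-sided",
) -> GroupComparisonResult:
    """Gate-selected comparison of two or more groups.

    Two groups: Shapiro-Wilk per group; if both normal, an F-test decides
    between Student's t (homoscedastic) and Welch's t; otherwise
    Mann-Whitney U. More groups: one-way ANOVA with Bonferroni post-tests
    when all gates pass, else Kruskal-Wallis with Dunn post-tests. Groups
    with fewer than 3 observations force the nonparametric branch with a
    warning.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    names = list(groups)

    small = any(len(v) < 3 for v in groups.values())
    if small:
        import warnings

        warnings.warn("group with < 3 observations: nonparametric fallback", stacklevel=2)
        shapiro_ps = {g: float("nan") for g in names}
        normal = False
    else:
        shapiro_ps = {g: _shapiro_p(v) for g, v in groups.items()}
        normal = all(p > alpha_gate for p in shapiro_ps.values())

    if len(groups) == 2:
        a, b = (groups[n] for n in names)
        var_p = _variance_ratio_p(a, b) if not small else float("nan")
        diag = {"shapiro_p": shapiro_ps, "variance_ratio_p": var_p}
        if normal:
            if var_p > alpha_gate:
                t, p = ss.ttest_ind(a, b, equal_var=True, alternative=alternative)
                return GroupComparisonResult("t", float(t), float(p), diag)
            t, p = ss.ttest_ind(a, b, equal_var=False, alternative=alternative)
            return GroupComparisonResult("welch_t", float(t), float(p), diag)
        u, p = ss.mannwhitneyu(a, b, alternative=alternative)
        return GroupComparisonResult("mann_whitney_u", float(u), float(p), diag)

    # k groups
    vals = list(groups.values())
    if small:
        homoscedastic = False
        var_p = float("nan")
    else:
        var_p = float(ss.levene(*vals, center="mean").pvalue)  # k-group F-type gate
        homoscedastic = var_p > alpha_gate
    diag = {"shapiro_p": shapiro_ps, "variance_gate_p": var_p}
    if normal and homoscedastic:
        f, p = ss.f_oneway(*vals)
        return GroupComparisonResult(
            "anova", float(f), float(p), diag, posthoc=_bonferroni_ttests(groups)
        )
    h, p = ss.kruskal(*vals)
    return GroupComparisonResult(
        "kruskal_wallis", float(h), float(p), diag, posthoc=_dunn_posthoc(groups)
    )
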