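"""Univariate statistical primitives shared by all analysis stages.

Every statistic here (F, H, rank sums, studentized range q, Dunn z) is
computed from its defining formula; only the reference distributions
(F, chi-square, normal, studentized range) come from :mod:`scipy.stats`.
Results are returned as small typed records so downstream modules can
serialize them uniformly.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "anova_oneway",
    "tukey_hsd",
    "kruskal_wallis",
    "dunn_test",
    "wilcoxon_rank_sum",
    "adjust_p",
    "normality_route",
    "permutation_p",
    "EXACT_WILCOXON_MAX_N",
]

#: largest combined sample size for which the Wilcoxon null distribution is
#: enumerated exactly; beyond this the tie-corrected normal approximation
#: (with continuity correction) is used.
EXACT_WILCOXON_MAX_N = 20


@dataclass
class TestResult:
    """Outcome of a single hypothesis test.

    Attributes
    ----------
    statistic : float
        The test statistic (F, H, U, t, chi-square ... depending on ``method``).
    p_value : float
        Two-sided p-value in [0, 1] unless the method is inherently one-sided.
    df : tuple or float or None
        Degrees of freedom where the reference distribution has any.
    method : str
        Short label of the procedure that produced the result.
    degenerate : bool
        True when the input admitted no variation and the p-value was set to
        1 by convention.
    extra : dict
        Method-specific additions (e.g. a ratio of medians).
    """

    statistic: float
    p_value: float
    df: object = None
    method: str = ""
    degenerate: bool = False
    extra: dict = field(default_factory=dict)


# PosthocTable: represented as a pandas DataFrame with columns
# group_a, group_b, estimate, raw_p, adjusted_p, adjust_method — one row per
# unordered pair of groups.
POSTHOC_COLUMNS = ["group_a", "group_b", "estimate", "raw_p", "adjusted_p", "adjust_method"]


def _split_groups(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    labels = sorted(pd.unique(groups).tolist(), key=str)
    parts = [values[groups == g] for g in labels]
    return values, labels, parts


def _anova_decomposition(values, parts):
    n = values.size
    k = len(parts)
    grand = values.mean()
    ss_between = sum(p.size * (p.mean() - grand) ** 2 for p in parts)
    ss_within = sum(((p - p.mean()) ** 2).sum() for p in parts)
    df_b, df_w = k - 1, n - k
    return ss_between, ss_within, df_b, df_w


def anova_oneway(values, groups) -> TestResult:
    """One-way fixed-effects analysis of variance.

    F = MS_between / MS_within with (k-1, n-k) degrees of freedom. All-equal
    input is flagged degenerate with p = 1; a singleton group is rejected
    because the within-group mean square would be undefined for it.
    """
    values, labels, parts = _split_groups(values, groups)
    if len(parts) < 2:
        raise ValueError("anova_oneway requires at least 2 groups")
    for lab, p in zip(labels, parts):
        if p.size < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 observations")
    ss_b, ss_w, df_b, df_w = _anova_decomposition(values, parts)
    if ss_w <= 0 and ss_b <= 0:
        return TestResult(0.0, 1.0, (df_b, df_w), "anova_oneway", degenerate=True)
    if ss_w <= 0:
        return TestResult(math.inf, 0.0, (df_b, df_w), "anova_oneway")
    f = (ss_b / df_b) / (ss_w / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return TestResult(float(f), p, (df_b, df_w), "anova_oneway")


def tukey_hsd(values, groups) -> pd.DataFrame:
    """Tukey's honestly-significant-difference pairwise comparisons.

    For each unordered pair, q = |mean_a - mean_b| / sqrt(MS_within / 2 *
    (1/n_a + 1/n_b)) is referred to the studentized-range distribution with
    k groups and the ANOVA error degrees of freedom (Tukey-Kramer for
    unbalanced groups). Estimates are differences of means (a - b).
    """
    values, labels, parts = _split_groups(values, groups)
    if len(parts) < 2:
        raise ValueError("tukey_hsd requires at least 2 groups")
    for lab, p in zip(labels, parts):
        if p.size < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 observations")
    ss_b, ss_w, df_b, df_w = _anova_decomposition(values, parts)
    k = len(parts)
    ms_w = ss_w / df_w if df_w > 0 else 0.0
    degenerate = ms_w <= 0
    if degenerate:
        warnings.warn("tukey_hsd: zero within-group variance; all p set to 1")
    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
        pa, pb = parts[i], parts[j]
        est = pa.mean() - pb.mean()
        if degenerate:
            p = 1.0
        else:
            se = math.sqrt(ms_w / 2.0 * (1.0 / pa.size + 1.0 / pb.size))
            q = abs(est) / se
            p = float(sps.studentized_range.sf(q, k, df_w))
        rows.append((a, b, est, p, p, "tukey"))
    return pd.DataFrame(rows, columns=POSTHOC_COLUMNS)


def _midranks(values):
    return sps.rankdata(values, method="average")


def _tie_counts(values):
    _, counts = np.unique(values, return_counts=True)
    return counts[counts > 1]


def kruskal_wallis(values, groups) -> TestResult:
    """Kruskal-Wallis rank-sum test with midranks and tie correction."""
    values, labels, parts = _split_groups(values, groups)
    if len(parts) < 2:
        raise ValueError("kruskal_wallis requires at least 2 groups")
    n = values.size
    ranks = _midranks(values)
    if np.ptp(values) == 0:
        return TestResult(0.0, 1.0, len(parts) - 1, "kruskal_wallis", degenerate=True)
    h = 12.0 / (n * (n + 1)) * sum(
        ranks[np.asarray(groups) == g].sum() ** 2 / (np.asarray(groups) == g).sum()
        for g in labels
    ) - 3.0 * (n + 1)
    ties = _tie_counts(values)
    correction = 1.0 - (ties**3 - ties).sum() / (n**3 - n)
    h /= correction
    df = len(parts) - 1
    p = float(sps.chi2.sf(h, df))
    return TestResult(float(h), p, df, "kruskal_wallis")


def dunn_test(values, groups, adjust: str = "benjamini-hochberg") -> pd.DataFrame:
    """Dunn's post hoc test on ranks after a Kruskal-Wallis analysis.

    z_ab = (rbar_a - rbar_b) / sqrt((N(N+1)/12 - T) (1/n_a + 1/n_b)) with the
    tie term T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p, adjusted with
    Benjamini-Hochberg by default. Estimates are rank-mean differences.
    """
    values, labels, parts = _split_groups(values, groups)
    if len(parts) < 2:
        raise ValueError("dunn_test requires at least 2 groups")
    n = values.size
    ranks = _midranks(values)
    groups = np.asarray(groups)
    rbar = {g: ranks[groups == g].mean() for g in labels}
    sizes = {g: (groups == g).sum() for g in labels}
    ties = _tie_counts(values)
    tie_term = (ties**3 - ties).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term
    degenerate = var_base <= 0
    rows = []
    raw = []
    for a, b in itertools.combinations(labels, 2):
        est = rbar[a] - rbar[b]
        if degenerate:
            p = 1.0
        else:
            se = math.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = est / se
            p = float(2.0 * sps.norm.sf(abs(z)))
        rows.append([a, b, est, p])
        raw.append(p)
    adj = adjust_p(raw, method=adjust) if raw else []
    return pd.DataFrame(
        [r + [a, adjust] for r, a in zip(rows, adj)], columns=POSTHOC_COLUMNS
    )


def wilcoxon_rank_sum(x, y, exact_max_n: int = EXACT_WILCOXON_MAX_N) -> TestResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    Exact two-sided p by full enumeration of the C(n, n_x) rank assignments
    when the combined size does not exceed ``exact_max_n`` (ties handled by
    enumerating over the observed pooled values), otherwise a tie-corrected
    normal approximation with continuity correction. Statistic is the
    Mann-Whitney U of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    if np.ptp(pooled) == 0:
        return TestResult(float(u), 1.0, None, "wilcoxon_rank_sum", degenerate=True)
    if n <= exact_max_n:
        # enumerate U over every subset of size n1 of the pooled ranks
        us = np.array(
            [sum(c) - n1 * (n1 + 1) / 2.0 for c in itertools.combinations(ranks, n1)]
        )
        total = us.size
        p = 2.0 * min((us <= u).sum(), (us >= u).sum()) / total
        p = min(1.0, p)
        method = "wilcoxon_rank_sum_exact"
    else:
        mu = n1 * n2 / 2.0
        ties = _tie_counts(pooled)
        tie_term = (ties**3 - ties).sum() / (n * (n - 1))
        sd = math.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie_term))
        if sd == 0:
            return TestResult(float(u), 1.0, None, "wilcoxon_rank_sum", degenerate=True)
        z = (u - mu - 0.5 * np.sign(u - mu)) / sd
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        method = "wilcoxon_rank_sum_normal"
    return TestResult(float(u), float(p), None, method)


def adjust_p(pvals, method: str = "benjamini-hochberg"):
    """Multiple-testing adjustment, preserving input order.

    ``bonferroni``: min(1, m p). ``benjamini-hochberg``: step-up with
    enforced monotonicity.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.array([])
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method in ("benjamini-hochberg", "bh", "fdr_bh"):
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(1.0, adj)
        return out
    raise ValueError(f"unknown adjustment method: {method!r}")


def normality_route(residuals, alpha: float = 0.05) -> str:
    """Decide between parametric and rank-based testing from model residuals.

    Shapiro-Wilk at the given alpha: 'parametric' when normality is not
    rejected, 'nonparametric' otherwise. Constant residuals go the
    nonparametric route with a warning.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 3:
        raise ValueError("need at least 3 residuals to assess normality")
    if np.ptp(r) == 0:
        warnings.warn("normality_route: constant residuals; routing nonparametric")
        return "nonparametric"
    _, p = sps.shapiro(r)
    return "parametric" if p >= alpha else "nonparametric"


def permutation_p(observed: float, permuted, rule: str = "ge", plus_one: bool = False) -> float:
    """Empirical permutation p-value.

    ``rule='ge'`` is the fraction of permuted statistics greater than or
    equal to the observed one; it may return exactly 0. ``plus_one`` applies
    the (count + 1) / (N + 1) correction that counts the observed arrangement
    as one of the permutations.
    """
    permuted = np.asarray(permuted, dtype=float)
    if permuted.size == 0:
        raise ValueError("permuted must be nonempty")
    if rule != "ge":
        raise ValueError(f"unknown rule: {rule!r}")
    count = int((permuted >= observed).sum())
    if plus_one:
        return (count + 1) / (permuted.size + 1)
    return count / permuted.size
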