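"""Group-level statistics for learning and transfer effects.

Learning and transfer are quantified as the difference of pre- and
post-training thresholds in base-10 log units, ``log10(pre / post)``, which
is positive for an improvement and invariant under a common rescaling of
both thresholds.  The module provides the analyses applied to those scores:
two-tailed one-sample and independent t-tests with Cohen's d, one-way
between-subject ANOVA with eta squared and Bonferroni-corrected pairwise
contrasts, Shapiro-Wilk normality checks, and a noncentral-t power-based
sample-size determination for the one-sample design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "ContrastResult",
    "log_improvement",
    "one_sample_t",
    "independent_t",
    "cohens_d_from_t",
    "oneway_anova",
    "eta_squared_from_f",
    "pairwise_contrasts",
    "normality_check",
    "power_one_sample_t",
    "sample_size_one_sample_t",
]


@dataclass(frozen=True)
class TestResult:
    """A t or F test with its effect size."""

    statistic: float
    df: Union[float, tuple[float, float]]
    p: float
    effect_size: float
    effect_name: str  # "cohens_d" or "eta_squared"
    n: Union[int, tuple[int, ...]]
    flag: Optional[str] = None


@dataclass(frozen=True)
class ContrastResult:
    """One pairwise contrast, in both conventions (pooled ANOVA error term
    and Welch)."""

    pair: tuple[int, int]
    t_pooled: float
    df_pooled: float
    p_pooled: float
    p_pooled_adj: float
    t_welch: float
    df_welch: float
    p_welch: float
    p_welch_adj: float


def log_improvement(pre: float, post: float) -> float:
    """Improvement in log10 units: ``log10(pre / post)`` (> 0 when the
    threshold decreased)."""
    if not (pre > 0 and post > 0):
        raise ValueError("thresholds must be positive")
    return math.log10(pre / post)


def one_sample_t(scores: Sequence[float], mu0: float = 0.0) -> TestResult:
    """Two-tailed one-sample t-test with Cohen's d = (mean - mu0) / SD."""
    a = np.asarray(scores, dtype=float)
    n = a.size
    if n < 2:
        raise ValueError("need n >= 2")
    sd = a.std(ddof=1)
    if sd == 0:
        return TestResult(
            statistic=math.nan, df=n - 1, p=math.nan, effect_size=math.nan,
            effect_name="cohens_d", n=n, flag="degenerate: zero variance",
        )
    t, p = sps.ttest_1samp(a, popmean=mu0)
    d = (a.mean() - mu0) / sd
    return TestResult(float(t), n - 1, float(p), float(d), "cohens_d", n)


def independent_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-tailed independent-samples t-test (pooled variance) with Cohen's d
    using the pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    df = a.size + b.size - 2
    sp = math.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    )
    d = (a.mean() - b.mean()) / sp if sp > 0 else math.nan
    return TestResult(float(t), df, float(p), float(d), "cohens_d",
                      (a.size, b.size))


def cohens_d_from_t(t: float, n: int) -> float:
    """One-sample design identity ``d = t / sqrt(n)``."""
    if n < 2:
        raise ValueError("need n >= 2")
    return t / math.sqrt(n)


def eta_squared_from_f(f: float, df1: float, df2: float) -> float:
    """``eta^2 = df1*F / (df1*F + df2)``, the F-statistic form of the
    between/total sum-of-squares ratio."""
    return (df1 * f) / (df1 * f + df2)


def oneway_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way between-subject ANOVA with eta squared.

    Eta squared is computed from the sums of squares and checked against the
    ``df1*F / (df1*F + df2)`` identity.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with n >= 2 each")
    grand = np.concatenate(gs)
    ss_total = float(((grand - grand.mean()) ** 2).sum())
    ss_between = float(
        sum(g.size * (g.mean() - grand.mean()) ** 2 for g in gs)
    )
    ss_within = ss_total - ss_between
    df1 = len(gs) - 1
    df2 = grand.size - len(gs)
    if ss_within <= 0:
        return TestResult(
            statistic=math.inf, df=(df1, df2), p=0.0, effect_size=1.0,
            effect_name="eta_squared", n=tuple(g.size for g in gs),
            flag="degenerate: zero within-group variance",
        )
    f = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f, df1, df2))
    eta2 = ss_between / ss_total
    assert math.isclose(eta2, eta_squared_from_f(f, df1, df2),
                        rel_tol=1e-10, abs_tol=1e-12)
    return TestResult(float(f), (df1, df2), p, float(eta2), "eta_squared",
                      tuple(g.size for g in gs))


def pairwise_contrasts(
    groups: Sequence[Sequence[float]], correction: str = "bonferroni"
) -> list[ContrastResult]:
    """All pairwise contrasts after a one-way ANOVA.

    The primary statistic uses the pooled ANOVA error term (MS within, with
    its N - k degrees of freedom); a Welch t is reported alongside.  p-values
    are Bonferroni-adjusted over the number of pairs.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with n >= 2 each")
    n_total = sum(g.size for g in gs)
    k = len(gs)
    df_err = n_total - k
    mse = sum((g.size - 1) * g.var(ddof=1) for g in gs) / df_err
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    m = len(pairs) if correction == "bonferroni" else 1
    out = []
    for i, j in pairs:
        a, b = gs[i], gs[j]
        diff = a.mean() - b.mean()
        if mse > 0:
            t_p = diff / math.sqrt(mse * (1.0 / a.size + 1.0 / b.size))
            p_p = 2.0 * float(sps.t.sf(abs(t_p), df_err))
        else:
            t_p, p_p = (0.0, 1.0) if diff == 0 else (math.inf, 0.0)
        tw, pw = sps.ttest_ind(a, b, equal_var=False)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        if va + vb > 0:
            df_w = (va + vb) ** 2 / (
                va**2 / (a.size - 1) + vb**2 / (b.size - 1)
            )
        else:
            df_w = float(df_err)
        out.append(
            ContrastResult(
                pair=(i, j),
                t_pooled=float(t_p), df_pooled=float(df_err), p_pooled=p_p,
                p_pooled_adj=min(1.0, p_p * m),
                t_welch=float(tw), df_welch=float(df_w), p_welch=float(pw),
                p_welch_adj=min(1.0, float(pw) * m),
            )
        )
    return out


def normality_check(scores: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p (valid for 3 <= n <= 5000)."""
    a = np.asarray(scores, dtype=float)
    if not (3 <= a.size <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    w, p = sps.shapiro(a)
    return float(w), float(p)


def power_one_sample_t(d: float, n: int, alpha: float = 0.05) -> float:
    """Power of the two-tailed one-sample t-test at effect size ``d`` and
    sample size ``n``, from the noncentral t distribution with noncentrality
    ``d * sqrt(n)``."""
    if n < 2:
        raise ValueError("need n >= 2")
    df = n - 1
    nc = d * math.sqrt(n)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(
        sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc)
    )


def sample_size_one_sample_t(
    d: float, alpha: float = 0.05, power: float = 0.80, n_max: int = 100000
) -> int:
    """Smallest integer n such that the two-tailed one-sample t-test reaches
    the target power at effect size ``d`` (exact noncentral-t search, no
    normal approximation)."""
    if not (d > 0):
        raise ValueError("d must be > 0")
    if not (0.0 < alpha < 1.0 and 0.0 < power < 1.0):
        raise ValueError("alpha and power must lie in (0, 1)")
    for n in range(2, n_max + 1):
        if power_one_sample_t(d, n, alpha) >= power:
            return n
    raise ValueError("target power unattainable within n_max")
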