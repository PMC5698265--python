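"""Group statistics: summaries, one-way ANOVA and pairwise two-sample
tests, computable from raw per-animal values or from printed summary
statistics (mean, SD, n).

SD is the sample standard deviation (n - 1 denominator). Pairwise
comparisons default to the unadjusted pooled-variance t test; Welch and
Tukey-HSD variants are available behind the ``method`` flag. All tests are
two-sided.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "summarize",
    "pooled_t_from_summary",
    "welch_t_from_summary",
    "tukey_from_summaries",
    "one_way_anova",
    "pairwise_tests",
    "significance_pattern",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("group summaries need n >= 2")
        if self.sd < 0:
            raise ValueError("SD must be nonnegative")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: tuple[float, ...]
    p_value: float
    comparison: tuple[str, ...]
    test: str = "pooled-t"

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if any(d <= 0 for d in self.df):
            raise ValueError("degrees of freedom must be positive")


def summarize(values, label: str = "") -> GroupSummary:
    """Sample mean and SD (n - 1 denominator)."""
    x = np.asarray(list(values), dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values per group")
    return GroupSummary(label=label, n=len(x), mean=float(np.mean(x)),
                        sd=float(np.std(x, ddof=1)))


def _degenerate_p(a: GroupSummary, b: GroupSummary):
    """Convention when both SDs are exactly zero."""
    if a.mean == b.mean:
        return 0.0, 1.0
    log.warning("both SDs are 0 with different means (%s vs %s): p := 0",
                a.label, b.label)
    return math.inf, 0.0


def pooled_t_from_summary(a: GroupSummary, b: GroupSummary) -> TestResult:
    """Two-sided pooled-variance two-sample t test from summaries."""
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if sp2 == 0.0:
        t, p = _degenerate_p(a, b)
    else:
        se = math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
        t = (a.mean - b.mean) / se
        p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(statistic=t, df=(float(df),), p_value=p,
                      comparison=(a.label, b.label), test="pooled-t")


def welch_t_from_summary(a: GroupSummary, b: GroupSummary) -> TestResult:
    """Two-sided Welch (unequal-variance) t test from summaries."""
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    if va + vb == 0.0:
        t, p = _degenerate_p(a, b)
        df = float(a.n + b.n - 2)
    else:
        t = (a.mean - b.mean) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
        p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(statistic=t, df=(df,), p_value=p,
                      comparison=(a.label, b.label), test="welch-t")


def _coerce_summaries(groups) -> list[GroupSummary]:
    out = []
    for i, g in enumerate(groups):
        if isinstance(g, GroupSummary):
            out.append(g)
        else:
            out.append(summarize(g, label=f"group{i + 1}"))
    return out


def one_way_anova(groups) -> TestResult:
    """One-way fixed-effects ANOVA.

    ``groups``: list of GroupSummary or of raw value sequences. The
    summary path computes the between-SS from means and within-SS from SDs,
    which is exact, so both paths agree.
    """
    gs = _coerce_summaries(list(groups))
    if len(gs) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    n_total = sum(g.n for g in gs)
    k = len(gs)
    grand = sum(g.n * g.mean for g in gs) / n_total
    ss_between = sum(g.n * (g.mean - grand) ** 2 for g in gs)
    ss_within = sum((g.n - 1) * g.sd**2 for g in gs)
    df_b, df_w = k - 1, n_total - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0.0:
        f = 0.0 if ms_b == 0.0 else math.inf
        p = 1.0 if ms_b == 0.0 else 0.0
    else:
        f = ms_b / ms_w
        p = float(sps.f.sf(f, df_b, df_w))
    return TestResult(statistic=f, df=(float(df_b), float(df_w)), p_value=p,
                      comparison=tuple(g.label for g in gs), test="anova")


def tukey_from_summaries(groups: list[GroupSummary]) -> list[TestResult]:
    """Tukey HSD pairwise comparisons from summaries (studentized range)."""
    gs = list(groups)
    n_total = sum(g.n for g in gs)
    k = len(gs)
    df_w = n_total - k
    ms_w = sum((g.n - 1) * g.sd**2 for g in gs) / df_w
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = gs[i], gs[j]
            se = math.sqrt(ms_w / 2.0 * (1.0 / a.n + 1.0 / b.n))
            if se == 0.0:
                q, p = _degenerate_p(a, b)
            else:
                q = abs(a.mean - b.mean) / se
                p = float(sps.studentized_range.sf(q, k, df_w))
            out.append(TestResult(statistic=q, df=(float(df_w),),
                                  p_value=min(1.0, p),
                                  comparison=(a.label, b.label),
                                  test="tukey-hsd"))
    return out


def pairwise_tests(groups: list[GroupSummary],
                   method: str = "pooled") -> list[TestResult]:
    """All pairwise comparisons with the chosen method
    (``pooled`` | ``welch`` | ``tukey``)."""
    if method == "tukey":
        return tukey_from_summaries(groups)
    fn = {"pooled": pooled_t_from_summary, "welch": welch_t_from_summary}.get(method)
    if fn is None:
        raise ValueError("method must be 'pooled', 'welch' or 'tukey'")
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            out.append(fn(groups[i], groups[j]))
    return out


def significance_pattern(results, alpha: float = 0.05) -> pd.DataFrame:
    """Tidy comparison table with a strict p < alpha significance flag."""
    rows = []
    for r in results:
        rows.append({
            "comparison": " vs ".join(r.comparison),
            "test": r.test,
            "statistic": r.statistic,
            "df": r.df[0] if len(r.df) == 1 else str(tuple(r.df)),
            "p": r.p_value,
            "significant": bool(r.p_value < alpha),
        })
    return pd.DataFrame(rows, columns=["comparison", "test", "statistic",
                                       "df", "p", "significant"])
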