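"""Statistical tests used across the result tables, plus group summaries.

Choices (all configurable where noted): two-group comparisons use
Welch's t when both groups pass Shapiro-Wilk normality at alpha = 0.05,
otherwise Mann-Whitney U with tie correction; Dunn's pairwise z-tests
after Kruskal-Wallis use a Bonferroni adjustment over the tested pairs;
IQR summaries use linear-interpolation (type 7) quantiles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "ZeroVarianceError",
    "one_sample_test",
    "two_group_test",
    "paired_test",
    "kruskal_dunn",
    "group_summary",
]


class ZeroVarianceError(ValueError):
    """A t-statistic is undefined because the data have zero variance."""


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    n: tuple
    mean: Optional[float] = None
    sem: Optional[float] = None
    flags: list = field(default_factory=list)


def one_sample_test(values: Sequence[float], null_value: float) -> TestResult:
    """Two-sided one-sample t test against ``null_value``.

    Reports the sample mean and SEM alongside the test.

    Raises
    ------
    ZeroVarianceError
        When the sample has zero variance (t undefined).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2")
    if np.ptp(x) == 0:
        raise ZeroVarianceError("zero variance: one-sample t undefined")
    res = stats.ttest_1samp(x, null_value)
    return TestResult(
        test="one-sample t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(int(x.size),),
        mean=float(x.mean()),
        sem=float(stats.sem(x)),
    )


def two_group_test(a, b, mode: str = "auto") -> TestResult:
    """Two-sided two-group comparison.

    ``mode="t"`` forces Welch's t; ``mode="mann_whitney"`` forces the
    rank test; ``mode="auto"`` picks Welch's t when both groups pass
    Shapiro-Wilk at alpha = 0.05, otherwise Mann-Whitney U (tie
    corrected).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if mode not in ("auto", "t", "mann_whitney"):
        raise ValueError("unknown mode")
    flags = []
    if mode == "auto":
        normal = all(
            np.ptp(g) > 0 and stats.shapiro(g).pvalue > 0.05 for g in (a, b)
        )
        mode = "t" if normal else "mann_whitney"
        flags.append(f"auto->{mode}")
    if mode == "t":
        res = stats.ttest_ind(a, b, equal_var=False)
        name = "Welch t"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "Mann-Whitney U"
    return TestResult(test=name, statistic=float(res.statistic),
                      p_value=float(res.pvalue),
                      n=(int(a.size), int(b.size)), flags=flags)


def paired_test(pre, post) -> TestResult:
    """Two-sided paired t test on post - pre differences.

    Zero variance of the differences leaves the statistic undefined; the
    result is returned with NaN statistic/p and a ``zero_variance``
    flag rather than raising.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size != post.size:
        raise ValueError("pre and post must have equal length")
    if pre.size < 2:
        raise ValueError("need n >= 2 pairs")
    diff = post - pre
    if np.ptp(diff) == 0:
        return TestResult(test="paired t", statistic=float("nan"),
                          p_value=float("nan"), n=(int(pre.size),),
                          mean=float(diff.mean()),
                          flags=["zero_variance"])
    res = stats.ttest_rel(post, pre)
    return TestResult(test="paired t", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n=(int(pre.size),),
                      mean=float(diff.mean()), sem=float(stats.sem(diff)))


def kruskal_dunn(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    adjust: str = "bonferroni",
) -> tuple[TestResult, pd.DataFrame]:
    """Kruskal-Wallis across >= 3 groups plus Dunn's pairwise z-tests.

    Dunn's test compares mean ranks on the pooled (tie-corrected)
    ranking; pairwise p-values are Bonferroni-adjusted over the tested
    pairs by default (``adjust="none"`` disables the correction).

    Returns
    -------
    (TestResult, DataFrame)
        The global test and a pairwise table with columns
        ``group_a, group_b, z, p_raw, p_adj``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]

    H, p_global = stats.kruskal(*groups)
    global_res = TestResult(test="Kruskal-Wallis", statistic=float(H),
                            p_value=float(p_global),
                            n=tuple(int(g.size) for g in groups))

    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    N = pooled.size
    # tie correction term for the Dunn variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    sizes = [g.size for g in groups]
    mean_ranks = []
    start = 0
    for n in sizes:
        mean_ranks.append(ranks[start:start + n].mean())
        start += n

    pairs = list(itertools.combinations(range(len(groups)), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        se = np.sqrt(
            (N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1)))
            * (1.0 / sizes[i] + 1.0 / sizes[j])
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(p_raw * m, 1.0) if adjust == "bonferroni" else p_raw
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "z": float(z), "p_raw": float(p_raw),
                     "p_adj": float(p_adj)})
    return global_res, pd.DataFrame(rows)


def group_summary(values: Sequence[float]) -> dict:
    """Mean +/- SEM and the IQR (linear-interpolation quantiles)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty group")
    q1, q3 = np.percentile(x, [25, 75])  # type-7 linear interpolation
    return {
        "n": int(x.size),
        "mean": float(x.mean()),
        "sem": float(stats.sem(x)) if x.size > 1 else float("nan"),
        "median": float(np.median(x)),
        "iqr_low": float(q1),
        "iqr_high": float(q3),
    }
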