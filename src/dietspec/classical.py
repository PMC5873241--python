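"""The two classical tests used around the specialization indices.

One-way ANOVA compares mean prey sizes among taxa (or among individuals in
the single-resource subset); the paired t-test compares per-individual PS_i
values between the one-bout and pooled three-bout designs.  Statistics are
computed here; tail probabilities come from scipy's F and t distributions.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _stats


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its degrees of freedom, p-value, and sample size.

    ``df2`` is ``None`` for single-df-family tests (the paired t)."""

    statistic: float
    df1: float
    df2: float | None
    p_value: float
    n: int

    def __str__(self) -> str:
        if self.df2 is not None:
            return (
                f"F({self.df1:g}, {self.df2:g}) = {self.statistic:.2f}, "
                f"P = {self.p_value:.4g}"
            )
        return (
            f"t({self.df1:g}) = {self.statistic:.2f}, P = {self.p_value:.4g}"
        )


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within, df (k-1, n-k),
    p from the upper tail of the F distribution."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs at least 1 value")
    n = sum(a.size for a in arrays)
    if n <= k:
        raise ValueError("total sample size must exceed the number of groups")
    pooled = np.concatenate(arrays)
    grand = pooled.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ssw <= 0:
        raise ValueError("zero within-group variance: F is undefined")
    df1, df2 = k - 1, n - k
    f = (ssb / df1) / (ssw / df2)
    p = float(_stats.f.sf(f, df1, df2))
    return TestResult(statistic=float(f), df1=df1, df2=df2, p_value=p, n=n)


def paired_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided paired t-test on the differences x - y.

    t = mean(d) / (sd(d)/sqrt(n)) with the sample (n-1) standard deviation,
    df = n - 1.  All-zero differences are an error (no variability to test).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d sequences of equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = x - y
    if np.all(d == 0):
        raise ValueError("all differences are zero: nothing to test")
    sd = d.std(ddof=1)
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = float(2 * _stats.t.sf(abs(t), df))
    return TestResult(statistic=float(t), df1=df, df2=None, p_value=p, n=n)


def pairwise_welch_bonferroni(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """All pairwise Welch t-tests with Bonferroni correction.

    A stand-in post-hoc procedure for flagging which groups differ after a
    significant ANOVA (the groups here are typically individual foragers and
    the values their prey sizes); returns one row per pair with the raw and
    Bonferroni-corrected p-values.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(arrays))]
    if len(labels) != len(arrays):
        raise ValueError("labels must match groups")
    pairs = list(combinations(range(len(arrays)), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        t, p = _stats.ttest_ind(arrays[i], arrays[j], equal_var=False)
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "t": float(t),
                "p_raw": float(p),
                "p_bonferroni": float(min(1.0, p * m)),
            }
        )
    return pd.DataFrame(rows)
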