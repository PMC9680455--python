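"""Single-factor ANOVA and paired t-test.

Both tests are computed from first principles (sums of squares, mean
difference) with p-values from the exact F and t distributions — the
two-sided convention for t and the upper tail for F, matching common
spreadsheet output.  The test suite cross-checks them against scipy's
reference implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .errors import InvalidParameterError

__all__ = ["TestResult", "anova_single_factor", "paired_t_test"]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: tuple
    test_name: str


def anova_single_factor(groups) -> TestResult:
    """Classic one-way ANOVA: F = MS_between / MS_within.

    ``groups`` is a sequence of >= 2 sequences of measurements, each with
    >= 2 values.  Degrees of freedom are ``(k - 1, N - k)``.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise InvalidParameterError("ANOVA needs at least two groups")
    for i, g in enumerate(arrays):
        if g.ndim != 1 or len(g) < 2:
            raise InvalidParameterError(f"group {i} needs at least two values")
    N = sum(len(g) for g in arrays)
    k = len(arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df_b, df_w = k - 1, N - k
    if ss_within == 0 and ss_between == 0:
        raise InvalidParameterError("all values identical: F is undefined")
    if ss_within == 0:
        f_stat, p = math.inf, 0.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p = float(_sps.f.sf(f_stat, df_b, df_w))
    return TestResult(
        statistic=float(f_stat), p_value=p, df=(df_b, df_w),
        test_name="anova_single_factor",
    )


def paired_t_test(a, b) -> TestResult:
    """Paired two-sample t-test: t = mean(d) / (sd(d) / sqrt(n)).

    Two-sided p with ``df = n - 1``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidParameterError("paired t-test needs two equal-length 1-D samples")
    n = len(a)
    if n < 2:
        raise InvalidParameterError("paired t-test needs n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise InvalidParameterError("zero variance of differences: t is degenerate")
    t_stat = d.mean() / (sd / math.sqrt(n))
    p = float(2.0 * _sps.t.sf(abs(t_stat), n - 1))
    return TestResult(
        statistic=float(t_stat), p_value=p, df=(n - 1,), test_name="paired_t_test"
    )
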