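"""The study's statistical toolkit: median/IQR, Pearson chi-squared on 2x2
tables, relative risk, and the Wilcoxon rank-sum (Mann-Whitney) test with
normal approximation and tie correction.

All tests are two-sided. The chi-squared statistic is Pearson's without
continuity correction (a Yates-corrected variant is available behind a
flag). Quartiles use linear interpolation between order statistics.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats as _sps


@dataclasses.dataclass(frozen=True)
class TwoByTwoTable:
    """Exposure x outcome counts: a/b exposed with/without the outcome,
    c/d unexposed with/without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v}")
        if self.total == 0:
            raise ValueError("grand total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, col2) marginal totals."""
        return (
            self.a + self.b,
            self.c + self.d,
            self.a + self.c,
            self.b + self.d,
        )

    @property
    def is_degenerate(self) -> bool:
        return any(m == 0 for m in self.margins)


@dataclasses.dataclass
class StatResult:
    method: str  # "chi_squared" | "rank_sum" | "relative_risk"
    statistic: float | None = None
    p_value: float | None = None
    effect: float | None = None
    conf_int: tuple[float, float] | None = None
    n: int | None = None


@dataclasses.dataclass
class MedianIQR:
    median: float
    q1: float
    q3: float
    n: int


def median_iqr(values) -> MedianIQR:
    """Median and interquartile range by linear interpolation.

    Raises on an empty input.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr requires a non-empty list")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return MedianIQR(float(med), float(q1), float(q3), int(arr.size))


def chi_squared_2x2(t: TwoByTwoTable, yates: bool = False) -> StatResult:
    """Pearson chi-squared on a 2x2 table, df = 1.

    Closed form n(ad - bc)^2 / (r1 r2 c1 c2); no continuity correction by
    default. Raises on a zero margin (degenerate table).
    """
    if t.is_degenerate:
        raise ValueError("degenerate table: zero marginal total")
    r1, r2, c1, c2 = t.margins
    n = t.total
    diff = abs(t.a * t.d - t.b * t.c)
    if yates:
        diff = max(0.0, diff - n / 2.0)
    stat = n * diff * diff / (r1 * r2 * c1 * c2)
    p = float(_sps.chi2.sf(stat, df=1))
    return StatResult("chi_squared", statistic=float(stat), p_value=p, n=n)


def relative_risk(t: TwoByTwoTable, conf_level: float = 0.95) -> StatResult:
    """Relative risk (a/(a+b)) / (c/(c+d)) with a log-normal CI.

    Raises when the risk in the unexposed group is zero (RR undefined) or a
    row total is zero.
    """
    r1, r2, _, _ = t.margins
    if r1 == 0 or r2 == 0:
        raise ValueError("degenerate table: zero row total")
    if t.c == 0:
        raise ValueError("undefined RR: no outcomes among the unexposed")
    rr = (t.a / r1) / (t.c / r2)
    ci = None
    if t.a > 0:
        se = math.sqrt(1 / t.a - 1 / r1 + 1 / t.c - 1 / r2)
        z = float(_sps.norm.ppf(0.5 + conf_level / 2))
        ci = (rr * math.exp(-z * se), rr * math.exp(z * se))
    return StatResult("relative_risk", effect=float(rr), conf_int=ci, n=t.total)


def rank_sum_test(x, y) -> StatResult:
    """Two-sample Wilcoxon rank-sum test, normal approximation.

    Mid-ranks for ties; the variance carries the tie correction
    n1 n2 / 12 * [(N + 1) - sum(t^3 - t) / (N (N - 1))]. The statistic is the
    signed z for the first sample's rank sum (positive when x tends larger),
    p two-sided. Raises when every value in both samples is identical.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        raise ValueError("zero variance: all values identical across both samples")
    ranks = _sps.rankdata(combined, method="average")
    n1, n2 = x.size, y.size
    big_n = n1 + n2
    w = float(ranks[:n1].sum())
    mu = n1 * (big_n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
    z = (w - mu) / math.sqrt(var)
    p = float(2 * _sps.norm.sf(abs(z)))
    return StatResult("rank_sum", statistic=float(z), p_value=min(p, 1.0), n=big_n)
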