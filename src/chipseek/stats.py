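"""Statistics for search-validation studies of clinical free text.

Covers the full analysis toolkit: positive predictive value from chart
review, Yates-corrected 2x2 chi-squared tests, cohort proportion
comparisons, the Fleiss continuity-corrected two-proportion sample size,
age-at-event summaries (median / IQR), a two-sample t-test on
log-transformed ages, extrapolation of event counts from a sampled PPV,
and compliance fractions against a legislative deadline.

Conventions that matter (and are recorded on every result object):

* the chi-squared statistic uses the Yates continuity correction by
  default, with ``|O - E| - 0.5`` floored at zero;
* quantiles interpolate linearly between order statistics;
* the t-test is Welch's by default, computed on natural-log ages, with
  zero ages shifted by +1 day before the log.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .classify import ClassificationTable, HitCategory

__all__ = [
    "TwoByTwo",
    "ChiSqResult",
    "SampleSizeSpec",
    "AgeSummary",
    "LogTTestResult",
    "CategoryComparison",
    "Extrapolation",
    "ppv",
    "chisq_2x2",
    "compare_category_proportions",
    "fleiss_sample_size",
    "simulate_power",
    "age_days",
    "summarize_ages",
    "log_t_test",
    "extrapolate_events",
    "compliance_fraction",
]


@dataclass(frozen=True)
class TwoByTwo:
    """A 2x2 contingency table: row 1 = cohort 1 (yes, no); row 2 = cohort 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class ChiSqResult:
    statistic: float
    df: int
    p_value: float
    yates: bool


def ppv(true_positives: int, total_hits: int) -> float:
    """Positive predictive value: fraction of hits that are true events."""
    if total_hits <= 0:
        raise ValueError("total_hits must be positive")
    if not 0 <= true_positives <= total_hits:
        raise ValueError("true_positives must lie in [0, total_hits]")
    return true_positives / total_hits


def chisq_2x2(table: TwoByTwo, yates: bool = True) -> ChiSqResult:
    """Pearson chi-squared test on a 2x2 table with 1 degree of freedom.

    With ``yates`` (the default) each ``|O - E|`` is reduced by 0.5 and
    floored at zero before squaring, the classic continuity correction for
    1-df tables. Degenerate margins (an all-zero row or column) raise.
    """
    r1, r2, c1, c2 = table.margins()
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("degenerate 2x2 table: a row or column total is zero")
    n = table.n
    obs = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    expected = np.outer([r1, r2], [c1, c2]) / n
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev**2 / expected).sum())
    return ChiSqResult(
        statistic=stat, df=1, p_value=float(sps.chi2.sf(stat, 1)), yates=yates
    )


@dataclass(frozen=True)
class CategoryComparison:
    """One row of a cohort-vs-cohort false-positive reason comparison.

    Percentages use the false-positive totals as denominators (matching how
    such tables are usually printed), while the chi-squared test puts each
    count against the full cohort sample size — both conventions are
    carried explicitly.
    """

    category: HitCategory
    count_valid: int
    count_invalid: int
    pct_valid: float
    pct_invalid: float
    chisq: ChiSqResult | None
    note: str = ""


def compare_category_proportions(
    valid: ClassificationTable,
    invalid: ClassificationTable,
    *,
    min_total: int = 10,
) -> list[CategoryComparison]:
    """Compare false-positive reasons between the two chip-field cohorts.

    For every non-implantation category, the 2x2 test is
    (count, sample size - count) per cohort — i.e. denominators are the
    full cohort sample sizes. Percentages are reported over each cohort's
    false-positive total. Categories whose combined count across cohorts is
    below ``min_total`` (expected cell count < 5 under equal margins) are
    flagged "too infrequent" and not tested.
    """
    fp_valid = valid.total - valid[HitCategory.IMPLANTATION_EVENT]
    fp_invalid = invalid.total - invalid[HitCategory.IMPLANTATION_EVENT]
    rows: list[CategoryComparison] = []
    for cat in HitCategory:
        if cat is HitCategory.IMPLANTATION_EVENT:
            continue
        cv, ci = valid[cat], invalid[cat]
        chisq: ChiSqResult | None = None
        note = ""
        if cv + ci >= min_total:
            chisq = chisq_2x2(
                TwoByTwo(cv, valid.total - cv, ci, invalid.total - ci)
            )
        else:
            note = "too infrequent"
        rows.append(
            CategoryComparison(
                category=cat,
                count_valid=cv,
                count_invalid=ci,
                pct_valid=100.0 * cv / fp_valid if fp_valid else math.nan,
                pct_invalid=100.0 * ci / fp_invalid if fp_invalid else math.nan,
                chisq=chisq,
                note=note,
            )
        )
    return rows


@dataclass(frozen=True)
class SampleSizeSpec:
    """Two-proportion sample size with the Fleiss continuity correction."""

    p1: float
    p2: float
    power: float
    confidence: float
    n_uncorrected: float
    n_per_group: int


def fleiss_sample_size(
    p1: float, p2: float, power: float = 0.80, confidence: float = 0.95
) -> SampleSizeSpec:
    """Per-group n to detect p1 vs p2 (two-sided) with a continuity correction.

    The normal-approximation sample size

    .. math::

       n = \\frac{(z_{\\alpha/2}\\sqrt{2\\bar p\\bar q}
            + z_{\\beta}\\sqrt{p_1 q_1 + p_2 q_2})^2}{(p_1-p_2)^2}

    is inflated by the Fleiss continuity correction ``2 / |p1 - p2|`` and
    rounded up. Symmetric in (p1, p2); raises when p1 == p2.
    """
    for name, v in (("p1", p1), ("p2", p2), ("power", power), ("confidence", confidence)):
        if not 0 < v < 1:
            raise ValueError(f"{name} must lie strictly between 0 and 1")
    if p1 == p2:
        raise ValueError("sample size is undefined for p1 == p2")
    z_alpha = sps.norm.ppf(1 - (1 - confidence) / 2)
    z_beta = sps.norm.ppf(power)
    pbar = (p1 + p2) / 2
    n = (
        z_alpha * math.sqrt(2 * pbar * (1 - pbar))
        + z_beta * math.sqrt(p1 * (1 - p1) + p2 * (1 - p2))
    ) ** 2 / (p1 - p2) ** 2
    n_cc = n + 2 / abs(p1 - p2)
    return SampleSizeSpec(
        p1=p1,
        p2=p2,
        power=power,
        confidence=confidence,
        n_uncorrected=n,
        n_per_group=math.ceil(n_cc),
    )


def simulate_power(
    p1: float,
    p2: float,
    n_per_group: int,
    *,
    reps: int = 20_000,
    alpha: float = 0.05,
    seed: int = 0,
    yates: bool = True,
) -> float:
    """Monte-Carlo power of the 2x2 chi-squared test at the given group size.

    Draws ``reps`` pairs of binomial samples and applies the (optionally
    Yates-corrected) test, returning the rejection fraction at ``alpha``.
    Vectorised; degenerate draws (an all-zero margin) count as
    non-rejections.
    """
    rng = np.random.default_rng(seed)
    a = rng.binomial(n_per_group, p1, reps).astype(float)
    c = rng.binomial(n_per_group, p2, reps).astype(float)
    b, d = n_per_group - a, n_per_group - c
    n = 2.0 * n_per_group
    c1, c2 = a + c, b + d
    ok = (c1 > 0) & (c2 > 0)
    cross = np.abs(a * d - b * c)
    if yates:
        cross = np.maximum(cross - n / 2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * cross**2 / (n_per_group * n_per_group * c1 * c2)
    reject = ok & (sps.chi2.sf(stat, 1) < alpha)
    return float(reject.mean())


def age_days(date_of_birth: date, event_date: date) -> int:
    """Whole-day age at an event; negative differences raise (bad record)."""
    delta = (event_date - date_of_birth).days
    if delta < 0:
        raise ValueError(
            f"event date {event_date} precedes date of birth {date_of_birth}"
        )
    return delta


@dataclass(frozen=True)
class AgeSummary:
    n: int
    median_days: float
    iqr_days: float


def summarize_ages(ages: Sequence[float]) -> AgeSummary:
    """Median and IQR of ages via linear-interpolation quantiles."""
    if len(ages) == 0:
        raise ValueError("ages must be non-empty")
    arr = np.asarray(ages, dtype=float)
    q25, q50, q75 = np.percentile(arr, [25, 50, 75])
    return AgeSummary(n=len(arr), median_days=float(q50), iqr_days=float(q75 - q25))


@dataclass(frozen=True)
class LogTTestResult:
    t_statistic: float
    p_value: float
    df: float
    equal_var: bool
    zeros_shifted: bool


def log_t_test(
    group_a: Sequence[float], group_b: Sequence[float], *, equal_var: bool = False
) -> LogTTestResult:
    """Two-sample t-test on natural-log ages (Welch by default).

    Ages of exactly 0 days are shifted to 1 day before the log (recorded in
    the result); negative ages raise. The statistic is invariant to the log
    base and to rescaling both groups by a common positive constant.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("ages must be non-negative")
    shifted = bool((a == 0).any() or (b == 0).any())
    a = np.where(a == 0, 1.0, a)
    b = np.where(b == 0, 1.0, b)
    res = sps.ttest_ind(np.log(a), np.log(b), equal_var=equal_var)
    return LogTTestResult(
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.df),
        equal_var=equal_var,
        zeros_shifted=shifted,
    )


@dataclass(frozen=True)
class Extrapolation:
    """Estimated event count among all hits, exact and to 2 significant figures."""

    total_hits: int
    ppv: float
    exact: float
    rounded: float


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    mag = math.floor(math.log10(abs(x)))
    return round(x, -(mag - sig + 1))


def extrapolate_events(total_hits: int, ppv_value: float) -> Extrapolation:
    """Scale a sampled PPV up to the full hit count."""
    if total_hits < 0 or not 0 <= ppv_value <= 1:
        raise ValueError("need total_hits >= 0 and ppv in [0, 1]")
    exact = total_hits * ppv_value
    return Extrapolation(
        total_hits=total_hits, ppv=ppv_value, exact=exact, rounded=_round_sig(exact)
    )


def compliance_fraction(ages: Sequence[float], deadline_days: float) -> float:
    """Fraction of implantation ages at or below a legislative deadline."""
    arr = np.asarray(ages, dtype=float)
    if arr.size == 0:
        raise ValueError("ages must be non-empty")
    return float((arr <= deadline_days).mean())
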