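"""Evaluation statistics for dichotomous classifiers against a binary outcome.

Everything is computed from first principles on counts: 2x2 diagnostic
metrics with Wilson score intervals, McNemar's paired test (exact binomial
branch for small discordant totals, continuity-corrected chi-square
otherwise), the odds ratio with a Woolf log-normal interval, the Pearson
r x c chi-square, the Wilcoxon rank-sum test with midranks and tie-corrected
normal approximation, and the Welch t-test.  scipy supplies only the
reference distributions (normal, chi-square, t, binomial) and midranks.

Report-time rounding follows a half-up one-decimal percent convention
(:func:`percent`); internal values keep full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TwoByTwo",
    "MetricCI",
    "DiagnosticMetrics",
    "ORResult",
    "TestResult",
    "round_half_up",
    "percent",
    "wilson_interval",
    "confusion",
    "diagnostic_metrics",
    "mcnemar",
    "odds_ratio",
    "chi2_rxc",
    "wilcoxon_ranksum",
    "welch_t",
    "welch_t_from_summary",
]

_Z95 = 1.96  # two-sided 95% normal quantile, as conventionally rounded


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed clinical
    tables), not banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(p: float, ndigits: int = 1) -> float:
    """Proportion -> percent with half-up rounding."""
    return round_half_up(100.0 * p, ndigits)


@dataclass(frozen=True)
class TwoByTwo:
    """Classification-versus-outcome count table.

    Rows are predicted MAJOR / NONMAJOR, columns are poor / good outcome:
    ``tp`` = major & poor, ``fp`` = major & good, ``fn`` = non-major & poor,
    ``tn`` = non-major & good.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def swap_rows(self) -> "TwoByTwo":
        return TwoByTwo(tp=self.fn, fp=self.tn, fn=self.tp, tn=self.fp)

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fp], [self.fn, self.tn]], dtype=float)


def confusion(predicted_major: Sequence, poor_outcome: Sequence) -> TwoByTwo:
    """Cross-tabulate a boolean prediction against the poor-outcome label."""
    pred = np.asarray(predicted_major, dtype=bool)
    poor = np.asarray(poor_outcome, dtype=bool)
    if pred.shape != poor.shape or pred.ndim != 1:
        raise ValueError("predictions and outcomes must be equal-length 1-d sequences")
    if pred.size == 0:
        raise ValueError("empty input")
    return TwoByTwo(
        tp=int(np.sum(pred & poor)),
        fp=int(np.sum(pred & ~poor)),
        fn=int(np.sum(~pred & poor)),
        tn=int(np.sum(~pred & ~poor)),
    )


@dataclass(frozen=True)
class MetricCI:
    """A proportion with its two-sided 95% Wilson interval.

    ``defined`` is False when the denominator is zero, in which case the
    numbers are NaN rather than an error.
    """

    estimate: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int
    defined: bool = True


def wilson_interval(k: int, n: int, z: float = _Z95) -> tuple:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        return (math.nan, math.nan)
    p = k / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = (z / denom) * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
    lo = 0.0 if k == 0 else max(0.0, centre - half)
    hi = 1.0 if k == n else min(1.0, centre + half)
    return (lo, hi)


def _metric(k: int, n: int) -> MetricCI:
    if n == 0:
        return MetricCI(math.nan, math.nan, math.nan, k, n, defined=False)
    lo, hi = wilson_interval(k, n)
    return MetricCI(k / n, lo, hi, k, n)


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: MetricCI
    specificity: MetricCI
    ppv: MetricCI
    npv: MetricCI
    accuracy: MetricCI
    prevalence: float

    def rounded_percents(self) -> dict:
        return {
            name: percent(getattr(self, name).estimate)
            for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy")
        }


def diagnostic_metrics(t: TwoByTwo) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV, accuracy with Wilson 95% CIs.

    The exact identity accuracy = prevalence*sensitivity +
    (1-prevalence)*specificity holds on the returned counts.
    """
    return DiagnosticMetrics(
        sensitivity=_metric(t.tp, t.tp + t.fn),
        specificity=_metric(t.tn, t.tn + t.fp),
        ppv=_metric(t.tp, t.tp + t.fp),
        npv=_metric(t.tn, t.tn + t.fn),
        accuracy=_metric(t.tp + t.tn, t.n),
        prevalence=(t.tp + t.fn) / t.n if t.n else math.nan,
    )


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: Optional[float]
    p_value: float
    method: str
    degenerate: bool = False


#: Discordant-pair total at or below which McNemar uses the exact binomial.
MCNEMAR_EXACT_THRESHOLD = 25


def mcnemar(b: int, c: int, exact_threshold: int = MCNEMAR_EXACT_THRESHOLD) -> TestResult:
    """McNemar's test from the two discordant counts of a paired 2x2.

    Exact two-sided binomial p (doubled smaller tail, capped at 1) when
    ``b + c <= exact_threshold``; otherwise the continuity-corrected
    chi-square on 1 df.  ``b + c == 0`` yields p = 1 with a degenerate flag.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return TestResult(0.0, None, 1.0, "mcnemar-degenerate", degenerate=True)
    if n <= exact_threshold:
        k = min(b, c)
        p = min(1.0, 2.0 * float(sps.binom.cdf(k, n, 0.5)))
        return TestResult(float(k), None, p, "mcnemar-exact")
    stat = (abs(b - c) - 1) ** 2 / n
    return TestResult(stat, 1, float(sps.chi2.sf(stat, 1)), "mcnemar-chi2-cc")


@dataclass(frozen=True)
class ORResult:
    estimate: float
    ci_low: float
    ci_high: float
    log_se: float
    continuity_corrected: bool = False


def odds_ratio(t: TwoByTwo, z: float = _Z95) -> ORResult:
    """Cross-product odds ratio with the Woolf log-normal 95% interval.

    If any cell is zero the Haldane-Anscombe 0.5 correction is added to all
    four cells and the result is flagged.
    """
    cells = [t.tp, t.fp, t.fn, t.tn]
    corrected = any(v == 0 for v in cells)
    a, b_, c_, d = ((v + 0.5) for v in cells) if corrected else cells
    est = (a * d) / (b_ * c_)
    se = math.sqrt(1 / a + 1 / b_ + 1 / c_ + 1 / d)
    log_or = math.log(est)
    return ORResult(
        estimate=est,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        log_se=se,
        continuity_corrected=corrected,
    )


def chi2_rxc(table, yates: bool = False) -> TestResult:
    """Pearson chi-square for an r x c count table, df = (r-1)(c-1).

    No continuity correction for general tables; ``yates=True`` applies the
    Yates correction (2x2 only).  A zero marginal row or column is an error.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero marginal row or column")
    expected = np.outer(rows, cols) / obs.sum()
    diff = np.abs(obs - expected)
    if yates:
        if obs.shape != (2, 2):
            raise ValueError("Yates correction applies to 2x2 tables only")
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float(np.sum(diff**2 / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    method = "pearson-chi2-yates" if yates else "pearson-chi2"
    return TestResult(stat, df, float(sps.chi2.sf(stat, df)), method)


def wilcoxon_ranksum(x: Sequence, y: Sequence) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Midranks handle ties; the normal approximation uses the tie-corrected
    null variance of the rank sum of ``x``.  If every value across both
    groups is identical the result is degenerate with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    w = float(ranks[:n1].sum())
    n = n1 + n2
    mean_w = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:
        return TestResult(w, None, 1.0, "wilcoxon-ranksum-degenerate", degenerate=True)
    z = (w - mean_w) / math.sqrt(var_w)
    return TestResult(w, None, float(2 * sps.norm.sf(abs(z))), "wilcoxon-ranksum-normal")


def welch_t(x: Sequence, y: Sequence) -> TestResult:
    """Welch's unequal-variance t-test with Satterthwaite df, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    return welch_t_from_summary(
        float(x.mean()), float(x.std(ddof=1)), x.size,
        float(y.mean()), float(y.std(ddof=1)), y.size,
    )


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    """Welch's t from group summary statistics (mean, SD, n)."""
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0:
        raise ValueError("zero variance in both groups")
    stat = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TestResult(stat, df, float(2 * sps.t.sf(abs(stat), df)), "welch-t")
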