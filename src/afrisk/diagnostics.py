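"""Diagnostic-accuracy statistics and the group-comparison tests.

All ratios are kept at full precision internally; rendering rounds half-up
only at output time (``render_percent`` / ``render_value``). Undefined
quantities (zero denominators) are NaN-flagged, never 0 or 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import stats

from .protocol import ContingencyTable

__all__ = [
    "DiagnosticStats",
    "GroupTestResult",
    "diagnostic_stats",
    "compare_quantitative",
    "compare_qualitative",
    "render_percent",
    "render_value",
]


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def _wilson_ci(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    if n == 0:
        return (math.nan, math.nan)
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (max(center - half, 0.0), min(center + half, 1.0))


@dataclass(frozen=True)
class DiagnosticStats:
    sens: float
    spec: float
    ppv: float
    npv: float
    accuracy: float
    lr_pos: float
    lr_neg: float
    n_total: int
    ci: dict  # 95% CIs (Wilson for proportions, log method for LRs); extension

    def as_dict(self) -> dict:
        return {
            "sens": self.sens,
            "spec": self.spec,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
            "lr_pos": self.lr_pos,
            "lr_neg": self.lr_neg,
        }


@dataclass(frozen=True)
class GroupTestResult:
    test_name: str  # t | mann_whitney | fisher | chi2
    statistic: float
    p_value: float

    def __post_init__(self):
        if not math.isnan(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")


def diagnostic_stats(table: ContingencyTable) -> DiagnosticStats:
    """The seven accuracy statistics of a 2x2 table.

    sens = tp/(tp+fn), spec = tn/(tn+fp), ppv = tp/(tp+fp), npv = tn/(tn+fn),
    accuracy = (tp+tn)/n, lr+ = sens/(1-spec), lr- = (1-sens)/spec. Each is
    NaN-flagged when its denominator is zero.
    """
    if table.n_total == 0:
        raise ValueError("empty contingency table")
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    lr_pos = (
        sens / (1.0 - spec)
        if not math.isnan(sens) and not math.isnan(spec) and spec < 1.0
        else math.nan
    )
    lr_neg = (
        (1.0 - sens) / spec
        if not math.isnan(sens) and not math.isnan(spec) and spec > 0.0
        else math.nan
    )
    ci = {
        "sens": _wilson_ci(tp, tp + fn),
        "spec": _wilson_ci(tn, tn + fp),
        "ppv": _wilson_ci(tp, tp + fp),
        "npv": _wilson_ci(tn, tn + fn),
        "accuracy": _wilson_ci(tp + tn, table.n_total),
    }
    # log-method CIs for likelihood ratios (only when all cells allow it)
    if min(tp, fp, fn, tn) > 0:
        z = 1.959963984540054
        se_pos = math.sqrt(1 / tp - 1 / (tp + fn) + 1 / fp - 1 / (fp + tn))
        se_neg = math.sqrt(1 / fn - 1 / (tp + fn) + 1 / tn - 1 / (fp + tn))
        ci["lr_pos"] = (lr_pos * math.exp(-z * se_pos), lr_pos * math.exp(z * se_pos))
        ci["lr_neg"] = (lr_neg * math.exp(-z * se_neg), lr_neg * math.exp(z * se_neg))
    return DiagnosticStats(
        sens=sens,
        spec=spec,
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        accuracy=_ratio(tp + tn, table.n_total),
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        n_total=table.n_total,
        ci=ci,
    )


def render_value(x: float, decimals: int) -> float:
    """Round half-up to ``decimals`` places (rendering only, never internal)."""
    if math.isnan(x):
        return math.nan
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def render_percent(p: float, decimals: int = 0) -> float:
    """Render a proportion as a half-up rounded percentage."""
    return render_value(p * 100.0, decimals)


def compare_quantitative(
    x, y, normality_alpha: float = 0.05
) -> GroupTestResult:
    """Two-group comparison of a quantitative variable.

    Shapiro-Wilk screens each group at ``normality_alpha``; if both pass, a
    two-sample Student t-test is used, otherwise Mann-Whitney. The chosen
    test is recorded in the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each sample needs n >= 3")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        return GroupTestResult("t", math.nan, math.nan)
    normal = True
    for s in (x, y):
        if np.ptp(s) == 0:
            normal = False
            break
        if stats.shapiro(s).pvalue < normality_alpha:
            normal = False
            break
    if normal:
        res = stats.ttest_ind(x, y)
        return GroupTestResult("t", float(res.statistic), float(res.pvalue))
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return GroupTestResult("mann_whitney", float(res.statistic), float(res.pvalue))


def compare_qualitative(table) -> GroupTestResult:
    """Two-group comparison of a qualitative (2x2) variable.

    Fisher's exact test when any expected cell count is below 5, otherwise
    the chi-squared test with continuity correction.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or np.any(arr < 0):
        raise ValueError("need a non-negative 2x2 table")
    if arr.sum() == 0:
        return GroupTestResult("fisher", math.nan, math.nan)
    row = arr.sum(axis=1, keepdims=True)
    col = arr.sum(axis=0, keepdims=True)
    expected = row @ col / arr.sum()
    if np.any(expected < 5):
        odds, p = stats.fisher_exact(arr)
        return GroupTestResult("fisher", float(odds), float(p))
    res = stats.chi2_contingency(arr, correction=True)
    return GroupTestResult("chi2", float(res.statistic), float(res.pvalue))
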