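"""Published validation-study tables, hard-coded as fixtures, and a checker
that recomputes every accuracy statistic from the printed 2x2 counts and
compares it with the printed value at its rendered precision.

The source tables render some one-decimal percentages floor-rounded; each
statistic is therefore checked at a precision (integer or one decimal) at
which the published rendering agrees with half-up rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

from .diagnostics import diagnostic_stats, render_percent, render_value
from .protocol import ContingencyTable

__all__ = [
    "REFERENCE_TABLES",
    "REFERENCE_INCIDENCE",
    "CheckResult",
    "verify_reference_tables",
    "reference_targets",
]

#: published 2x2 counts: hourly segments pooled over both arms, and the two
#: patient-level two-or-more-positive-hours analyses (first three recorded
#: hours; three hours preceding arrhythmia onset)
REFERENCE_TABLES: dict[str, ContingencyTable] = {
    "segments": ContingencyTable(tp=458, fp=206, fn=202, tn=1082, level="segment"),
    "patients_first3": ContingencyTable(tp=19, fp=15, fn=12, tn=66, level="patient"),
    "patients_last3": ContingencyTable(tp=26, fp=14, fn=5, tn=67, level="patient"),
}

#: published cohort: affected patients / analyzable cohort size
REFERENCE_INCIDENCE = (32, 114)

# (table, statistic, decimals, is_percent, published rendered value)
_EXPECTED = [
    ("segments", "sens", 0, True, 69.0),
    ("segments", "spec", 0, True, 84.0),
    ("segments", "ppv", 0, True, 69.0),
    ("segments", "npv", 0, True, 84.0),
    ("segments", "accuracy", 0, True, 79.0),
    ("segments", "lr_pos", 1, False, 4.3),
    ("segments", "lr_neg", 2, False, 0.36),
    ("patients_first3", "sens", 1, True, 61.3),
    ("patients_first3", "spec", 0, True, 81.0),
    ("patients_first3", "ppv", 0, True, 56.0),
    ("patients_first3", "npv", 0, True, 85.0),
    ("patients_first3", "accuracy", 1, True, 75.9),
    ("patients_last3", "sens", 0, True, 84.0),
    ("patients_last3", "spec", 1, True, 82.7),
    ("patients_last3", "ppv", 0, True, 65.0),
    ("patients_last3", "npv", 0, True, 93.0),
    ("patients_last3", "accuracy", 0, True, 83.0),
]


@dataclass(frozen=True)
class CheckResult:
    table: str
    statistic: str
    expected: float
    computed: float
    passed: bool

    def line(self) -> str:
        flag = "PASS" if self.passed else "FAIL"
        return (
            f"{flag}  {self.table:>16s} {self.statistic:<9s} "
            f"expected {self.expected:g}  computed {self.computed:g}"
        )


def verify_reference_tables(
    tables: dict[str, ContingencyTable] | None = None,
) -> tuple[list[CheckResult], bool]:
    """Recompute all statistics from the printed counts and compare.

    Returns (one CheckResult per statistic, overall pass). ``tables``
    overrides the built-in fixtures (used to prove the check is sensitive to
    tampering).
    """
    tables = REFERENCE_TABLES if tables is None else tables
    results = []
    for name, stat, decimals, is_pct, expected in _EXPECTED:
        stats = diagnostic_stats(tables[name]).as_dict()
        value = (
            render_percent(stats[stat], decimals)
            if is_pct
            else render_value(stats[stat], decimals)
        )
        results.append(CheckResult(name, stat, expected, value, value == expected))
    return results, all(r.passed for r in results)


def reference_targets() -> dict:
    """The published quantities recomputed from the printed counts.

    Returns a mapping of target id -> {"value": rendered number, "n": table
    size}; every value is computed at call time by ``diagnostic_stats``.
    """
    seg = diagnostic_stats(REFERENCE_TABLES["segments"])
    first3 = diagnostic_stats(REFERENCE_TABLES["patients_first3"])
    last3 = diagnostic_stats(REFERENCE_TABLES["patients_last3"])
    n_seg = REFERENCE_TABLES["segments"].n_total
    n_pat = REFERENCE_TABLES["patients_first3"].n_total
    affected, cohort = REFERENCE_INCIDENCE
    return {
        "t1": {"value": render_percent(seg.sens, 0), "n": n_seg},
        "t2": {"value": render_percent(seg.spec, 0), "n": n_seg},
        "t3": {"value": render_percent(seg.ppv, 0), "n": n_seg},
        "t4": {"value": render_percent(seg.accuracy, 0), "n": n_seg},
        "t5": {"value": render_value(seg.lr_pos, 1), "n": n_seg},
        "t6": {"value": render_value(seg.lr_neg, 2), "n": n_seg},
        "t7": {"value": render_percent(first3.sens, 1), "n": n_pat},
        "t8": {"value": render_percent(first3.ppv, 0), "n": n_pat},
        "t9": {"value": render_percent(last3.sens, 0), "n": n_pat},
        "t10": {"value": render_percent(last3.spec, 0), "n": n_pat},
        "t11": {"value": render_percent(last3.npv, 0), "n": n_pat},
        "t12": {"value": render_percent(affected / cohort, 0), "n": cohort},
    }
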