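"""Case/control segment selection and patient-level prediction rules.

Group I: patients who developed AF (>= 30 s) during monitoring; their
analyzable hourly segments in the 24 h window ending at onset are the case
segments. Group II: patients without AF; their analyzable postoperative
day-2 segments are the controls. Patient-level calls use the
"two-or-more-positive hours out of three" rule on the FIRST3 and LAST3
windows. A positive segment from a group-II patient is a false positive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .classifier import ClassifierConfig, RiskResult, classify_series
from .ingest import BeatSeries, HourSegment, SECONDS_PER_HOUR, segment_hours
from . import features
from .features import SpectralHRV

__all__ = [
    "ProtocolError",
    "PatientRecord",
    "WindowCall",
    "ContingencyTable",
    "CohortEvaluation",
    "analyze_record",
    "select_case_segments",
    "select_control_segments",
    "window_call",
    "segment_contingency",
    "patient_contingency",
    "window_positivity_rates",
    "evaluate_cohort",
    "autonomic_contrast",
]

log = logging.getLogger(__name__)

#: patients whose AF starts within this many hours of monitoring onset are
#: excluded at cohort assembly (acute arrhythmia, not a prediction target)
ACUTE_AF_EXCLUSION_HOURS = 6.0


class ProtocolError(ValueError):
    """Violation of the study protocol's preconditions."""


@dataclass
class PatientRecord:
    patient_id: str
    group: str  # "I" or "II"
    series: BeatSeries
    af_onset_abs_hours: float | None = None  # hours since day-1 00:00
    segments: list = field(default_factory=list, repr=False)
    risk_results: dict = field(default_factory=dict, repr=False)
    unanalyzable: list = field(default_factory=list)

    def __post_init__(self):
        if self.group not in ("I", "II"):
            raise ProtocolError("group must be 'I' or 'II'")
        if (self.group == "I") != (self.af_onset_abs_hours is not None):
            raise ProtocolError("group I iff af_onset present")
        if self.group == "I":
            day = int(self.af_onset_abs_hours // 24) + 1
            if not 1 <= day <= 5:
                raise ProtocolError("onset day must be in [1, 5]")

    @property
    def onset_rec_seconds(self) -> float | None:
        """AF onset in seconds since recording start."""
        if self.af_onset_abs_hours is None:
            return None
        return (self.af_onset_abs_hours - self.series.start_abs_hours) * 3600.0


@dataclass(frozen=True)
class WindowCall:
    patient_id: str
    window: str  # "FIRST3" or "LAST3"
    n_positive: int | None
    call: bool | None  # None: undefined (fewer than 3 analyzable hours)

    @property
    def defined(self) -> bool:
        return self.call is not None


@dataclass(frozen=True)
class ContingencyTable:
    tp: int
    fp: int
    fn: int
    tn: int
    level: str = "segment"

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def swapped(self) -> "ContingencyTable":
        """Swap rows and columns (cases<->controls, positive<->negative)."""
        return ContingencyTable(self.tn, self.fn, self.fp, self.tp, self.level)


# ---------------------------------------------------------------------------
# per-record analysis
# ---------------------------------------------------------------------------

def analyze_record(
    record: PatientRecord,
    config: ClassifierConfig = ClassifierConfig(),
    use_truth_labels: bool = False,
) -> PatientRecord:
    """Run the hourly classification pipeline and attach results in place.

    By default the pipeline re-detects ectopy from the raw intervals
    (ground-truth labels, when present, are stripped) — the honest end-to-end
    path for synthetic data.
    """
    from .classifier import preprocess_series

    series = record.series if use_truth_labels else record.series.strip_labels()
    series = preprocess_series(series, config)
    results, unanalyzable = classify_series(series, config, clean=False)
    record.risk_results = {r.segment_index: r for r in results}
    record.unanalyzable = unanalyzable
    record.segments = segment_hours(series, config.min_beats_hour)
    return record


def _analyzable(record: PatientRecord) -> list[HourSegment]:
    return [
        s
        for s in record.segments
        if s.analyzable and s.segment_index in record.risk_results
    ]


def select_case_segments(record: PatientRecord) -> list[HourSegment]:
    """Analyzable hourly segments in the 24 h window ending at AF onset.

    Only whole segments that end at or before onset qualify (the partial hour
    containing onset is truncated away so no AF contaminates the selection);
    fewer than 24 are returned when the recording is shorter.
    """
    if record.group != "I":
        raise ProtocolError(f"{record.patient_id}: case selection needs a group-I record")
    onset_s = record.onset_rec_seconds
    if onset_s is None or onset_s <= 0:
        raise ProtocolError(f"{record.patient_id}: AF onset precedes recording start")
    lo = onset_s - 24.0 * SECONDS_PER_HOUR
    return [
        s
        for s in _analyzable(record)
        if s.start_t >= lo and s.end_t <= onset_s
    ]


def select_control_segments(record: PatientRecord) -> list[HourSegment]:
    """Analyzable hourly segments of postoperative day 2 for a group-II record.

    A record with no day-2 coverage yields an empty list (the caller excludes
    the patient, with a log entry).
    """
    if record.group != "II":
        raise ProtocolError(f"{record.patient_id}: control selection needs a group-II record")
    segs = [s for s in _analyzable(record) if s.day == 2]
    if not segs:
        log.warning("%s: no analyzable day-2 coverage; patient excluded", record.patient_id)
    return segs


def window_call(
    results: list[RiskResult], min_positives: int = 2, window: str = ""
) -> WindowCall:
    """Patient-level call from exactly three hourly results.

    call = (number of positive results >= min_positives). Fewer than three
    results gives an undefined call; such patients are excluded from the
    corresponding patient-level analysis.
    """
    pid = results[0].patient_id if results else ""
    if len(results) != 3:
        return WindowCall(pid, window, None, None)
    n_pos = sum(r.positive for r in results)
    return WindowCall(pid, window, n_pos, n_pos >= min_positives)


def segment_contingency(
    case_results: list[RiskResult], control_results: list[RiskResult]
) -> ContingencyTable:
    """Segment-level 2x2 table: positive case segments are TP, positive
    control segments FP."""
    case_ids = {r.patient_id for r in case_results}
    control_ids = {r.patient_id for r in control_results}
    if case_ids & control_ids:
        raise ProtocolError(f"patients in both arms: {sorted(case_ids & control_ids)}")
    tp = sum(r.positive for r in case_results)
    fp = sum(r.positive for r in control_results)
    return ContingencyTable(
        tp=tp,
        fp=fp,
        fn=len(case_results) - tp,
        tn=len(control_results) - fp,
        level="segment",
    )


def patient_contingency(
    calls_i: list[WindowCall], calls_ii: list[WindowCall]
) -> ContingencyTable:
    """Patient-level 2x2 table from one window's calls across both groups."""
    ids = [c.patient_id for c in calls_i] + [c.patient_id for c in calls_ii]
    if len(ids) != len(set(ids)):
        raise ProtocolError("duplicate patient in contingency input")
    if any(not c.defined for c in calls_i + calls_ii):
        raise ProtocolError("undefined window calls must be excluded upstream")
    tp = sum(c.call for c in calls_i)
    fp = sum(c.call for c in calls_ii)
    return ContingencyTable(
        tp=tp,
        fp=fp,
        fn=len(calls_i) - tp,
        tn=len(calls_ii) - fp,
        level="patient",
    )


@dataclass
class WindowRates:
    """Pooled positive-segment rates per group per window (plus per-patient means)."""

    pooled: dict
    per_patient_mean: dict
    difference: dict  # group -> (LAST3 - FIRST3) pooled difference


def window_positivity_rates(
    windows: dict,
) -> WindowRates:
    """Positivity rates from per-patient window results.

    ``windows`` maps group -> window -> list of per-patient [RiskResult]*3.
    Rates pool segments over patients; per-patient mean proportions are also
    reported for transparency.
    """
    pooled: dict = {}
    per_patient: dict = {}
    for group, by_window in windows.items():
        pooled[group] = {}
        per_patient[group] = {}
        for window, patients in by_window.items():
            flat = [r.positive for results in patients for r in results]
            pooled[group][window] = float(np.mean(flat)) if flat else math.nan
            props = [
                float(np.mean([r.positive for r in results]))
                for results in patients
                if results
            ]
            per_patient[group][window] = float(np.mean(props)) if props else math.nan
    diff = {
        g: pooled[g].get("LAST3", math.nan) - pooled[g].get("FIRST3", math.nan)
        for g in pooled
    }
    return WindowRates(pooled, per_patient, diff)


# ---------------------------------------------------------------------------
# cohort evaluation
# ---------------------------------------------------------------------------

@dataclass
class CohortEvaluation:
    segment_table: ContingencyTable
    patient_table_first3: ContingencyTable
    patient_table_last3: ContingencyTable
    rates: WindowRates
    n_case_segments: int
    n_control_segments: int
    excluded: list  # (patient_id, reason)
    included_i: list
    included_ii: list


def _first_n(segs: list[HourSegment], n: int = 3) -> list[HourSegment]:
    return segs[:n]


def _last_n(segs: list[HourSegment], n: int = 3) -> list[HourSegment]:
    return segs[-n:] if len(segs) >= n else []


def evaluate_cohort(
    records: list[PatientRecord],
    config: ClassifierConfig = ClassifierConfig(),
    min_positives: int = 2,
    analyzed: bool = False,
) -> CohortEvaluation:
    """Apply the full case/control protocol to an analyzed cohort.

    Exclusions (each enumerated with a reason): AF onset within the first
    6 h of monitoring; group-II patients without day-2 coverage; patients
    with fewer than three analyzable hours in a window are excluded from
    that window's patient-level table only.
    """
    excluded: list = []
    case_results: list[RiskResult] = []
    control_results: list[RiskResult] = []
    calls: dict = {"FIRST3": {"I": [], "II": []}, "LAST3": {"I": [], "II": []}}
    windows = {"I": {"FIRST3": [], "LAST3": []}, "II": {"FIRST3": [], "LAST3": []}}
    included = {"I": [], "II": []}

    for record in records:
        if not analyzed:
            analyze_record(record, config)
        if record.group == "I":
            onset_s = record.onset_rec_seconds
            if onset_s is not None and onset_s < ACUTE_AF_EXCLUSION_HOURS * 3600.0:
                excluded.append((record.patient_id, "acute AF in first 6 h of monitoring"))
                continue
            selected = select_case_segments(record)
            sel_results = [record.risk_results[s.segment_index] for s in selected]
            case_results.extend(sel_results)
            first3 = [
                record.risk_results[s.segment_index]
                for s in _first_n(_analyzable(record))
            ]
            last3 = [record.risk_results[s.segment_index] for s in _last_n(selected)]
        else:
            selected = select_control_segments(record)
            if not selected:
                excluded.append((record.patient_id, "no analyzable day-2 coverage"))
                continue
            sel_results = [record.risk_results[s.segment_index] for s in selected]
            control_results.extend(sel_results)
            first3 = [record.risk_results[s.segment_index] for s in _first_n(selected)]
            last3 = [record.risk_results[s.segment_index] for s in _last_n(selected)]
        included[record.group].append(record.patient_id)
        for window, results in (("FIRST3", first3), ("LAST3", last3)):
            call = window_call(results, min_positives, window)
            if call.defined:
                calls[window][record.group].append(call)
                windows[record.group][window].append(results)
            else:
                excluded.append(
                    (record.patient_id, f"fewer than 3 analyzable hours in {window}")
                )

    return CohortEvaluation(
        segment_table=segment_contingency(case_results, control_results),
        patient_table_first3=patient_contingency(
            calls["FIRST3"]["I"], calls["FIRST3"]["II"]
        ),
        patient_table_last3=patient_contingency(
            calls["LAST3"]["I"], calls["LAST3"]["II"]
        ),
        rates=window_positivity_rates(windows),
        n_case_segments=len(case_results),
        n_control_segments=len(control_results),
        excluded=excluded,
        included_i=included["I"],
        included_ii=included["II"],
    )


# ---------------------------------------------------------------------------
# autonomic sub-analysis
# ---------------------------------------------------------------------------

@dataclass
class AutonomicContrast:
    """First-recorded-hour vs last-pre-onset-hour spectral contrast, group I."""

    hf_first: list
    hf_last: list
    lfhf_first: list
    lfhf_last: list
    n_patients: int
    hf_increase_p: float
    lfhf_decrease_p: float


def autonomic_contrast(records: list[PatientRecord]) -> AutonomicContrast:
    """Per-patient HF-power and LF/HF contrast for group-I records.

    Compares the first analyzable recorded hour against the last analyzable
    hour before AF onset; sign-test p-values (exact binomial) for HF rising
    and LF/HF falling.
    """
    from scipy.stats import binomtest

    hf_first, hf_last, lfhf_first, lfhf_last = [], [], [], []
    for record in records:
        if record.group != "I":
            continue
        analyzable = _analyzable(record)
        selected = select_case_segments(record)
        if not analyzable or not selected:
            continue
        first = analyzable[0]
        last = selected[-1]
        sp_f = features.spectral_power(first)
        sp_l = features.spectral_power(last)
        if not (sp_f.defined and sp_l.defined):
            continue
        hf_first.append(sp_f.hf_power)
        hf_last.append(sp_l.hf_power)
        lfhf_first.append(sp_f.lf_hf)
        lfhf_last.append(sp_l.lf_hf)

    n = len(hf_first)
    if n == 0:
        return AutonomicContrast([], [], [], [], 0, math.nan, math.nan)
    hf_up = int(np.sum(np.array(hf_last) > np.array(hf_first)))
    lfhf_down = int(np.sum(np.array(lfhf_last) < np.array(lfhf_first)))
    p_hf = binomtest(hf_up, n, 0.5, alternative="greater").pvalue
    p_lfhf = binomtest(lfhf_down, n, 0.5, alternative="greater").pvalue
    return AutonomicContrast(
        hf_first, hf_last, lfhf_first, lfhf_last, n, float(p_hf), float(p_lfhf)
    )
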