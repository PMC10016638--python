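"""Three-class AF-risk classification of hourly RR segments.

Risk 0: sinus rhythm. Risk 1: increased paroxysmal-AF risk. Risk 2: AF
present. A segment is positive when risk >= 1. Risk 2 is driven by an
explicit >= 30 s AF-stretch detector and dominates every other rule.

Every numeric threshold lives in :class:`ClassifierConfig`; the defaults are
documented stand-ins for an undisclosed commercial decision matrix, tuned
once against the default synthetic cohort and then frozen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import yaml

from .ingest import (
    BeatSeries,
    HourSegment,
    SECONDS_PER_HOUR,
    clean_artifacts,
    label_premature_beats,
    segment_hours,
)
from . import features
from .features import (
    EctopyMetrics,
    Pattern,
    PoincareDescriptors,
    TimeDomainHRV,
    isdefined,
)

__all__ = [
    "ClassifierConfig",
    "AFStretch",
    "RiskResult",
    "detect_af_stretches",
    "classify_segment",
    "classify_series",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """All decision-matrix thresholds, named and unit-annotated."""

    # --- risk-1 rules -------------------------------------------------
    pac_density_risk1: float = 30.0   # PACs per hour
    dispersion_risk1: float = 0.042   # normalized-dRR dispersion (unitless)
    # --- AF-stretch detector (risk 2) --------------------------------
    cv_af: float = 0.10               # windowed RR coefficient of variation
    autocorr_af: float = 0.2          # windowed lag-1 autocorrelation (below)
    dispersion_af: float = 0.10       # windowed normalized-dRR dispersion
    af_irregular_delta: float = 0.05  # |normalized dRR| above this is "irregular"
    af_irregular_fraction: float = 0.45  # fraction of irregular pairs required
    af_min_duration: float = 30.0     # s, minimum reportable AF stretch
    af_window: float = 60.0           # s, sliding-window length
    af_step: float = 10.0             # s, sliding-window step
    af_min_window_beats: int = 20     # beats required to evaluate a window
    # --- Poincaré pattern rules (shared with hrv_features) -----------
    pattern_d1: float = 0.035         # COMET dispersion ceiling
    pattern_d2: float = 0.08          # DISPERSED dispersion floor
    pattern_rho0: float = 0.2         # lag-1 autocorrelation split
    k_outlier: float = 3.0            # outlier gate, multiples of dispersion
    cluster_eps: float = 0.02         # 1-D density-grouping gap
    cluster_min: int = 25             # minimum cluster population
    # --- segmentation / cleaning ------------------------------------
    min_beats_hour: int = 1800        # analyzable-hour floor
    min_rr: float = 300.0             # ms, artifact range
    max_rr: float = 2200.0            # ms
    jump_fraction: float = 0.5        # artifact jump rule
    prematurity: float = 0.80         # PAC labeling: short-interval gate
    pause: float = 1.15               # PAC labeling: compensatory-pause gate

    def __post_init__(self):
        if self.af_min_duration <= 0:
            raise ValueError("af_min_duration must be positive")
        if self.dispersion_risk1 > self.dispersion_af:
            raise ValueError("risk-1 dispersion threshold must be <= AF threshold")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ClassifierConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass(frozen=True)
class AFStretch:
    """A contiguous AF-like stretch inside one hour segment."""

    start_t: float
    end_t: float
    n_beats: int

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t


@dataclass(frozen=True)
class RiskResult:
    patient_id: str
    segment_index: int
    risk: int
    evidence: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.risk not in (0, 1, 2):
            raise ValueError("risk must be 0, 1 or 2")

    @property
    def positive(self) -> bool:
        return self.risk >= 1


# ---------------------------------------------------------------------------
# AF-stretch detection
# ---------------------------------------------------------------------------

def detect_af_stretches(
    segment: HourSegment, config: ClassifierConfig = ClassifierConfig()
) -> list[AFStretch]:
    """Detect AF-like stretches of at least ``af_min_duration`` seconds.

    Sliding windows (``af_window`` s long, every ``af_step`` s) are flagged
    when cv > cv_af AND lag-1 autocorrelation < autocorr_af AND local
    normalized-dRR dispersion > dispersion_af AND the fraction of irregular
    successive pairs (|normalized dRR| > af_irregular_delta) exceeds
    af_irregular_fraction — the last criterion separates genuine AF (nearly
    every pair irregular) from clustered ectopy (isolated large pairs).
    Overlapping flagged windows are merged and merged runs shorter than the
    minimum duration discarded.
    """
    n = segment.n_beats
    if n < config.af_min_window_beats:
        return []
    t, rr = segment.t, segment.rr

    # prefix sums for O(1) window statistics
    c1 = np.concatenate(([0.0], np.cumsum(rr)))
    c2 = np.concatenate(([0.0], np.cumsum(rr * rr)))
    contig = segment.contiguous_pairs()  # len n-1, interval i
    prod = np.where(contig, rr[:-1] * rr[1:], 0.0)
    a = segment.rr[:-1]
    b = segment.rr[1:]
    nd = np.where(contig, (a - b) / (a + b), 0.0)
    p1 = np.concatenate(([0.0], np.cumsum(prod)))
    d1 = np.concatenate(([0.0], np.cumsum(nd)))
    d2 = np.concatenate(([0.0], np.cumsum(nd * nd)))
    irr = contig & (np.abs(nd) > config.af_irregular_delta)
    ir1 = np.concatenate(([0], np.cumsum(irr.astype(np.int64))))
    cn = np.concatenate(([0], np.cumsum(contig.astype(np.int64))))

    seg_start, seg_end = segment.start_t, segment.end_t
    last_start = max(seg_start, min(seg_end, t[-1]) - config.af_window)
    starts = np.arange(seg_start, last_start + 1e-9, config.af_step)
    if starts.size == 0:
        starts = np.array([seg_start])
    ends = starts + config.af_window

    lo = np.searchsorted(t, starts, side="left")
    hi = np.searchsorted(t, ends, side="left")
    m = hi - lo
    flagged = []
    for s, e, i0, i1, cnt in zip(starts, ends, lo, hi, m):
        if cnt < config.af_min_window_beats:
            continue
        mean = (c1[i1] - c1[i0]) / cnt
        var = (c2[i1] - c2[i0]) / cnt - mean * mean
        if var <= 0:
            continue
        cv = math.sqrt(var) / mean
        if cv <= config.cv_af:
            continue
        # pair stats over intervals i0..i1-2 (pairs fully inside the window)
        j0, j1 = i0, max(i0, i1 - 1)
        npair = int(cn[j1] - cn[j0])
        if npair < config.af_min_window_beats - 2:
            continue
        if (ir1[j1] - ir1[j0]) / npair <= config.af_irregular_fraction:
            continue
        disp_var = (d2[j1] - d2[j0]) / npair - ((d1[j1] - d1[j0]) / npair) ** 2
        disp = math.sqrt(max(disp_var, 0.0))
        if disp <= config.dispersion_af:
            continue
        acf = ((p1[j1] - p1[j0]) / npair - mean * mean) / var
        if acf >= config.autocorr_af:
            continue
        flagged.append((s, e))

    if not flagged:
        return []
    merged = []
    cur_s, cur_e = flagged[0]
    for s, e in flagged[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            merged.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    merged.append((cur_s, cur_e))
    out = []
    for s, e in merged:
        if e - s >= config.af_min_duration:
            i0, i1 = np.searchsorted(t, (s, e), side="left")
            out.append(AFStretch(float(s), float(min(e, seg_end)), int(i1 - i0)))
    return out


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_segment(
    td: TimeDomainHRV,
    pc: PoincareDescriptors,
    em: EctopyMetrics,
    af: list[AFStretch],
    config: ClassifierConfig = ClassifierConfig(),
    patient_id: str = "",
    segment_index: int = 0,
) -> RiskResult | None:
    """Map one segment's features to a risk class.

    Precedence: any reportable AF stretch -> risk 2 (even when the NN-based
    features are undefined, as in an hour of uninterrupted AF); else any
    risk-1 rule (SCATTERED/DISPERSED pattern, PAC density, dispersion) ->
    risk 1; else risk 0. Without AF evidence, undefined-flagged features make
    the segment unanalyzable (returns None; callers must exclude it from
    contingency counts).
    """
    if not af and not (td.defined and pc.defined):
        return None
    pac_density = em.pac_per_hour if isdefined(em.pac_per_hour) else 0.0
    defined = td.defined and pc.defined
    evidence = {
        "af_stretches": len(af),
        "af_seconds": round(sum(s.duration for s in af), 1),
        "pattern": pc.pattern.value if pc.pattern else None,
        "pac_per_hour": round(pac_density, 2),
        "dispersion": round(pc.dispersion, 5) if defined else None,
        "cv": round(td.cv, 5) if defined else None,
        "rule_af": bool(af),
        "rule_pattern": pc.pattern is Pattern.SCATTERED
        or pc.pattern is Pattern.DISPERSED,
        "rule_pac": pac_density >= config.pac_density_risk1,
        "rule_dispersion": defined and pc.dispersion >= config.dispersion_risk1,
    }
    if af:
        risk = 2
    elif evidence["rule_pattern"] or evidence["rule_pac"] or evidence["rule_dispersion"]:
        risk = 1
    else:
        risk = 0
    return RiskResult(patient_id, segment_index, risk, evidence)


def analyze_segment(
    segment: HourSegment, config: ClassifierConfig = ClassifierConfig()
) -> RiskResult | None:
    """Compute features for one segment and classify it."""
    td = features.time_domain(segment)
    pc = features.poincare_descriptors(
        segment,
        k_outlier=config.k_outlier,
        cluster_eps=config.cluster_eps,
        cluster_min=config.cluster_min,
        d1=config.pattern_d1,
        d2=config.pattern_d2,
        rho0=config.pattern_rho0,
    )
    em = features.ectopy_metrics(segment)
    af = detect_af_stretches(segment, config)
    return classify_segment(
        td, pc, em, af, config, segment.patient_id, segment.segment_index
    )


def preprocess_series(
    series: BeatSeries,
    config: ClassifierConfig = ClassifierConfig(),
    clean: bool = True,
) -> BeatSeries:
    """Clean artifacts and ensure beats carry rhythm labels.

    When the series has no ectopy annotations, premature beats are detected
    and labeled A; remaining unlabeled beats are treated as sinus (N).
    """
    if clean:
        series, _ = clean_artifacts(
            series, config.min_rr, config.max_rr, config.jump_fraction
        )
    if not np.any(series.labels == "A"):
        series = label_premature_beats(series, config.prematurity, config.pause)
        if np.any(series.labels == "U"):
            series = series.copy()
            series.labels[series.labels == "U"] = "N"
    return series


def classify_series(
    series: BeatSeries,
    config: ClassifierConfig = ClassifierConfig(),
    clean: bool = True,
) -> tuple[list[RiskResult], list[int]]:
    """Run the full per-hour pipeline on one recording.

    Cleans artifacts, labels premature beats when the series carries no
    ectopy annotations, segments into hours, and classifies every analyzable
    segment. Returns (results in segment order, unanalyzable segment
    indices). Classification is a pure function of (series, config).
    """
    series = preprocess_series(series, config, clean)
    segments = segment_hours(series, config.min_beats_hour)
    results: list[RiskResult] = []
    unanalyzable: list[int] = []
    for seg in segments:
        res = analyze_segment(seg, config) if seg.analyzable else None
        if res is None:
            unanalyzable.append(seg.segment_index)
        else:
            results.append(res)
    return results, unanalyzable
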