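"""Reading, validation, cleaning and hourly segmentation of RR-interval series.

The pipeline's raw material is a beat-to-beat series: for every beat, the
elapsed time since recording start (seconds), the preceding inter-beat
interval (milliseconds) and a single-character label::

    N  normal sinus beat
    A  atrial premature beat
    V  ventricular premature beat
    X  artifact
    U  unlabeled

Series are stored column-wise as numpy arrays for speed; the ``Beat``
dataclass is a convenience view for row-wise access.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Beat",
    "BeatSeries",
    "HourSegment",
    "CleanReport",
    "Dialect",
    "CorruptSeriesError",
    "read_rr_table",
    "write_rr_table",
    "clean_artifacts",
    "segment_hours",
    "label_premature_beats",
]

log = logging.getLogger(__name__)

VALID_LABELS = frozenset("NAVXU")

#: tolerance (ms) for "t difference equals rr" consistency between columns
T_RR_TOL_MS = 1.0

#: tolerance (ms) used to decide whether two recorded beats are contiguous
#: (no beat was removed between them), e.g. after artifact cleaning
PAIR_GAP_TOL_MS = 5.0

SECONDS_PER_HOUR = 3600.0


class CorruptSeriesError(ValueError):
    """Raised when more than 5% of the rows of an input file are unusable."""


@dataclass(frozen=True)
class Beat:
    """A single beat: time since recording start (s), preceding RR (ms), label."""

    t: float
    rr: float
    label: str = "U"


@dataclass
class BeatSeries:
    """An ordered beat-to-beat RR series for one patient.

    ``t`` is seconds since recording start, strictly increasing; ``rr`` is
    milliseconds, strictly positive. ``start_day`` is the postoperative day
    index (1-5) on which the recording begins and ``start_hour`` the
    time-of-day (hours) of the first beat.
    """

    patient_id: str
    t: np.ndarray
    rr: np.ndarray
    labels: np.ndarray
    start_day: int = 1
    start_hour: float = 0.0
    #: hour indices flagged unanalyzable by QC (propagated to segments)
    flagged_hours: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.rr = np.asarray(self.rr, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype="<U1")
        self.validate()

    def validate(self) -> None:
        if self.t.shape != self.rr.shape or self.t.shape != self.labels.shape:
            raise ValueError("t, rr and labels must have equal length")
        if self.n_beats == 0:
            raise ValueError("empty BeatSeries")
        if np.any(self.rr <= 0):
            raise ValueError("rr must be strictly positive")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        bad = set(np.unique(self.labels)) - VALID_LABELS
        if bad:
            raise ValueError(f"invalid beat labels: {sorted(bad)}")
        if not 1 <= self.start_day <= 5:
            raise ValueError("start_day must be in [1, 5]")

    @property
    def n_beats(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        """Covered duration in seconds (time of last beat)."""
        return float(self.t[-1] - self.t[0])

    @property
    def start_abs_hours(self) -> float:
        """Recording start on the absolute postoperative axis (hours since day-1 00:00)."""
        return (self.start_day - 1) * 24.0 + self.start_hour

    def beats(self) -> Iterator[Beat]:
        for t, rr, lab in zip(self.t, self.rr, self.labels):
            yield Beat(float(t), float(rr), str(lab))

    def copy(self) -> "BeatSeries":
        return replace(
            self, t=self.t.copy(), rr=self.rr.copy(), labels=self.labels.copy()
        )

    def strip_labels(self) -> "BeatSeries":
        """Return a copy with every beat unlabeled (label U)."""
        out = self.copy()
        out.labels = np.full(self.n_beats, "U", dtype="<U1")
        return out

    def equals(self, other: "BeatSeries", atol_t: float = 0.0) -> bool:
        return (
            self.patient_id == other.patient_id
            and self.n_beats == other.n_beats
            and np.allclose(self.t, other.t, atol=atol_t, rtol=0)
            and np.array_equal(self.rr, other.rr)
            and np.array_equal(self.labels, other.labels)
        )


@dataclass
class HourSegment:
    """One hourly analysis window: beats with t in [3600*k, 3600*(k+1))."""

    patient_id: str
    segment_index: int
    t: np.ndarray
    rr: np.ndarray
    labels: np.ndarray
    day: int
    analyzable: bool = True

    @property
    def n_beats(self) -> int:
        return int(self.t.size)

    @property
    def start_t(self) -> float:
        return self.segment_index * SECONDS_PER_HOUR

    @property
    def end_t(self) -> float:
        return (self.segment_index + 1) * SECONDS_PER_HOUR

    @property
    def covered_duration(self) -> float:
        """Span of time actually covered by beats, in seconds."""
        if self.n_beats < 2:
            return 0.0
        return float(self.t[-1] - self.t[0])

    def contiguous_pairs(self) -> np.ndarray:
        """Boolean mask over intervals 1..n-1: True where beat i-1 -> i is gap-free.

        An interval is contiguous when the recorded time step matches its RR
        within ``PAIR_GAP_TOL_MS`` — i.e. no beat was removed in between.
        """
        if self.n_beats < 2:
            return np.zeros(0, dtype=bool)
        dt_ms = np.diff(self.t) * 1000.0
        return np.abs(dt_ms - self.rr[1:]) <= PAIR_GAP_TOL_MS


@dataclass(frozen=True)
class Dialect:
    """Column/units mapping for delimited RR tables.

    The default dialect is comma-separated with header ``t_s,rr_ms,label``;
    times in seconds, RR in milliseconds. Set ``t_col=None`` for files
    without a time column (cumulative time is reconstructed from RR), and
    ``label_col=None`` for two-column or RR-only files.
    """

    sep: str = ","
    t_col: str | None = "t_s"
    rr_col: str = "rr_ms"
    label_col: str | None = "label"
    rr_units: str = "ms"  # "ms" or "s"
    t_units: str = "s"


DEFAULT_DIALECT = Dialect()


@dataclass
class CleanReport:
    """Outcome of :func:`clean_artifacts`."""

    n_removed: int
    n_input: int
    removed_by_rule: dict
    flagged_hours: frozenset

    @property
    def fraction_removed(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def read_rr_table(
    path,
    dialect: Dialect = DEFAULT_DIALECT,
    patient_id: str | None = None,
) -> BeatSeries:
    """Read a delimited RR table into a validated :class:`BeatSeries`.

    Rows with non-positive or unparsable RR are rejected with a warning; if
    more than 5% of rows are rejected the series is considered corrupt.
    Seconds are converted to ms; when the time column is absent, cumulative
    time is reconstructed from RR (first beat at t = 0). Missing labels
    default to ``U``. A JSON sidecar (``<file>.meta.json``), when present,
    supplies ``patient_id``, ``start_day`` and ``start_hour``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"rr_ingest: input file not found: {path}")
    df = pd.read_csv(path, sep=dialect.sep, float_precision="round_trip")
    if dialect.rr_col not in df.columns:
        raise CorruptSeriesError(
            f"rr_ingest: column {dialect.rr_col!r} missing in {path}"
        )
    n_rows = len(df)
    rr = pd.to_numeric(df[dialect.rr_col], errors="coerce").to_numpy(dtype=np.float64)
    if dialect.rr_units == "s":
        rr = rr * 1000.0
    elif dialect.rr_units != "ms":
        raise ValueError(f"unknown rr units {dialect.rr_units!r}")
    good = np.isfinite(rr) & (rr > 0)
    n_rejected = int(n_rows - good.sum())
    if n_rejected:
        log.warning("%s: rejected %d of %d rows (bad RR)", path, n_rejected, n_rows)
    if n_rows == 0 or n_rejected > 0.05 * n_rows:
        raise CorruptSeriesError(
            f"corrupt series: {n_rejected}/{n_rows} unusable rows in {path}"
        )

    if dialect.t_col is not None and dialect.t_col in df.columns:
        t = pd.to_numeric(df[dialect.t_col], errors="coerce").to_numpy(np.float64)
        if dialect.t_units == "ms":
            t = t / 1000.0
        t = t[good]
        rr = rr[good]
        # consistency: dt vs rr, warn only (cleaned series legitimately has gaps)
        dt_ms = np.diff(t) * 1000.0
        n_off = int(np.sum(np.abs(dt_ms - rr[1:]) > T_RR_TOL_MS))
        if n_off:
            log.debug("%s: %d intervals where dt != rr (gaps?)", path, n_off)
    else:
        rr = rr[good]
        t = np.concatenate(([0.0], np.cumsum(rr[1:]) / 1000.0))

    if dialect.label_col is not None and dialect.label_col in df.columns:
        labels = (
            df[dialect.label_col][good]
            .fillna("U")
            .astype(str)
            .str.strip()
            .str.upper()
            .to_numpy(dtype="<U1")
        )
        labels[~np.isin(labels, list(VALID_LABELS))] = "U"
    else:
        labels = np.full(rr.size, "U", dtype="<U1")

    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return BeatSeries(
        patient_id=patient_id or meta.get("patient_id", path.stem),
        t=t,
        rr=rr,
        labels=labels,
        start_day=int(meta.get("start_day", 1)),
        start_hour=float(meta.get("start_hour", 0.0)),
    )


def write_rr_table(series: BeatSeries, path, write_sidecar: bool = True) -> None:
    """Write one beat per row (``t_s,rr_ms,label``) with a header.

    Floats are written with shortest round-trip repr so that
    write -> read -> write is byte-identical.
    """
    path = Path(path)
    lines = ["t_s,rr_ms,label"]
    lines.extend(
        f"{float(t)!r},{float(rr)!r},{lab}"
        for t, rr, lab in zip(series.t, series.rr, series.labels)
    )
    path.write_text("\n".join(lines) + "\n")
    if write_sidecar:
        _sidecar_path(path).write_text(
            json.dumps(
                {
                    "patient_id": series.patient_id,
                    "start_day": series.start_day,
                    "start_hour": series.start_hour,
                },
                indent=0,
                sort_keys=True,
            )
            + "\n"
        )


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------

def _local_median_excl_self(values: np.ndarray, half: int = 5) -> np.ndarray:
    """Median of the (up to) 2*half surrounding values, excluding the value itself."""
    n = values.size
    if n == 1:
        return values.copy()
    width = 2 * half + 1
    padded = np.pad(values, half, mode="edge")
    win = np.lib.stride_tricks.sliding_window_view(padded, width)  # (n, width)
    win = np.delete(win, half, axis=1)
    return np.median(win, axis=1)


def clean_artifacts(
    series: BeatSeries,
    min_rr: float = 300.0,
    max_rr: float = 2200.0,
    jump_fraction: float = 0.5,
    max_removed_per_hour: float = 0.2,
) -> tuple[BeatSeries, CleanReport]:
    """Remove artifact beats; report the removals.

    Removes beats labeled X, beats with RR outside [min_rr, max_rr], and
    N/U-labeled beats whose RR deviates from the running median of the 10
    surrounding N/U beats by more than ``jump_fraction`` of that median. The
    jump rule is iterated to a fixed point, so the operation is idempotent.
    Hours in which more than ``max_removed_per_hour`` of beats were removed
    are flagged unanalyzable (never silently passed).
    """
    if not min_rr < max_rr:
        raise ValueError("min_rr must be < max_rr")
    t, rr, labels = series.t, series.rr, series.labels
    n_input = series.n_beats

    remove = (labels == "X") | (rr < min_rr) | (rr > max_rr)
    by_rule = {
        "label_X": int(np.sum(labels == "X")),
        "range": int(np.sum(((rr < min_rr) | (rr > max_rr)) & (labels != "X"))),
        "jump": 0,
    }
    keep = ~remove
    # iterate the jump rule to a fixed point on the surviving beats
    while True:
        idx = np.flatnonzero(keep)
        ref_mask = np.isin(labels[idx], ("N", "U"))
        ref_idx = idx[ref_mask]
        if ref_idx.size < 3:
            break
        med = _local_median_excl_self(rr[ref_idx])
        dev = np.abs(rr[ref_idx] - med) > jump_fraction * med
        if not dev.any():
            break
        keep[ref_idx[dev]] = False
        by_rule["jump"] += int(dev.sum())

    removed = ~keep
    n_removed = int(removed.sum())
    if n_removed == n_input:
        raise CorruptSeriesError("clean_artifacts removed every beat")

    hours = np.floor(t / SECONDS_PER_HOUR).astype(int)
    flagged = set(series.flagged_hours)
    for h in np.unique(hours):
        in_h = hours == h
        frac = removed[in_h].mean()
        if frac > max_removed_per_hour:
            flagged.add(int(h))
            log.warning(
                "%s hour %d: %.0f%% of beats removed -> flagged unanalyzable",
                series.patient_id,
                h,
                100 * frac,
            )

    cleaned = BeatSeries(
        patient_id=series.patient_id,
        t=t[keep],
        rr=rr[keep],
        labels=labels[keep],
        start_day=series.start_day,
        start_hour=series.start_hour,
        flagged_hours=frozenset(flagged),
    )
    return cleaned, CleanReport(n_removed, n_input, by_rule, frozenset(flagged))


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_hours(series: BeatSeries, min_beats: int = 1800) -> list[HourSegment]:
    """Partition beats into half-open hourly bins [3600k, 3600(k+1)).

    Every beat appears in exactly one segment. Segments with fewer than
    ``min_beats`` beats, or flagged by QC, are marked unanalyzable.
    """
    if series.n_beats == 0:
        return []
    hours = np.floor(series.t / SECONDS_PER_HOUR).astype(int)
    n_segments = int(hours[-1]) + 1
    bounds = np.searchsorted(hours, np.arange(n_segments + 1))
    segments = []
    for k in range(n_segments):
        lo, hi = bounds[k], bounds[k + 1]
        day = series.start_day + int((series.start_hour + k) // 24)
        segments.append(
            HourSegment(
                patient_id=series.patient_id,
                segment_index=k,
                t=series.t[lo:hi],
                rr=series.rr[lo:hi],
                labels=series.labels[lo:hi],
                day=day,
                analyzable=(hi - lo) >= min_beats and k not in series.flagged_hours,
            )
        )
    return segments


# ---------------------------------------------------------------------------
# Premature-beat labeling
# ---------------------------------------------------------------------------

def label_premature_beats(
    series: BeatSeries,
    prematurity: float = 0.80,
    pause: float = 1.15,
) -> BeatSeries:
    """Label premature atrial beats in an (essentially) unlabeled series.

    A beat whose RR is shorter than ``prematurity`` x (local median of the 10
    surrounding RR) and whose successor RR exceeds ``pause`` x that median is
    relabeled ``A``. Beats already labeled A/V/X are never touched; the
    operation is a no-op on fully labeled series.
    """
    out = series.copy()
    n = out.n_beats
    if n < 3:
        return out
    med = _local_median_excl_self(out.rr)
    eligible = np.isin(out.labels, ("N", "U"))
    short = out.rr < prematurity * med
    has_pause = np.zeros(n, dtype=bool)
    has_pause[:-1] = out.rr[1:] > pause * med[:-1]
    hit = eligible & short & has_pause
    out.labels[hit] = "A"
    out.flagged_hours = series.flagged_hours
    return out
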