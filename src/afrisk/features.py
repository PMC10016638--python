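"""Linear (time-domain), Poincaré and spectral HRV descriptors per hour segment.

All statistics use *population* variance so that closed-form oracles match
bit-for-bit. Undefined quantities are NaN, never silent zeros; use
:func:`isdefined` to test.

The central nonlinear quantity is the normalized successive-difference
    n_i = (RR_i - RR_{i+1}) / (RR_i + RR_{i+1})
which is dimensionless and strictly inside (-1, 1) for positive intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.signal import lombscargle

from .ingest import HourSegment

__all__ = [
    "Pattern",
    "TimeDomainHRV",
    "PoincareDescriptors",
    "SpectralHRV",
    "EctopyMetrics",
    "isdefined",
    "time_domain",
    "normalized_delta_rr",
    "poincare_descriptors",
    "spectral_power",
    "ectopy_metrics",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

#: numerical floor below which band powers are reported as exactly 0 ms^2
POWER_FLOOR = 1e-6


def isdefined(x: float) -> bool:
    """True when a descriptor value is defined (not the NaN undefined flag)."""
    return x is not None and not math.isnan(x)


class Pattern(str, Enum):
    """Qualitative Poincaré-plot classes (quantitative surrogate rules)."""

    COMET = "COMET"          # single tight cluster: sinus rhythm
    SCATTERED = "SCATTERED"  # main cluster + arms: elevated paroxysmal-AF risk
    DISPERSED = "DISPERSED"  # no dominant cluster: AF-like irregularity


@dataclass(frozen=True)
class TimeDomainHRV:
    mean_nn: float
    sdnn: float
    rmssd: float
    pnn50: float
    cv: float
    n_nn: int

    @property
    def defined(self) -> bool:
        return isdefined(self.sdnn)


@dataclass(frozen=True)
class PoincareDescriptors:
    sd1: float
    sd2: float
    sd_ratio: float
    dispersion: float
    outlier_fraction: float
    cluster_count: int
    lag1_autocorr: float
    pattern: Pattern | None
    n_pairs: int
    norm_delta_rr: np.ndarray = field(repr=False, default=None)

    @property
    def defined(self) -> bool:
        return isdefined(self.sd1)


@dataclass(frozen=True)
class SpectralHRV:
    lf_power: float
    hf_power: float
    lf_hf: float

    @property
    def defined(self) -> bool:
        return isdefined(self.lf_power)


@dataclass(frozen=True)
class EctopyMetrics:
    pac_count: int
    pac_per_hour: float
    pac_per_1000: float
    max_pac_run: int


_UNDEFINED_TD = TimeDomainHRV(*(math.nan,) * 5, n_nn=0)
_UNDEFINED_SPECTRAL = SpectralHRV(math.nan, math.nan, math.nan)


# ---------------------------------------------------------------------------
# interval bookkeeping
# ---------------------------------------------------------------------------

def _nn_mask(segment: HourSegment) -> np.ndarray:
    """Mask over intervals 1..n-1: interval i is NN iff beats i-1 and i are
    both labeled N and the interval is contiguous (no removed beat between)."""
    lab = segment.labels
    if lab.size < 2:
        return np.zeros(0, dtype=bool)
    return (lab[:-1] == "N") & (lab[1:] == "N") & segment.contiguous_pairs()


def _usable_pair_mask(segment: HourSegment) -> np.ndarray:
    """Mask over successive interval pairs (i, i+1), i = 1..n-2: both
    intervals contiguous and no artifact-labeled beat adjacent."""
    lab = segment.labels
    if lab.size < 3:
        return np.zeros(0, dtype=bool)
    contig = segment.contiguous_pairs()
    not_x = lab != "X"
    beats_ok = not_x[:-2] & not_x[1:-1] & not_x[2:]
    return contig[:-1] & contig[1:] & beats_ok


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def time_domain(segment: HourSegment) -> TimeDomainHRV:
    """Time-domain HRV over normal-to-normal (NN) intervals only.

    sdnn is the population standard deviation; rmssd the root-mean-square of
    successive NN differences (both intervals NN); pnn50 the percentage of
    successive NN differences with |d| > 50 ms. Fewer than 2 successive NN
    pairs gives an undefined-flagged result.
    """
    nn = _nn_mask(segment)
    rr = segment.rr[1:][nn]
    # successive pairs: intervals i and i+1 both NN and adjacent in the record
    both = nn[:-1] & nn[1:]
    d = segment.rr[2:][both[:]] - segment.rr[1:-1][both]
    if d.size < 2:
        return _UNDEFINED_TD
    mean_nn = float(np.mean(rr))
    sdnn = float(np.std(rr))
    rmssd = float(np.sqrt(np.mean(d * d)))
    pnn50 = float(100.0 * np.mean(np.abs(d) > 50.0))
    return TimeDomainHRV(mean_nn, sdnn, rmssd, pnn50, sdnn / mean_nn, int(rr.size))


def normalized_delta_rr(segment: HourSegment) -> np.ndarray:
    """Normalized successive differences (RR_i - RR_{i+1}) / (RR_i + RR_{i+1}).

    One value per usable consecutive interval pair; artifact-adjacent and
    gap-spanning pairs are excluded. Every value is strictly inside (-1, 1).
    """
    if segment.n_beats < 3:
        raise ValueError("normalized_delta_rr needs at least 2 intervals")
    a = segment.rr[1:-1]
    b = segment.rr[2:]
    vals = (a - b) / (a + b)
    return vals[_usable_pair_mask(segment)]


def _gap_clusters(values: np.ndarray, eps: float, min_count: int) -> int:
    """Density grouping of 1-D values: split sorted values at gaps > eps,
    count groups with at least ``min_count`` members."""
    if values.size == 0:
        return 0
    s = np.sort(values)
    splits = np.flatnonzero(np.diff(s) > eps)
    sizes = np.diff(np.concatenate(([0], splits + 1, [s.size])))
    return int(np.sum(sizes >= min_count))


def _lag1_autocorr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation between successive intervals (x_i, x_{i+1})."""
    if x.size < 3:
        return math.nan
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return math.nan
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def classify_pattern(
    dispersion: float,
    outlier_fraction: float,
    cluster_count: int,
    lag1: float,
    d1: float = 0.035,
    d2: float = 0.08,
    rho0: float = 0.2,
    outlier_thr: float = 0.02,
) -> Pattern:
    """Quantitative surrogate for the visual Poincaré classes.

    DISPERSED: high normalized-difference dispersion with no serial
    correlation (AF signature). SCATTERED: side clusters or an outlier arm on
    a serially correlated rhythm (ectopy on sinus). COMET: one tight cluster.
    Intermediate combinations fall back to SCATTERED (conservative).
    """
    lag_low = (not isdefined(lag1)) or lag1 <= rho0
    if dispersion >= d2 and lag_low:
        return Pattern.DISPERSED
    if cluster_count <= 1 and outlier_fraction < outlier_thr and dispersion < d1:
        return Pattern.COMET
    return Pattern.SCATTERED


def poincare_descriptors(
    segment: HourSegment,
    k_outlier: float = 3.0,
    cluster_eps: float = 0.02,
    cluster_min: int = 25,
    d1: float = 0.035,
    d2: float = 0.08,
    rho0: float = 0.2,
    min_pairs: int = 100,
) -> PoincareDescriptors:
    """Poincaré-plot descriptors over all usable interval pairs.

    sd1 = sqrt(Var(dRR)/2); sd2 = sqrt(2 Var(RR) - Var(dRR)/2), floored at 0,
    with population variances over the intervals entering pairs — so that
    sd1^2 + sd2^2 = 2 sdnn^2 holds by construction. Dispersion and outliers
    are computed on the normalized successive differences; cluster_count by
    1-D density grouping; the qualitative pattern by `classify_pattern`.
    """
    if segment.n_beats < 3:
        return PoincareDescriptors(
            *(math.nan,) * 5, 0, math.nan, None, 0, np.zeros(0)
        )
    pair_ok = _usable_pair_mask(segment)
    n_pairs = int(pair_ok.sum())
    if n_pairs < min_pairs:
        return PoincareDescriptors(
            *(math.nan,) * 5, 0, math.nan, None, n_pairs, np.zeros(0)
        )
    x = segment.rr[1:-1][pair_ok]
    y = segment.rr[2:][pair_ok]
    rr_all = np.concatenate((x, y[-1:]))  # intervals participating in pairs
    var_rr = float(np.var(rr_all))
    var_drr = float(np.var(y - x))
    sd1 = math.sqrt(var_drr / 2.0)
    sd2 = math.sqrt(max(2.0 * var_rr - var_drr / 2.0, 0.0))
    sd_ratio = sd1 / sd2 if sd2 > 0 else math.nan

    ndrr = (x - y) / (x + y)
    dispersion = float(np.std(ndrr))
    if dispersion > 0:
        center = float(np.median(ndrr))
        outlier_fraction = float(
            np.mean(np.abs(ndrr - center) > k_outlier * dispersion)
        )
    else:
        outlier_fraction = 0.0
    cluster_count = _gap_clusters(ndrr, cluster_eps, cluster_min)
    lag1 = _lag1_autocorr(x, y)
    pattern = classify_pattern(
        dispersion, outlier_fraction, cluster_count, lag1, d1, d2, rho0
    )
    return PoincareDescriptors(
        sd1, sd2, sd_ratio, dispersion, outlier_fraction,
        cluster_count, lag1, pattern, n_pairs, ndrr,
    )


def spectral_power(
    segment: HourSegment,
    lf_band: tuple[float, float] = LF_BAND,
    hf_band: tuple[float, float] = HF_BAND,
    min_nn: int = 300,
    min_span: float = 300.0,
) -> SpectralHRV:
    """LF/HF band powers from a least-squares (Lomb-Scargle) periodogram.

    Computed on the NN tachogram at its irregular beat times — ectopic and
    artifact intervals are excluded without interpolation. Band power is the
    periodogram summed on a grid at the Rayleigh resolution (df = 1/T),
    normalized so a pure tone of amplitude A contributes A^2/2 ms^2.
    """
    nn = _nn_mask(segment)
    rr = segment.rr[1:][nn]
    t = segment.t[1:][nn]
    if rr.size < min_nn or (t[-1] - t[0] if rr.size else 0.0) < min_span:
        return _UNDEFINED_SPECTRAL
    x = rr - rr.mean()
    if float(np.var(x)) < POWER_FLOOR:
        return SpectralHRV(0.0, 0.0, math.nan)
    span = float(t[-1] - t[0])
    df = 1.0 / span
    freqs = np.arange(lf_band[0], hf_band[1] + df / 2, df)
    pgram = lombscargle(t, x, 2 * np.pi * freqs)
    power = 2.0 * pgram / rr.size  # tone of amplitude A -> A^2/2 at its bin
    in_lf = (freqs >= lf_band[0]) & (freqs < lf_band[1])
    in_hf = (freqs >= hf_band[0]) & (freqs < hf_band[1])
    lf = float(power[in_lf].sum())
    hf = float(power[in_hf].sum())
    lf = 0.0 if lf < POWER_FLOOR else lf
    hf = 0.0 if hf < POWER_FLOOR else hf
    return SpectralHRV(lf, hf, lf / hf if hf > 0 else math.nan)


def ectopy_metrics(segment: HourSegment) -> EctopyMetrics:
    """Atrial-ectopy counts and densities over the segment.

    Densities are scaled by the duration actually covered by beats, reported
    both per hour and per 1000 beats. ``max_pac_run`` is the longest run of
    consecutive A-labeled beats.
    """
    is_a = segment.labels == "A"
    count = int(is_a.sum())
    dur_h = segment.covered_duration / 3600.0
    per_hour = count / dur_h if dur_h > 0 else math.nan
    per_1000 = 1000.0 * count / segment.n_beats if segment.n_beats else math.nan
    max_run = 0
    if count:
        padded = np.concatenate(([False], is_a, [False])).astype(int)
        edges = np.diff(padded)
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        max_run = int((ends - starts).max())
    return EctopyMetrics(count, per_hour, per_1000, max_run)
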