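"""Synthetic RR-interval recordings and cohorts with known ground truth.

Generates multi-day postoperative-style recordings: sinus rhythm with LF/HF
autonomic modulation, premature atrial complexes (PACs), a pre-onset ramp of
ectopy density and HF modulation for affected patients, and AF episodes of
serially uncorrelated irregular intervals. Every generator is a pure
function of (parameters, seed).

Physiological realism is limited to the statistical signatures the
downstream classifier reads; there is no respiration or baroreflex model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .ingest import BeatSeries

__all__ = [
    "SinusParams",
    "AFParams",
    "PatientProfile",
    "CohortConfig",
    "GroundTruth",
    "simulate_sinus",
    "inject_pacs",
    "inject_artifacts",
    "simulate_af",
    "simulate_patient",
    "simulate_cohort",
    "patient_seed",
]

RR_FLOOR_MS = 300.0
F_LF = 0.10  # Hz, low-frequency modulation tone
F_HF = 0.25  # Hz, high-frequency modulation tone


@dataclass(frozen=True)
class SinusParams:
    """Sinus-rhythm generator parameters (ms unless noted)."""

    mean_rr: float = 800.0
    a_lf: float = 30.0       # amplitude of the 0.10 Hz tone
    a_hf: float = 30.0       # amplitude of the 0.25 Hz tone
    noise_sd: float = 20.0
    drift: float = 0.0       # ms per hour

    def __post_init__(self):
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if min(self.a_lf, self.a_hf, self.noise_sd) < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass(frozen=True)
class AFParams:
    """AF-episode generator: i.i.d. Gamma RR intervals."""

    mean_rr_af: float = 600.0
    cv_af: float = 0.20
    min_duration: float = 30.0  # s

    def __post_init__(self):
        if self.cv_af <= 0:
            raise ValueError("cv_af must be positive")


@dataclass(frozen=True)
class PatientProfile:
    patient_id: str
    group: str                       # "I" (AF develops) or "II" (stays sinus)
    sinus: SinusParams = SinusParams()
    af: AFParams = AFParams()
    pac_base_rate: float = 12.0      # PACs per hour
    onset_abs_hours: float | None = None  # hours since day-1 00:00
    episode_minutes: float = 20.0
    ramp_hours: float = 4.0
    ramp_pac_mult: float = 4.0
    ramp_hf_mult: float = 2.0
    start_day: int = 1
    start_hour: float = 10.0         # time-of-day of recording start
    recording_end_abs_hours: float = 48.0

    def __post_init__(self):
        if self.group not in ("I", "II"):
            raise ValueError("group must be 'I' or 'II'")
        if (self.group == "I") != (self.onset_abs_hours is not None):
            raise ValueError("group I iff onset is set")

    @property
    def start_abs_hours(self) -> float:
        return (self.start_day - 1) * 24.0 + self.start_hour


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 114
    prevalence: float = 0.28
    onset_day_weights: tuple = (0.15, 0.45, 0.25, 0.10, 0.05)
    recording_days: tuple = (1, 5)
    master_seed: int = 20230315
    # per-patient PAC base rates: lognormal(log median, sigma) per group
    pac_rate_median_i: float = 22.0
    pac_rate_sigma_i: float = 0.45
    pac_rate_median_ii: float = 8.5
    pac_rate_sigma_ii: float = 0.6

    def __post_init__(self):
        if not 0.0 <= self.prevalence < 1.0:
            raise ValueError("prevalence must be in [0, 1)")


@dataclass
class GroundTruth:
    """Everything the generator knows about one synthetic recording."""

    patient_id: str
    group: str
    onset_abs_hours: float | None = None
    episode_start_t: float | None = None   # seconds since recording start
    episode_end_t: float | None = None
    pac_times: np.ndarray = field(default_factory=lambda: np.zeros(0))
    artifact_times: np.ndarray = field(default_factory=lambda: np.zeros(0))
    seed: int | None = None


def patient_seed(master_seed: int, index: int) -> int:
    """Deterministic per-patient seed derived from the master seed."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0])


# ---------------------------------------------------------------------------
# sinus rhythm
# ---------------------------------------------------------------------------

def simulate_sinus(
    params: SinusParams,
    duration: float,
    seed,
    t0: float = 0.0,
    patient_id: str = "sim",
    ramp: tuple[float, float, float] | None = None,
    start_day: int = 1,
    start_hour: float = 0.0,
) -> BeatSeries:
    """Simulate sinus rhythm for ``duration`` seconds starting at t0.

    Beat times follow the recurrence
        RR_i = mean_rr + a_lf sin(2 pi f_lf t_{i-1}) + a_hf sin(2 pi f_hf
        t_{i-1}) + drift * t/3600 + eps_i,   t_i = t_{i-1} + RR_i / 1000
    with eps ~ Normal(0, noise_sd^2). ``ramp`` = (ramp_start_t, ramp_end_t,
    hf_mult) scales the HF amplitude linearly from 1x at ramp_start to
    hf_mult at ramp_end (clamped outside). Parameter combinations driving RR
    below the 300 ms floor are a hard error.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if params.mean_rr - params.a_lf - params.a_hf * (
        ramp[2] if ramp else 1.0
    ) - 5 * params.noise_sd < RR_FLOOR_MS:
        raise ValueError("sinus parameters drive RR below the 300 ms floor")
    rng = np.random.default_rng(seed)
    n_est = int(duration * 1000.0 / params.mean_rr * 1.15) + 16
    eps = rng.normal(0.0, params.noise_sd, n_est) if params.noise_sd > 0 else None

    mean = params.mean_rr
    drift = params.drift / 3600.0  # ms per second
    w_lf = 2.0 * math.pi * F_LF
    w_hf = 2.0 * math.pi * F_HF
    end = t0 + duration

    if params.a_lf == 0.0 and params.a_hf == 0.0 and drift == 0.0:
        # vectorized fast path: no time-dependent terms in the recurrence
        rr = np.full(n_est, mean) if eps is None else mean + eps
        np.maximum(rr, RR_FLOOR_MS, out=rr)
        t = t0 + np.cumsum(rr) / 1000.0
        n = int(np.searchsorted(t, end, side="right"))
        rr, t = rr[:n], t[:n]
    else:
        sin = math.sin
        rr_list: list[float] = []
        t_list: list[float] = []
        t = t0
        i = 0
        if ramp is not None:
            r0, r1, mult = ramp
            inv_span = 1.0 / (r1 - r0) if r1 > r0 else 0.0
        while t < end:
            if i >= n_est:  # top up noise if the estimate fell short
                extra = rng.normal(0.0, params.noise_sd, n_est // 4 + 16)
                eps = np.concatenate((eps, extra)) if eps is not None else extra
                n_est = eps.size
            a_hf = params.a_hf
            if ramp is not None and a_hf > 0.0:
                frac = (t - r0) * inv_span
                frac = 0.0 if frac < 0.0 else (1.0 if frac > 1.0 else frac)
                a_hf *= 1.0 + (mult - 1.0) * frac
            rr = (
                mean
                + params.a_lf * sin(w_lf * t)
                + a_hf * sin(w_hf * t)
                + drift * (t - t0)
            )
            if eps is not None:
                rr += eps[i]
            if rr < RR_FLOOR_MS:
                rr = RR_FLOOR_MS
            t += rr / 1000.0
            rr_list.append(rr)
            t_list.append(t)
            i += 1
        rr = np.asarray(rr_list)
        t = np.asarray(t_list)

    if rr.size < 2:
        raise ValueError("duration too short for the given mean RR")
    return BeatSeries(
        patient_id=patient_id,
        t=t,
        rr=rr,
        labels=np.full(rr.size, "N", dtype="<U1"),
        start_day=start_day,
        start_hour=start_hour,
    )


# ---------------------------------------------------------------------------
# ectopy and artifacts
# ---------------------------------------------------------------------------

def inject_pacs(
    series: BeatSeries,
    rate: float,
    seed,
    coupling: tuple[float, float] = (0.5, 0.7),
    pause: float = 1.2,
    rate_fn=None,
) -> tuple[BeatSeries, np.ndarray]:
    """Inject premature atrial complexes as a Poisson process.

    Candidate insertion times are drawn at ``rate`` PACs/hour (or, when
    ``rate_fn(t)->multiplier`` is given, an inhomogeneous process realized by
    thinning at rate * max multiplier). The beat nearest each insertion time
    becomes premature (RR = coupling x local RR, coupling ~ U(a, b)) and its
    successor carries a compensatory pause (pause x local RR); the premature
    beat is labeled A. Times are rebuilt from the modified RR sequence.
    Returns (new series, ground-truth times of the injected PACs).
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    out = series.copy()
    n = out.n_beats
    if rate == 0 or n < 5:
        return out, np.zeros(0)
    rng = np.random.default_rng(seed)
    span_h = (series.t[-1] - series.t[0]) / 3600.0
    max_mult = 1.0
    if rate_fn is not None:
        probe = np.linspace(series.t[0], series.t[-1], 512)
        max_mult = max(float(np.max([rate_fn(x) for x in probe])), 1e-9)
    n_cand = rng.poisson(rate * max_mult * span_h)
    times = np.sort(rng.uniform(series.t[0], series.t[-1], n_cand))
    if rate_fn is not None and times.size:
        accept = rng.uniform(0, 1, times.size) < np.array(
            [rate_fn(x) for x in times]
        ) / max_mult
        times = times[accept]

    idx = np.searchsorted(series.t, times)
    # keep indices with room for the pause beat, on sinus beats, non-adjacent
    idx = idx[(idx >= 2) & (idx <= n - 3)]
    if idx.size:
        keep = np.concatenate(([True], np.diff(idx) >= 3))
        idx = idx[keep]
        idx = idx[np.isin(out.labels[idx], ("N",)) & (out.labels[idx + 1] == "N")]
    if idx.size == 0:
        return out, np.zeros(0)
    # local reference = running median of surrounding beats, the same notion
    # of "local RR" the premature-beat detector uses
    from .ingest import _local_median_excl_self

    local = _local_median_excl_self(out.rr)[idx]
    if np.any(local * np.min(coupling) * 0.5 < 1.0):
        raise ValueError("PAC rate/coupling would produce overlapping beats")
    c = rng.uniform(coupling[0], coupling[1], idx.size)
    out.rr[idx] = c * local
    out.rr[idx + 1] = pause * local
    out.labels[idx] = "A"
    # rebuild times from the modified intervals (t[0] anchored)
    out.t = np.concatenate(([out.t[0]], out.t[0] + np.cumsum(out.rr[1:]) / 1000.0))
    return out, out.t[idx]


def inject_artifacts(
    series: BeatSeries, n: int, seed, low_ms: float = 120.0, high_ms: float = 2600.0
) -> tuple[BeatSeries, np.ndarray]:
    """Corrupt ``n`` random beats with out-of-range RR values (ground truth
    returned as beat indices). Times are left untouched so the artifacts also
    violate t/rr consistency, as real noise does."""
    out = series.copy()
    rng = np.random.default_rng(seed)
    idx = rng.choice(np.arange(1, out.n_beats - 1), size=n, replace=False)
    half = n // 2
    out.rr[idx[:half]] = rng.uniform(low_ms, 250.0, half)
    out.rr[idx[half:]] = rng.uniform(2300.0, high_ms, n - half)
    return out, np.sort(idx)


# ---------------------------------------------------------------------------
# atrial fibrillation
# ---------------------------------------------------------------------------

def simulate_af(
    params: AFParams,
    duration: float,
    seed,
    t0: float = 0.0,
    patient_id: str = "sim",
) -> BeatSeries:
    """Simulate an AF stretch: i.i.d. Gamma RR intervals, unlabeled (U).

    The Gamma shape/scale are set from the mean and coefficient of variation;
    successive intervals are serially independent by construction.
    """
    if duration < params.min_duration:
        raise ValueError("duration below the minimum AF episode duration")
    rng = np.random.default_rng(seed)
    shape = 1.0 / params.cv_af**2
    scale = params.mean_rr_af * params.cv_af**2
    n_est = int(duration * 1000.0 / params.mean_rr_af * 1.2) + 16
    rr = rng.gamma(shape, scale, n_est)
    np.maximum(rr, RR_FLOOR_MS * 0.5, out=rr)
    t = t0 + np.cumsum(rr) / 1000.0
    n = int(np.searchsorted(t, t0 + duration, side="right"))
    if n < 2:
        rr = rng.gamma(shape, scale, n_est * 2)
        t = t0 + np.cumsum(rr) / 1000.0
        n = int(np.searchsorted(t, t0 + duration, side="right"))
    return BeatSeries(
        patient_id=patient_id,
        t=t[:n],
        rr=rr[:n],
        labels=np.full(n, "U", dtype="<U1"),
    )


def _concat_series(parts: list[BeatSeries], template: BeatSeries) -> BeatSeries:
    return BeatSeries(
        patient_id=template.patient_id,
        t=np.concatenate([p.t for p in parts]),
        rr=np.concatenate([p.rr for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        start_day=template.start_day,
        start_hour=template.start_hour,
    )


# ---------------------------------------------------------------------------
# patients and cohorts
# ---------------------------------------------------------------------------

def simulate_patient(profile: PatientProfile, seed) -> tuple[BeatSeries, GroundTruth]:
    """Simulate one patient's recording plus its ground truth.

    Group II: sinus + PACs from recording start to the configured end. Group
    I: the same, but over the final ``ramp_hours`` before onset the PAC rate
    and HF amplitude rise linearly to ``ramp_pac_mult`` x / ``ramp_hf_mult``
    x baseline; at onset an AF episode of ``episode_minutes`` begins,
    followed by a short sinus tail. No AF beat ever precedes onset.
    """
    ss = np.random.SeedSequence(seed)
    s_sinus, s_pac, s_af, s_tail = ss.spawn(4)
    truth = GroundTruth(profile.patient_id, profile.group, seed=seed)

    if profile.group == "II":
        dur = (profile.recording_end_abs_hours - profile.start_abs_hours) * 3600.0
        if dur <= 0:
            raise ValueError("recording end precedes recording start")
        sinus = simulate_sinus(
            profile.sinus,
            dur,
            s_sinus,
            patient_id=profile.patient_id,
            start_day=profile.start_day,
            start_hour=profile.start_hour,
        )
        series, pac_t = inject_pacs(sinus, profile.pac_base_rate, s_pac)
        truth.pac_times = pac_t
        return series, truth

    onset_t = (profile.onset_abs_hours - profile.start_abs_hours) * 3600.0
    if onset_t <= 0:
        raise ValueError("AF onset precedes recording start")
    ramp_start = max(0.0, onset_t - profile.ramp_hours * 3600.0)
    sinus = simulate_sinus(
        profile.sinus,
        onset_t,
        s_sinus,
        patient_id=profile.patient_id,
        ramp=(ramp_start, onset_t, profile.ramp_hf_mult),
        start_day=profile.start_day,
        start_hour=profile.start_hour,
    )

    def pac_mult(t: float) -> float:
        if t <= ramp_start:
            return 1.0
        frac = min((t - ramp_start) / max(onset_t - ramp_start, 1e-9), 1.0)
        return 1.0 + (profile.ramp_pac_mult - 1.0) * frac

    pre, pac_t = inject_pacs(
        sinus, profile.pac_base_rate, s_pac, rate_fn=pac_mult
    )
    # trim beats pushed past onset by PAC timing perturbations
    n_pre = int(np.searchsorted(pre.t, onset_t, side="right"))
    pre = BeatSeries(
        pre.patient_id, pre.t[:n_pre], pre.rr[:n_pre], pre.labels[:n_pre],
        start_day=pre.start_day, start_hour=pre.start_hour,
    )
    episode_s = profile.episode_minutes * 60.0
    af = simulate_af(
        profile.af, episode_s, s_af, t0=pre.t[-1], patient_id=profile.patient_id
    )
    tail = simulate_sinus(
        profile.sinus, 1800.0, s_tail, t0=af.t[-1], patient_id=profile.patient_id
    )
    series = _concat_series([pre, af, tail], pre)
    # PAC timing perturbations shift the sinus stretch slightly, so the
    # episode actually starts at the end of the pre-onset part; the truth
    # records the realized onset (no AF beat ever precedes it).
    truth.episode_start_t = float(pre.t[-1])
    truth.episode_end_t = float(af.t[-1])
    truth.onset_abs_hours = profile.start_abs_hours + truth.episode_start_t / 3600.0
    truth.pac_times = pac_t[pac_t < truth.episode_start_t]
    return series, truth


def draw_profile(config: CohortConfig, index: int, rng: np.random.Generator) -> PatientProfile:
    """Draw one patient profile from the cohort's parameter ranges."""
    pid = f"P{index:03d}"
    group = "I" if rng.uniform() < config.prevalence else "II"
    sinus = SinusParams(
        mean_rr=float(rng.uniform(740.0, 900.0)),
        a_lf=float(rng.uniform(20.0, 35.0)),
        a_hf=float(rng.uniform(20.0, 35.0)),
        noise_sd=float(rng.uniform(15.0, 25.0)),
    )
    start_hour = float(rng.uniform(8.0, 16.0))
    start_abs = start_hour  # recordings start on day 1
    if group == "I":
        rate = float(
            np.exp(rng.normal(math.log(config.pac_rate_median_i), config.pac_rate_sigma_i))
        )
        days = np.arange(1, 6)
        w = np.asarray(config.onset_day_weights, dtype=float)
        w = w / w.sum()
        for _ in range(100):
            day = int(rng.choice(days, p=w))
            hour = float(rng.uniform(0.0, 24.0))
            onset_abs = (day - 1) * 24.0 + hour
            if onset_abs >= start_abs + 7.0:  # avoid immediate-postop AF exclusions
                break
        else:
            onset_abs = start_abs + 7.0
        af = AFParams(mean_rr_af=float(sinus.mean_rr * rng.uniform(0.70, 0.80)))
        episode_minutes = float(rng.uniform(10.0, 40.0))
        end_abs = onset_abs + episode_minutes / 60.0 + 1.0
        return PatientProfile(
            patient_id=pid,
            group="I",
            sinus=sinus,
            af=af,
            pac_base_rate=rate,
            onset_abs_hours=onset_abs,
            episode_minutes=episode_minutes,
            start_hour=start_hour,
            recording_end_abs_hours=end_abs,
        )
    rate = float(
        np.exp(rng.normal(math.log(config.pac_rate_median_ii), config.pac_rate_sigma_ii))
    )
    return PatientProfile(
        patient_id=pid,
        group="II",
        sinus=sinus,
        pac_base_rate=rate,
        start_hour=start_hour,
        recording_end_abs_hours=48.0,  # through the end of day 2
    )


def simulate_cohort(
    config: CohortConfig = CohortConfig(),
) -> tuple[list[tuple[BeatSeries, GroundTruth]], list[PatientProfile]]:
    """Simulate a full cohort; reproducible byte-for-byte from master_seed.

    Group membership is Bernoulli(prevalence); per-patient seeds are derived
    deterministically from the master seed.
    """
    if config.n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.master_seed, spawn_key=(0xC0, 0))
    )
    records = []
    profiles = []
    for i in range(config.n_patients):
        profile = draw_profile(config, i, rng)
        seed = patient_seed(config.master_seed, i)
        series, truth = simulate_patient(profile, seed)
        records.append((series, truth))
        profiles.append(profile)
    return records, profiles
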