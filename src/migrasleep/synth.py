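"""Seeded synthetic multi-day wrist-sensor datasets in the E4 export dialect.

The generator emulates what a wrist wearable records around one night of
sleep: high-movement wake padding on both ends, a low-movement sleep
interval, an AR(1) inter-beat-interval process whose successive-difference
spread realises a target RMSSD, a pulse waveform resampled to 64 Hz driven
by those intervals, heart rate as 60 / rolling-mean(IBI) at 1 Hz, and slow
4 Hz temperature/EDA drifts plus noise.  Nights before a migraine day can
carry configurable shifts of the nightly means, expressed in multiples of
the subject's between-night standard deviation, plus a within-night trend
term — the pre-ictal signature the downstream classifier is asked to
recover.

Everything is a pure function of ``(profile, effect, seed)``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np

from .e4_io import DiaryLabels, E4Session, SignalChannel
from .errors import ValidationError

#: calendar anchor for synthetic studies (an arbitrary Monday, UTC)
BASE_DATE = dt.date(2023, 3, 6)

_EPOCH = dt.datetime(1970, 1, 1, tzinfo=dt.timezone.utc)


def _posix(day: dt.date, hour_frac: float) -> float:
    """POSIX seconds of ``day`` at fractional clock hour ``hour_frac``."""
    midnight = dt.datetime.combine(day, dt.time(0), tzinfo=dt.timezone.utc)
    return (midnight - _EPOCH).total_seconds() + hour_frac * 3600.0


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject generative parameters.

    Baselines describe the *nocturnal* state; the ``*_sd`` values are
    between-night standard deviations, the unit in which
    :class:`EffectSpec` shifts are expressed.  Clock times are fractional
    hours; sleep onset is on the evening before the waking day.
    """

    subject_id: str = "S1"
    n_days: int = 28
    n_migraine_days: int = 9
    temp_mean: float = 33.5      # °C, wrist skin temperature during sleep
    temp_sd: float = 0.4
    eda_mean: float = 0.30       # µS, tonic skin conductance
    eda_sd: float = 0.08
    hr_mean: float = 58.0        # bpm, nocturnal resting heart rate
    hr_sd: float = 2.5
    rmssd_mean: float = 0.045    # s, time-domain HRV
    rmssd_sd: float = 0.008
    movement_rate: float = 4.0   # postural-shift bursts per hour of sleep
    movement_rate_sd: float = 1.5
    sleep_onset_hour: float = 23.0   # clock hour of falling asleep
    sleep_onset_sd: float = 0.5      # h
    sleep_duration_mean: float = 7.5  # h
    sleep_duration_sd: float = 0.5
    wake_pad_hours: float = 0.5      # awake recording on each side of sleep
    missing_night_prob: float = 0.1
    ibi_ar_coef: float = 0.9         # AR(1) coefficient of the IBI process

    def __post_init__(self) -> None:
        if not (0 <= self.n_migraine_days <= self.n_days):
            raise ValidationError("need 0 <= n_migraine_days <= n_days")
        for name in ("temp_sd", "eda_sd", "hr_sd", "rmssd_sd", "movement_rate_sd",
                     "sleep_onset_sd", "sleep_duration_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0.0 <= self.missing_night_prob <= 1.0):
            raise ValidationError("missing_night_prob must be in [0, 1]")
        if self.sleep_duration_mean <= 0 or self.wake_pad_hours < 0:
            raise ValidationError("durations must be positive")

    @property
    def mean_ibi(self) -> float:
        return 60.0 / self.hr_mean


@dataclass(frozen=True)
class EffectSpec:
    """Pre-migraine shifts, in multiples of the between-night SD.

    ``trend_shift`` adds a within-night linear ramp to skin temperature
    scaled so the last-quarter minus first-quarter mean difference equals
    ``trend_shift × temp_sd``.  A zero spec makes the two classes
    identically distributed by construction.
    """

    temp_shift: float = 0.0
    eda_shift: float = 0.0
    hr_shift: float = 0.0
    rmssd_shift: float = 0.0
    movement_shift: float = 0.0
    trend_shift: float = 0.0

    def __post_init__(self) -> None:
        for f in (self.temp_shift, self.eda_shift, self.hr_shift,
                  self.rmssd_shift, self.movement_shift, self.trend_shift):
            if not np.isfinite(f):
                raise ValidationError("effect shifts must be finite")

    @classmethod
    def null(cls) -> "EffectSpec":
        return cls()

    def scaled(self, factor: float) -> "EffectSpec":
        return EffectSpec(*(factor * x for x in (
            self.temp_shift, self.eda_shift, self.hr_shift,
            self.rmssd_shift, self.movement_shift, self.trend_shift)))


#: default pre-ictal signature: warmer, sweatier, faster heart with less
#: variability and more restless sleep
DEFAULT_EFFECT = EffectSpec(temp_shift=1.0, eda_shift=1.0, hr_shift=0.5,
                            rmssd_shift=-1.0, movement_shift=0.5)


def _pulse_template(phase: np.ndarray) -> np.ndarray:
    # one systolic upstroke per beat, returning to baseline at both ends so
    # each interval contributes exactly one interior peak
    s = np.sin(np.pi * np.clip(phase, 0.0, 1.0))
    return s * s


def synthesize_bvp_from_ibi(ibi: np.ndarray, rate: float = 64.0) -> np.ndarray:
    """Concatenate one single-pulse template per inter-beat interval,
    resampled to ``rate`` Hz; total length ``round(sum(ibi) * rate)``."""
    ibi = np.asarray(ibi, dtype=float)
    if ibi.size == 0:
        return np.empty(0)
    if np.any(ibi <= 0):
        raise ValidationError("inter-beat intervals must be positive")
    edges = np.concatenate(([0.0], np.cumsum(ibi)))
    n = int(round(edges[-1] * rate))
    t = np.arange(n) / rate
    beat = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(ibi) - 1)
    phase = (t - edges[beat]) / ibi[beat]
    return _pulse_template(phase)


def _ibi_process(rng: np.random.Generator, duration: float, mean_ibi: float,
                 rmssd: float, ar: float) -> np.ndarray:
    """AR(1)-perturbed IBI sequence spanning at least ``duration`` seconds.

    The innovation SD is chosen so the stationary successive-difference SD
    equals the RMSSD target: sd(diff) = sigma_e * sqrt(2 / (1 + ar)).
    """
    n = int(duration / mean_ibi) + 16
    sigma_e = rmssd * np.sqrt((1.0 + ar) / 2.0)
    e = rng.normal(0.0, sigma_e, size=n)
    x = np.empty(n)
    # start from the stationary distribution
    x[0] = rng.normal(0.0, sigma_e / np.sqrt(1.0 - ar * ar))
    for i in range(1, n):
        x[i] = ar * x[i - 1] + e[i]
    ibi = np.clip(mean_ibi + x, 0.35, 2.5)
    keep = np.searchsorted(np.cumsum(ibi), duration) + 1
    return ibi[: min(keep, n)]


def _movement_profile(rng: np.random.Generator, n: int, rate_hz: float,
                      sleep_lo: int, sleep_hi: int, burst_rate_per_h: float) -> np.ndarray:
    """Per-sample movement noise SD in raw 1/64 g units."""
    sd = np.full(n, 6.0)                      # wake: continuous movement
    sd[sleep_lo:sleep_hi] = 0.08              # sleep: stillness
    sleep_hours = (sleep_hi - sleep_lo) / rate_hz / 3600.0
    n_bursts = rng.poisson(max(burst_rate_per_h, 0.0) * sleep_hours)
    for _ in range(n_bursts):
        start = rng.integers(sleep_lo, max(sleep_hi - 1, sleep_lo + 1))
        length = int(rng.uniform(3.0, 15.0) * rate_hz)  # 3–15 s shifts
        sd[start: min(start + length, sleep_hi)] = rng.uniform(3.0, 8.0)
    return sd


def generate_night(profile: SubjectProfile, is_pre_migraine: bool,
                   effect: EffectSpec, seed: int, *, waking_day: dt.date | None = None,
                   return_truth: bool = False):
    """Generate one evening→morning :class:`E4Session`.

    With ``return_truth=True`` also returns a dict with the true sleep
    boundaries and the nightly parameter draws, for use as an oracle.
    """
    rng = np.random.default_rng(seed)
    if waking_day is None:
        waking_day = BASE_DATE + dt.timedelta(days=1)
    evening = waking_day - dt.timedelta(days=1)

    onset_hour = profile.sleep_onset_hour + rng.normal(0.0, profile.sleep_onset_sd)
    sleep_dur_h = max(profile.sleep_duration_mean + rng.normal(0.0, profile.sleep_duration_sd),
                      0.25)
    pad = profile.wake_pad_hours * 3600.0
    sleep_dur = sleep_dur_h * 3600.0
    total = 2 * pad + sleep_dur
    if total <= 0:
        raise ValidationError("night duration must be positive")
    start = _posix(evening, onset_hour) - pad
    sleep_start, sleep_end = start + pad, start + pad + sleep_dur

    pre = float(is_pre_migraine)
    temp_level = profile.temp_mean + rng.normal(0.0, profile.temp_sd) + pre * effect.temp_shift * profile.temp_sd
    eda_level = max(profile.eda_mean + rng.normal(0.0, profile.eda_sd) + pre * effect.eda_shift * profile.eda_sd, 0.02)
    hr_level = max(profile.hr_mean + rng.normal(0.0, profile.hr_sd) + pre * effect.hr_shift * profile.hr_sd, 35.0)
    rmssd = max(profile.rmssd_mean + rng.normal(0.0, profile.rmssd_sd) + pre * effect.rmssd_shift * profile.rmssd_sd,
                0.003)
    move_rate = max(profile.movement_rate + rng.normal(0.0, profile.movement_rate_sd)
                    + pre * effect.movement_shift * profile.movement_rate_sd, 0.0)

    # cardiac chain: IBI -> BVP -> HR
    ibi = _ibi_process(rng, total, 60.0 / hr_level, rmssd, profile.ibi_ar_coef)
    beat_times = np.cumsum(ibi)
    offsets = beat_times[beat_times <= total]
    ibi_kept = ibi[: len(offsets)]
    ibi_samples = np.column_stack([offsets, ibi_kept]) if len(offsets) else np.empty((0, 2))

    bvp = synthesize_bvp_from_ibi(ibi_kept, 64.0)
    n_bvp = int(round(total * 64.0))
    if len(bvp) < n_bvp:
        bvp = np.pad(bvp, (0, n_bvp - len(bvp)), mode="edge" if len(bvp) else "constant")
    bvp = bvp[:n_bvp] + rng.normal(0.0, 0.03, size=n_bvp)

    # HR at 1 Hz from a 10-beat rolling mean of the IBI
    n_hr = int(round(total))
    if len(ibi_kept) >= 1:
        k = min(10, len(ibi_kept))
        kern = np.ones(k) / k
        roll = np.convolve(ibi_kept, kern, mode="full")[k - 1: len(ibi_kept) + k - 1]
        hr_inst = 60.0 / roll
        tick = np.arange(n_hr, dtype=float)
        idx = np.clip(np.searchsorted(offsets, tick, side="right") - 1, 0, len(hr_inst) - 1)
        hr = hr_inst[idx] + rng.normal(0.0, 0.3, size=n_hr)
    else:
        hr = np.full(n_hr, hr_level)

    # accelerometer at 32 Hz, raw units of 1/64 g, gravity on z
    n_acc = int(round(total * 32.0))
    lo, hi = int(pad * 32.0), int((pad + sleep_dur) * 32.0)
    sd = _movement_profile(rng, n_acc, 32.0, lo, hi, move_rate)
    acc = rng.normal(0.0, 1.0, size=(n_acc, 3)) * sd[:, None]
    acc[:, 2] += 64.0
    acc = np.round(acc)

    # temperature and EDA at 4 Hz: level + slow drift + noise
    n_slow = int(round(total * 4.0))
    t_slow = np.arange(n_slow) / 4.0
    in_sleep = (t_slow >= pad) & (t_slow < pad + sleep_dur)
    ramp = np.clip((t_slow - pad) / max(sleep_dur, 1.0), 0.0, 1.0)
    temp = (temp_level - 0.3 + 0.3 * ramp
            + 0.1 * np.sin(2 * np.pi * t_slow / 5400.0)
            + rng.normal(0.0, 0.02, size=n_slow))
    if effect.trend_shift and is_pre_migraine:
        # linear ramp whose last-vs-first-quarter mean difference is the shift
        temp += (effect.trend_shift * profile.temp_sd / 0.75) * ramp
    temp[~in_sleep] -= 0.5  # exposed skin cools while up and about
    eda = (eda_level
           + 0.05 * eda_level * np.sin(2 * np.pi * t_slow / 3600.0)
           + rng.normal(0.0, 0.01, size=n_slow))
    eda[~in_sleep] += 0.1   # wake arousal
    eda = np.clip(eda, 0.0, None)

    sid = f"{profile.subject_id}_{waking_day.isoformat()}"
    channels = {
        "ACC": SignalChannel("ACC", start, 32.0, acc),
        "BVP": SignalChannel("BVP", start, 64.0, bvp),
        "EDA": SignalChannel("EDA", start, 4.0, eda),
        "HR": SignalChannel("HR", start, 1.0, hr),
        "TEMP": SignalChannel("TEMP", start, 4.0, temp),
        "IBI": SignalChannel("IBI", start, None, ibi_samples),
    }
    session = E4Session(sid, profile.subject_id, channels)
    if not return_truth:
        return session
    truth = {
        "sleep_start": sleep_start, "sleep_end": sleep_end,
        "temp_level": temp_level, "eda_level": eda_level,
        "hr_level": hr_level, "rmssd": rmssd, "movement_rate": move_rate,
        "is_pre_migraine": bool(is_pre_migraine),
    }
    return session, truth


def generate_subject_dataset(profile: SubjectProfile, effect: EffectSpec, seed: int,
                             *, return_truth: bool = False):
    """Generate a subject's full study: one night per day minus missing
    nights, plus the matching diary.

    Waking days are ``BASE_DATE + 1 .. BASE_DATE + n_days``; migraine days
    are placed uniformly at random without adjacency constraints; the diary
    always covers every day even when the night's recording is missing.
    """
    if profile.n_migraine_days > profile.n_days:
        raise ValidationError("n_migraine_days exceeds n_days")
    rng = np.random.default_rng(seed)
    mig_idx = set(rng.choice(profile.n_days, size=profile.n_migraine_days,
                             replace=False).tolist())
    night_seeds = rng.integers(0, 2**31 - 1, size=profile.n_days)
    drop = rng.random(profile.n_days) < profile.missing_night_prob

    sessions: list[E4Session] = []
    truths: dict[str, dict] = {}
    entries: dict = {}
    for d in range(profile.n_days):
        day = BASE_DATE + dt.timedelta(days=d + 1)
        is_mig = d in mig_idx
        entries[day] = (is_mig, "migraine" if is_mig else "")
        if drop[d]:
            continue
        out = generate_night(profile, is_mig, effect, int(night_seeds[d]),
                             waking_day=day, return_truth=return_truth)
        if return_truth:
            session, truth = out
            truths[session.session_id] = truth
        else:
            session = out
        sessions.append(session)
    diary = DiaryLabels(profile.subject_id, entries)
    if return_truth:
        return sessions, diary, truths
    return sessions, diary


def default_cohort(n_subjects: int = 7, seed: int = 0, **overrides) -> list[SubjectProfile]:
    """A cohort of subject profiles with realistic between-subject spread."""
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n_subjects):
        kwargs = dict(
            subject_id=f"S{i + 1}",
            n_days=int(rng.integers(24, 36)),
            n_migraine_days=int(rng.integers(5, 15)),
            temp_mean=float(rng.normal(33.5, 0.6)),
            eda_mean=float(rng.uniform(0.15, 0.6)),
            hr_mean=float(rng.normal(58.0, 5.0)),
            rmssd_mean=float(rng.uniform(0.03, 0.06)),
            movement_rate=float(rng.uniform(2.0, 6.0)),
        )
        kwargs.update(overrides)
        profiles.append(SubjectProfile(**kwargs))
    return profiles
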