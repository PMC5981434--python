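"""Preprocessing: acceleration magnitude, resampling to the 64 Hz pulse
grid, actigraphy-style sleep-interval detection, and night segmentation.

The pulse channel has the highest native rate (64 Hz), so every other
channel is brought onto its grid: slower regular channels by zero-order
hold (sample-and-hold, which invents no intra-sample structure), the
irregular inter-beat-interval events by linear interpolation.  Sleep is the
longest contiguous stretch in which the rolling standard deviation of the
acceleration magnitude stays below a threshold, with short restless gaps
bridged — a standard actigraphy heuristic standing in for per-night visual
inspection.  Each detected night is labelled with the diary status of the
calendar day the subject wakes into.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .e4_io import DiaryLabels, E4Session
from .errors import DetectionError, ValidationError

log = logging.getLogger(__name__)

GRID_RATE = 64.0

#: resampled signal columns, in registry order
BLOCK_COLUMNS = ("acc_mag", "bvp", "temp", "hr", "eda", "ibi_interp")


@dataclass(frozen=True)
class SleepDetectorParams:
    """Tunables of the movement-based sleep detector.

    window_s: rolling-SD window (s); threshold_g: stillness threshold on the
    rolling SD of acceleration magnitude (g); bridge_gap_s: restless gaps
    shorter than this are merged into the surrounding stillness (s);
    min_sleep_s: shortest interval accepted as a night's sleep (s).
    """

    window_s: float = 60.0
    threshold_g: float = 0.01
    bridge_gap_s: float = 300.0
    min_sleep_s: float = 3.0 * 3600.0
    #: local-time offset from UTC (h) used when mapping wake times to days
    tz_offset_hours: float = 0.0


@dataclass(frozen=True)
class ResampledBlock:
    """All channels of a session on one 64 Hz time base.

    ``t0`` is the POSIX time of the first grid point; column ``i`` sits at
    ``t0 + i / 64``.  The raw IBI events (absolute beat time, interval) are
    carried alongside for HRV features.
    """

    t0: float
    columns: dict[str, np.ndarray]
    ibi_events: np.ndarray  # (n, 2): absolute beat time (s), interval (s)

    def __post_init__(self) -> None:
        lengths = {k: len(v) for k, v in self.columns.items()}
        if len(set(lengths.values())) != 1:
            raise ValidationError(f"column lengths differ: {lengths}")
        for k, v in self.columns.items():
            if np.isnan(v).any():
                raise ValidationError(f"column {k} contains NaN after fill")

    def __len__(self) -> int:
        return len(next(iter(self.columns.values())))

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / GRID_RATE

    def slice_time(self, start: float, end: float) -> "ResampledBlock":
        """Restrict to grid points in ``[start, end)``."""
        i0 = max(int(np.ceil((start - self.t0) * GRID_RATE)), 0)
        i1 = min(int(np.ceil((end - self.t0) * GRID_RATE)), len(self))
        if i1 <= i0:
            raise ValidationError("empty time slice")
        cols = {k: v[i0:i1] for k, v in self.columns.items()}
        ev = self.ibi_events
        if len(ev):
            ev = ev[(ev[:, 0] >= start) & (ev[:, 0] < end)]
        return ResampledBlock(self.t0 + i0 / GRID_RATE, cols, ev)


@dataclass(frozen=True)
class NightRecording:
    """One night's sleep-restricted signal block plus its class label."""

    subject_id: str
    night_id: str
    sleep_start: float
    sleep_end: float
    block: ResampledBlock
    label: str  # "pre_migraine" | "non_migraine"

    def __post_init__(self) -> None:
        if self.sleep_end <= self.sleep_start:
            raise ValidationError("sleep_end must exceed sleep_start")
        if self.label not in ("pre_migraine", "non_migraine"):
            raise ValidationError(f"unknown label {self.label!r}")


def compute_acc_magnitude(acc_g: np.ndarray) -> np.ndarray:
    """Euclidean norm of 3-axis acceleration samples (already in g)."""
    acc_g = np.asarray(acc_g, dtype=float)
    if acc_g.ndim != 2 or acc_g.shape[1] != 3:
        raise ValidationError(f"expected (n, 3) acceleration, got {acc_g.shape}")
    return np.sqrt(np.einsum("ij,ij->i", acc_g, acc_g))


def resample_channels(session: E4Session) -> ResampledBlock:
    """Bring every channel to the shared 64 Hz grid over the overlap of all
    channel time spans."""
    regular = [session[name] for name in ("ACC", "BVP", "EDA", "HR", "TEMP")]
    start = max(ch.start_time for ch in regular)
    end = min(ch.end_time for ch in regular)
    n = int(np.floor((end - start) * GRID_RATE))
    if n <= 0:
        raise ValidationError("channels share no overlapping time span")
    t = start + np.arange(n) / GRID_RATE

    def hold_values(values: np.ndarray, start_time: float, rate: float) -> np.ndarray:
        idx = ((t - start_time) * rate).astype(np.int64)
        return values[np.clip(idx, 0, len(values) - 1)]

    def hold(ch) -> np.ndarray:
        return hold_values(ch.samples, ch.start_time, ch.sample_rate)

    # magnitude at the native 32 Hz, then held: hold and norm commute
    acc = session["ACC"]
    mag_native = compute_acc_magnitude(acc.samples / 64.0)  # raw 1/64 g -> g
    cols = {
        "acc_mag": hold_values(mag_native, acc.start_time, acc.sample_rate),
        "bvp": hold(session["BVP"]),
        "temp": hold(session["TEMP"]),
        "hr": hold(session["HR"]),
        "eda": hold(session["EDA"]),
    }

    if session.has_ibi and len(session["IBI"].samples):
        ev = session["IBI"].samples
        beat_times = session["IBI"].start_time + ev[:, 0]
        cols["ibi_interp"] = np.interp(t, beat_times, ev[:, 1])
        events = np.column_stack([beat_times, ev[:, 1]])
    else:
        # no beat events exported: fall back to the heart-rate channel
        cols["ibi_interp"] = 60.0 / np.clip(cols["hr"], 20.0, None)
        events = np.empty((0, 2))
    return ResampledBlock(start, cols, events)


def _rolling_std(x: np.ndarray, window: int) -> np.ndarray:
    return pd.Series(x).rolling(window, min_periods=window, center=True).std().to_numpy()


def detect_sleep_period(block: ResampledBlock,
                        params: SleepDetectorParams = SleepDetectorParams()) -> tuple[float, float]:
    """Longest stillness interval of the block, as POSIX ``(start, end)``.

    Stillness is rolling-SD(acc_mag) < threshold; interruptions shorter than
    the bridge gap are merged.  Raises :class:`DetectionError` when no
    interval reaches the minimum sleep duration.
    """
    win = max(int(params.window_s * GRID_RATE), 2)
    rstd = _rolling_std(block.columns["acc_mag"], win)
    quiet = np.nan_to_num(rstd, nan=np.inf) < params.threshold_g
    if not quiet.any():
        raise DetectionError("no low-movement samples found")

    # run-length encode, bridging short loud gaps between quiet runs
    padded = np.concatenate(([False], quiet, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    max_gap = int(params.bridge_gap_s * GRID_RATE)
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] <= max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    best = max(merged, key=lambda se: se[1] - se[0])
    dur = (best[1] - best[0]) / GRID_RATE
    if dur < params.min_sleep_s:
        raise DetectionError(
            f"longest stillness interval is {dur / 3600:.2f} h, "
            f"below the {params.min_sleep_s / 3600:.2f} h minimum")
    return block.t0 + best[0] / GRID_RATE, block.t0 + best[1] / GRID_RATE


def waking_date(sleep_end: float, tz_offset_hours: float = 0.0) -> dt.date:
    """Calendar day (local time) the subject wakes into."""
    t = dt.datetime.fromtimestamp(sleep_end + tz_offset_hours * 3600.0,
                                  tz=dt.timezone.utc)
    return t.date()


def segment_label_nights(sessions: list[E4Session], diary: DiaryLabels,
                         params: SleepDetectorParams = SleepDetectorParams()) -> list[NightRecording]:
    """One labelled :class:`NightRecording` per detectable sleep interval.

    Nights whose detection fails, or whose waking day has no diary entry,
    are dropped with a logged warning — mirroring how unusable nights fall
    out of a real study.
    """
    nights: list[NightRecording] = []
    for session in sessions:
        try:
            block = resample_channels(session)
            sleep_start, sleep_end = detect_sleep_period(block, params)
        except (DetectionError, ValidationError) as exc:
            log.warning("session %s: skipped (%s)", session.session_id, exc)
            continue
        day = waking_date(sleep_end, params.tz_offset_hours)
        flag = diary.is_migraine_day(day)
        if flag is None:
            log.warning("session %s: waking day %s has no diary entry; dropped",
                        session.session_id, day)
            continue
        label = "pre_migraine" if flag else "non_migraine"
        night = NightRecording(
            subject_id=session.subject_id or diary.subject_id,
            night_id=f"{session.subject_id or diary.subject_id}_{day.isoformat()}",
            sleep_start=sleep_start,
            sleep_end=sleep_end,
            block=block.slice_time(sleep_start, sleep_end),
            label=label,
        )
        log.info("night %s: sleep %.2f h, label %s", night.night_id,
                 (sleep_end - sleep_start) / 3600.0, label)
        nights.append(night)
    return nights
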