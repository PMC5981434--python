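"""Reading and writing the Empatica E4 CSV export dialect and diary labels.

The E4 wristband exports one CSV per channel.  For the regularly sampled
channels (ACC, BVP, EDA, HR, TEMP) the first row holds the session start
time as POSIX seconds (UTC), the second row the sampling rate in Hz, and
every following row one sample (three comma-separated values for the
accelerometer, one otherwise).  The inter-beat-interval file (IBI.csv) is an
event list: the first row is the start time, each later row an
``offset_seconds,interval_seconds`` pair.

Accelerometer samples are kept in the raw export unit of 1/64 g; conversion
to g happens at preprocessing so that a write→read round trip is the
identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: channels that must be present in every session, with their sample arity
REQUIRED_CHANNELS = ("ACC", "BVP", "EDA", "HR", "TEMP")
#: native sampling rates of the E4, Hz
NATIVE_RATES = {"ACC": 32.0, "BVP": 64.0, "EDA": 4.0, "HR": 1.0, "TEMP": 4.0}

_ARITY = {"ACC": 3, "IBI": 2}


@dataclass(frozen=True)
class SignalChannel:
    """One channel of an E4 session.

    ``samples`` is a 1-D float array, except ACC (shape ``(n, 3)``, units of
    1/64 g) and IBI (shape ``(n, 2)`` of ``(offset_s, interval_s)`` pairs,
    offsets relative to ``start_time``).  ``sample_rate`` is ``None`` for the
    event-based IBI channel.
    """

    name: str
    start_time: float
    sample_rate: float | None
    samples: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", arr)
        arity = _ARITY.get(self.name, 1)
        if arity == 1:
            if arr.ndim != 1:
                raise ValidationError(f"{self.name}: expected 1-D samples, got shape {arr.shape}")
        else:
            if arr.ndim != 2 or arr.shape[1] != arity:
                raise ValidationError(f"{self.name}: expected (n, {arity}) samples, got shape {arr.shape}")
        if self.name == "IBI":
            if self.sample_rate is not None:
                raise ValidationError("IBI is an event channel and has no sample rate")
            offsets = arr[:, 0] if len(arr) else np.empty(0)
            if len(offsets) > 1 and not np.all(np.diff(offsets) > 0):
                raise ValidationError("IBI offsets must be strictly increasing")
        else:
            if self.sample_rate is None or self.sample_rate <= 0:
                raise ValidationError(f"{self.name}: sample_rate must be positive")

    @property
    def duration(self) -> float:
        """Span of the channel in seconds."""
        if self.name == "IBI":
            return float(self.samples[-1, 0]) if len(self.samples) else 0.0
        return len(self.samples) / self.sample_rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalChannel):
            return NotImplemented
        return (
            self.name == other.name
            and self.start_time == other.start_time
            and self.sample_rate == other.sample_rate
            and self.samples.shape == other.samples.shape
            and np.array_equal(self.samples, other.samples)
        )


@dataclass(frozen=True)
class E4Session:
    """One contiguous wear session: required channels plus optional IBI."""

    session_id: str
    subject_id: str
    channels: dict[str, SignalChannel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_CHANNELS if c not in self.channels]
        if missing:
            raise ValidationError(f"session {self.session_id}: missing required channels {missing}")

    def __getitem__(self, name: str) -> SignalChannel:
        return self.channels[name]

    @property
    def has_ibi(self) -> bool:
        return "IBI" in self.channels

    @property
    def start_time(self) -> float:
        return min(ch.start_time for ch in self.channels.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, E4Session):
            return NotImplemented
        return (
            self.session_id == other.session_id
            and self.subject_id == other.subject_id
            and set(self.channels) == set(other.channels)
            and all(self.channels[k] == other.channels[k] for k in self.channels)
        )


@dataclass(frozen=True)
class DiaryLabels:
    """Per-calendar-day migraine/non-migraine flags from a subject's diary.

    ``entries`` maps ISO dates (``datetime.date``) to ``(migraine_day, note)``.
    Days without an entry are simply absent; they are never imputed.
    """

    subject_id: str
    entries: dict  # date -> (bool, str)

    def is_migraine_day(self, day) -> bool | None:
        """Diary flag for ``day``; ``None`` when the day has no entry."""
        hit = self.entries.get(day)
        return None if hit is None else bool(hit[0])

    @property
    def n_days(self) -> int:
        return len(self.entries)

    @property
    def n_migraine_days(self) -> int:
        return sum(1 for flag, _ in self.entries.values() if flag)


# ---------------------------------------------------------------------------
# session I/O


def _format_float(x: float) -> str:
    # integers print without a decimal point so integer-valued channels (raw
    # ACC counts) survive the round trip byte-for-byte
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def _samples_frame(arr: np.ndarray) -> pd.DataFrame:
    # integral-valued channels (raw accelerometer counts) print as integers
    if arr.size and np.all(arr == np.rint(arr)) and np.all(np.abs(arr) < 2**53):
        arr = arr.astype(np.int64)
    return pd.DataFrame(arr.reshape(len(arr), -1) if arr.ndim == 1 else arr)


def write_e4_session(session: E4Session, path: str | Path) -> None:
    """Write ``session`` as an Empatica-style directory of per-channel CSVs."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, ch in session.channels.items():
        with open(path / f"{name}.csv", "w", newline="") as fh:
            if name == "IBI":
                fh.write(_format_float(ch.start_time) + "\n")
            else:
                width = _ARITY.get(name, 1)
                fh.write(",".join([_format_float(ch.start_time)] * width) + "\n")
                fh.write(",".join([_format_float(ch.sample_rate)] * width) + "\n")
            if len(ch.samples):
                _samples_frame(ch.samples).to_csv(fh, header=False, index=False,
                                                  lineterminator="\n")


def _read_body(path: Path, skiprows: int, width: int) -> np.ndarray:
    """Data rows of a channel CSV as a float array of the given width."""
    try:
        df = pd.read_csv(path, header=None, skiprows=skiprows, dtype=float)
    except pd.errors.EmptyDataError:
        return np.empty((0, width))
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: malformed sample rows: {exc}") from exc
    if df.shape[1] != width:
        raise FormatError(f"{path}: expected {width} values per row, "
                          f"got {df.shape[1]}")
    arr = df.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise FormatError(f"{path}: missing values in sample rows")
    return arr


def _read_header_row(path: Path, line: str, what: str) -> float:
    try:
        return float(line.strip().split(",")[0])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: malformed {what}: {line!r}") from exc


def _read_channel_csv(path: Path, name: str) -> SignalChannel:
    try:
        with open(path) as fh:
            header = [fh.readline(), fh.readline()]
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if not header[0].strip():
        raise FormatError(f"{path}: empty file")
    start = _read_header_row(path, header[0], "start-time row")
    if name == "IBI":
        samples = _read_body(path, 1, 2)
        return SignalChannel(name, start, None, samples)
    if not header[1].strip():
        raise FormatError(f"{path}: missing sample-rate row")
    rate = _read_header_row(path, header[1], "sample-rate row")
    width = _ARITY.get(name, 1)
    samples = _read_body(path, 2, width)
    if width == 1:
        samples = samples.ravel()
    return SignalChannel(name, start, rate, samples)


def read_e4_session(path: str | Path, session_id: str | None = None, subject_id: str = "") -> E4Session:
    """Read an Empatica export directory into an :class:`E4Session`.

    Raises :class:`FormatError` for missing required files or malformed
    headers, :class:`ValidationError` for non-monotone IBI offsets.
    """
    path = Path(path)
    channels: dict[str, SignalChannel] = {}
    for name in REQUIRED_CHANNELS:
        f = path / f"{name}.csv"
        if not f.exists():
            raise FormatError(f"{path}: required channel file {name}.csv is missing")
        channels[name] = _read_channel_csv(f, name)
    ibi = path / "IBI.csv"
    if ibi.exists():
        channels["IBI"] = _read_channel_csv(ibi, "IBI")
    return E4Session(session_id or path.name, subject_id, channels)


# ---------------------------------------------------------------------------
# diary I/O


def read_diary(path: str | Path, subject_id: str = "") -> DiaryLabels:
    """Read a diary CSV with columns ``date`` (ISO-8601), ``migraine`` (0/1),
    ``note`` into :class:`DiaryLabels`."""
    try:
        df = pd.read_csv(path, dtype={"note": str}, keep_default_na=False)
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse diary {path}: {exc}") from exc
    if df.empty and set(df.columns) >= {"date", "migraine"}:
        return DiaryLabels(subject_id, {})
    for col in ("date", "migraine"):
        if col not in df.columns:
            raise FormatError(f"diary {path}: missing column {col!r}")
    try:
        dates = pd.to_datetime(df["date"], format="ISO8601").dt.date
    except (ValueError, TypeError) as exc:
        raise FormatError(f"diary {path}: unparseable date: {exc}") from exc
    if dates.duplicated().any():
        dup = dates[dates.duplicated()].iloc[0]
        raise ValidationError(f"diary {path}: duplicate entry for {dup}")
    flags = df["migraine"].astype(int)
    if not flags.isin((0, 1)).all():
        raise ValidationError(f"diary {path}: migraine flags must be 0/1")
    notes = df["note"] if "note" in df.columns else pd.Series([""] * len(df))
    entries = {d: (bool(f), str(n)) for d, f, n in zip(dates, flags, notes)}
    return DiaryLabels(subject_id, entries)


def write_diary(diary: DiaryLabels, path: str | Path) -> None:
    rows = [
        {"date": d.isoformat(), "migraine": int(flag), "note": note}
        for d, (flag, note) in sorted(diary.entries.items())
    ]
    pd.DataFrame(rows, columns=["date", "migraine", "note"]).to_csv(path, index=False)
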