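"""The 110-feature nightly vector.

Per night the pipeline computes, over the sleep-restricted 64 Hz block:

* full-night statistics — SD and mean of {acceleration magnitude, pulse,
  temperature, heart rate, EDA, inter-beat intervals}; minimum of the first
  four signals (EDA minimum is excluded: on the wrist it pins at zero);
  maximum, median and 5th/25th/75th/95th percentiles of the five resampled
  signals;
* quarter-comparison features — the night split into four equal-size parts
  by sample count, and for each of the same statistics the last-quarter
  value minus the first-quarter value (the last quarter is the closest to a
  morning attack);
* pairwise Pearson correlations of the six resampled columns, minus the
  (heart rate, interpolated IBI) pair, which is a deterministic transform
  pairing — 14 values;
* six time-domain HRV summaries of the raw inter-beat-interval event list.

That yields 46 + 44 + 14 + 6 = 110 features in a fixed, versioned order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ValidationError
from .preprocess import NightRecording, ResampledBlock

log = logging.getLogger(__name__)

_FIVE = ("acc", "bvp", "temp", "hr", "eda")
_MIN_SIGNALS = ("acc", "bvp", "temp", "hr")  # EDA minimum excluded
_COLUMN_OF = {"acc": "acc_mag", "bvp": "bvp", "temp": "temp",
              "hr": "hr", "eda": "eda", "ibi": "ibi_interp"}

_FULL_STATS = (("std", _FIVE + ("hrv",)), ("mean", _FIVE + ("hrv",)),
               ("min", _MIN_SIGNALS), ("max", _FIVE), ("median", _FIVE),
               ("p5", _FIVE), ("p25", _FIVE), ("p75", _FIVE), ("p95", _FIVE))
_QUARTER_STATS = (("std", _FIVE), ("mean", _FIVE), ("max", _FIVE),
                  ("min", _MIN_SIGNALS), ("median", _FIVE), ("p5", _FIVE),
                  ("p25", _FIVE), ("p75", _FIVE), ("p95", _FIVE))

_CORR_SIGNALS = ("acc", "bvp", "temp", "hr", "eda", "ibi")
#: all 15 unordered pairs of the six resampled columns minus (hr, ibi)
CORRELATION_PAIRS = tuple(
    (a, b)
    for i, a in enumerate(_CORR_SIGNALS)
    for b in _CORR_SIGNALS[i + 1:]
    if {a, b} != {"hr", "ibi"}
)

HRV_FEATURES = ("hrv_rmssd", "hrv_mean_diff", "hrv_sd_diff",
                "hrv_n_beats", "hrv_nn50", "hrv_total_power")

NN50_THRESHOLD_S = 0.050


def _build_registry() -> list[dict]:
    reg: list[dict] = []
    for stat, signals in _FULL_STATS:
        for sig in signals:
            reg.append({"name": f"{stat}_{sig}", "category": "full_night",
                        "definition": f"{stat} of {sig} over the whole sleep interval"})
    for stat, signals in _QUARTER_STATS:
        for sig in signals:
            reg.append({"name": f"qdiff_{stat}_{sig}", "category": "quarter_diff",
                        "definition": f"{stat} of {sig}: last sleep quarter minus first"})
    for a, b in CORRELATION_PAIRS:
        reg.append({"name": f"corr_{a}_{b}", "category": "correlation",
                    "definition": f"Pearson correlation of {a} and {b} on the 64 Hz grid"})
    defs = {
        "hrv_rmssd": "root mean square of successive IBI differences (s)",
        "hrv_mean_diff": "mean of successive IBI differences (s)",
        "hrv_sd_diff": "SD of successive IBI differences (s)",
        "hrv_n_beats": "number of measured heart beats",
        "hrv_nn50": "pairs of adjacent beats differing by more than 50 ms",
        "hrv_total_power": "total spectral power of the IBI series (s^2)",
    }
    for name in HRV_FEATURES:
        reg.append({"name": name, "category": "hrv", "definition": defs[name]})
    return reg


FEATURE_REGISTRY: tuple[dict, ...] = tuple(_build_registry())
FEATURE_NAMES: tuple[str, ...] = tuple(f["name"] for f in FEATURE_REGISTRY)
N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 110


def export_registry(path: str | Path) -> None:
    """Write the versioned feature registry as documented JSON."""
    Path(path).write_text(json.dumps(
        {"version": 1, "n_features": N_FEATURES, "features": list(FEATURE_REGISTRY)},
        indent=2) + "\n")


@dataclass(frozen=True)
class NightFeatureVector:
    """The 110 named features of one night, in registry order."""

    night_id: str
    subject_id: str
    label: str  # "pre_migraine" | "non_migraine"
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", arr)
        if arr.shape != (N_FEATURES,):
            raise ValidationError(f"expected {N_FEATURES} features, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            bad = [FEATURE_NAMES[i] for i in np.flatnonzero(~np.isfinite(arr))]
            raise ValidationError(f"non-finite features: {bad}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))


_PCT_STATS = ("median", "p5", "p25", "p75", "p95")
_PCT_Q = (50, 5, 25, 75, 95)


def _stat_table(x: np.ndarray) -> dict[str, float]:
    """All order/moment statistics of one series in a single pass.

    Percentiles use linear interpolation between order statistics; the SD
    is the ddof=1 sample SD (0 for a single sample).
    """
    out = {
        "std": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        "mean": float(np.mean(x)),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
    }
    pct = np.percentile(x, _PCT_Q)
    out.update(zip(_PCT_STATS, pct))
    return out


def _stat(stat: str, x: np.ndarray) -> float:
    if stat == "std":
        return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    if stat == "mean":
        return float(np.mean(x))
    if stat == "min":
        return float(np.min(x))
    if stat == "max":
        return float(np.max(x))
    if stat == "median":
        return float(np.median(x))
    # percentiles use linear interpolation between order statistics
    return float(np.percentile(x, int(stat[1:])))


def compute_quarter_diffs(block: ResampledBlock) -> np.ndarray:
    """Last-quarter minus first-quarter statistics: 44 values in registry
    order.  Quarters are the first and last ``floor(N/4)`` samples."""
    n = len(block)
    if n < 4:
        raise ValidationError("need at least 4 samples to form quarters")
    q = n // 4
    first = {s: _stat_table(block.columns[_COLUMN_OF[s]][:q]) for s in _FIVE}
    last = {s: _stat_table(block.columns[_COLUMN_OF[s]][-q:]) for s in _FIVE}
    out = []
    for stat, signals in _QUARTER_STATS:
        for sig in signals:
            out.append(last[sig][stat] - first[sig][stat])
    return np.asarray(out)


def compute_signal_correlations(block: ResampledBlock) -> np.ndarray:
    """Pearson correlations of the 14 retained column pairs; a zero-variance
    column yields correlation 0 by convention."""
    if len(block) < 2:
        raise ValidationError("need at least 2 samples for correlations")
    cols = {s: block.columns[_COLUMN_OF[s]] for s in _CORR_SIGNALS}
    sd = {s: np.std(v) for s, v in cols.items()}
    out = []
    for a, b in CORRELATION_PAIRS:
        if sd[a] == 0.0 or sd[b] == 0.0:
            out.append(0.0)
        else:
            out.append(float(np.corrcoef(cols[a], cols[b])[0, 1]))
    return np.asarray(out)


def compute_hrv_features(ibi: np.ndarray) -> np.ndarray:
    """Six time-domain HRV summaries of an inter-beat-interval sequence (s).

    With fewer than 3 intervals the difference-based features are reported
    as 0 with a warning; the beat count stays exact.
    """
    ibi = np.asarray(ibi, dtype=float)
    n_beats = float(len(ibi))
    if len(ibi) < 3:
        log.warning("HRV: only %d intervals; difference features set to 0", len(ibi))
        return np.array([0.0, 0.0, 0.0, n_beats, 0.0, 0.0])
    d = np.diff(ibi)
    rmssd = float(np.sqrt(np.mean(d * d)))
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    nn50 = float(np.sum(np.abs(d) > NN50_THRESHOLD_S))
    total_power = _total_power(ibi)
    return np.array([rmssd, mean_d, sd_d, n_beats, nn50, total_power])


def _total_power(ibi: np.ndarray, fs: float = 4.0, f_hi: float = 2.0) -> float:
    """Welch total power of the IBI series linearly resampled to ``fs`` Hz,
    integrated over 0–``f_hi`` Hz (s²)."""
    beat_t = np.cumsum(ibi)
    dur = beat_t[-1] - beat_t[0]
    n = int(dur * fs)
    if n < 8:
        return 0.0
    grid = beat_t[0] + np.arange(n) / fs
    x = np.interp(grid, beat_t, ibi)
    f, pxx = sps.welch(x, fs=fs, nperseg=min(256, n), detrend="constant")
    keep = f <= f_hi
    return float(np.trapezoid(pxx[keep], f[keep]))


def extract_night_features(night: NightRecording) -> NightFeatureVector:
    """Compute the full 110-feature vector of one night."""
    block = night.block
    if len(block) < 4:
        raise ValidationError("night block shorter than 4 samples")
    ibi_raw = block.ibi_events[:, 1] if len(block.ibi_events) else np.empty(0)

    tables = {s: _stat_table(block.columns[_COLUMN_OF[s]]) for s in _FIVE}
    if len(ibi_raw):
        tables["hrv"] = _stat_table(ibi_raw)
    else:
        tables["hrv"] = {k: 0.0 for k in ("std", "mean", "min", "max", *_PCT_STATS)}
    values = []
    for stat, signals in _FULL_STATS:
        for sig in signals:
            values.append(tables[sig][stat])
    values.extend(compute_quarter_diffs(block))
    values.extend(compute_signal_correlations(block))
    values.extend(compute_hrv_features(ibi_raw))
    return NightFeatureVector(night.night_id, night.subject_id, night.label,
                              np.asarray(values))


# ---------------------------------------------------------------------------
# tabular persistence

def features_to_frame(vectors: list[NightFeatureVector]) -> pd.DataFrame:
    rows = [{"subject_id": v.subject_id, "night_id": v.night_id, "label": v.label,
             **v.as_dict()} for v in vectors]
    return pd.DataFrame(rows, columns=["subject_id", "night_id", "label", *FEATURE_NAMES])


def frame_to_features(df: pd.DataFrame) -> list[NightFeatureVector]:
    return [NightFeatureVector(r["night_id"], r["subject_id"], r["label"],
                               r[list(FEATURE_NAMES)].to_numpy(dtype=float))
            for _, r in df.iterrows()]


def save_features(vectors: list[NightFeatureVector], path: str | Path) -> None:
    features_to_frame(vectors).to_csv(path, index=False)


def load_features(path: str | Path) -> list[NightFeatureVector]:
    return frame_to_features(pd.read_csv(path))
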