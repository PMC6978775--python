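"""Ingestion and preprocessing of RR-interval recordings.

A recording arrives as beat-to-beat RR intervals (milliseconds).  This module
converts them to instantaneous heart rate, removes physiologically implausible
beats (outside 40-180 bpm, the standard ambulatory-ECG artifact bounds),
and resamples the irregular beat series onto an evenly spaced grid so that
fixed-duration segments always hold the same number of samples.  Short gaps
left by artifact removal are bridged by linear interpolation during
resampling; a warning is emitted when a gap exceeds 5 s.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    DegenerateInputError,
    EmptyInputError,
    ParameterError,
    ParseError,
)

__all__ = [
    "BeatSeries",
    "UniformSeries",
    "AnnotationTrack",
    "load_rr",
    "filter_hr",
    "resample_uniform",
    "hr_summary",
    "preprocess_recording",
    "save_uniform",
    "load_uniform",
]

#: default artifact bounds in beats per minute
HR_LO = 40.0
HR_HI = 180.0

#: gap length (seconds) above which interpolation is flagged as suspect
GAP_WARN_S = 5.0


@dataclass(frozen=True)
class BeatSeries:
    """Irregular beat-timestamped heart-rate samples.

    Attributes
    ----------
    t : ndarray
        Beat timestamps in seconds from recording start (cumulative RR sums;
        ``t[0] == rr[0]/1000``).
    rr : ndarray
        RR intervals in milliseconds, strictly positive.
    """

    t: np.ndarray
    rr: np.ndarray

    def __post_init__(self) -> None:
        if len(self.t) != len(self.rr):
            raise ValueError("t and rr must have equal length")
        if len(self.rr) and np.any(self.rr <= 0):
            raise ValueError("RR intervals must be positive")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("beat timestamps must be strictly increasing")

    @property
    def hr(self) -> np.ndarray:
        """Instantaneous heart rate in beats/min (60000/RR)."""
        return 60000.0 / self.rr

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class UniformSeries:
    """Heart-rate samples on an evenly spaced grid.

    ``x[k]`` is the value at time ``t0 + k/fs`` seconds.
    """

    fs: float
    x: np.ndarray
    t0: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.x)) / self.fs

    @property
    def duration_s(self) -> float:
        return (len(self.x) - 1) / self.fs if len(self.x) else 0.0

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class AnnotationTrack:
    """Self-reported sleep windows (lights-off to lights-on), in seconds
    from recording start.  Intervals are half-open ``[start, end)``,
    non-overlapping and sorted."""

    sleep_intervals: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ivs = tuple((float(a), float(b)) for a, b in self.sleep_intervals)
        for a, b in ivs:
            if b <= a:
                raise ValueError(f"empty or inverted sleep interval ({a}, {b})")
        for (_, b0), (a1, _) in zip(ivs, ivs[1:]):
            if a1 < b0:
                raise ValueError("sleep intervals overlap")
        object.__setattr__(self, "sleep_intervals", ivs)

    def is_sleep(self, t: np.ndarray) -> np.ndarray:
        """Vectorized membership test: True where time ``t`` (seconds) falls
        inside a self-reported sleep window."""
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape, dtype=bool)
        for a, b in self.sleep_intervals:
            out |= (t >= a) & (t < b)
        return out

    def segment_labels(self, starts_s: np.ndarray, seg_len_s: float) -> np.ndarray:
        """Label each segment sleep/awake by membership of its midpoint."""
        mids = np.asarray(starts_s, dtype=float) + seg_len_s / 2.0
        return self.is_sleep(mids)

    @classmethod
    def from_json(cls, path) -> "AnnotationTrack":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(sleep_intervals=tuple(tuple(iv) for iv in obj["sleep"]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"sleep": [list(iv) for iv in self.sleep_intervals]}, fh)


def load_rr(path, dialect: str = "rr-only") -> BeatSeries:
    """Read an RR-interval file into a :class:`BeatSeries`.

    Parameters
    ----------
    path : path-like
        Plain-text file.  ``rr-only`` dialect: one RR interval (ms) per line,
        timestamps reconstructed as cumulative sums.  ``time-rr`` dialect:
        two whitespace-separated columns ``time_s  rr_ms``.
    """
    if dialect not in ("rr-only", "time-rr"):
        raise ParameterError(f"unknown dialect {dialect!r}")
    rr_vals, t_vals = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                if dialect == "rr-only":
                    (val,) = parts
                    rr_vals.append(float(val))
                else:
                    t_str, rr_str = parts
                    t_vals.append(float(t_str))
                    rr_vals.append(float(rr_str))
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: cannot parse {line!r}"
                ) from exc
    if not rr_vals:
        raise EmptyInputError(f"{path}: no RR values found")
    rr = np.asarray(rr_vals, dtype=float)
    if np.any(rr <= 0):
        bad = int(np.flatnonzero(rr <= 0)[0])
        raise ParseError(f"{path}: non-positive RR value at entry {bad + 1}")
    if dialect == "rr-only":
        t = np.cumsum(rr) / 1000.0
    else:
        t = np.asarray(t_vals, dtype=float)
    return BeatSeries(t=t, rr=rr)


def filter_hr(
    series: BeatSeries, lo: float = HR_LO, hi: float = HR_HI
) -> tuple[BeatSeries, float]:
    """Drop beats whose instantaneous HR lies outside ``[lo, hi]`` bpm.

    Timestamps of retained beats are unchanged — removal leaves gaps in the
    beat train which are closed later by :func:`resample_uniform`.

    Returns the filtered series and the removed fraction.
    """
    if not lo < hi:
        raise ParameterError(f"need lo < hi, got {lo} >= {hi}")
    hr = series.hr
    keep = (hr >= lo) & (hr <= hi)
    removed_fraction = 1.0 - keep.mean() if len(keep) else 0.0
    if len(keep) and not keep.any():
        raise DegenerateInputError("artifact filter removed every beat")
    return BeatSeries(t=series.t[keep], rr=series.rr[keep]), float(removed_fraction)


def resample_uniform(series: BeatSeries, fs: float = 2.0) -> UniformSeries:
    """Linearly interpolate instantaneous HR onto the grid ``t[0] + k/fs``.

    The grid covers ``[t[0], t[-1]]``; gaps between retained beats are
    bridged by the interpolation (warning when a gap exceeds 5 s).
    """
    if fs <= 0:
        raise ParameterError(f"sampling rate must be positive, got {fs}")
    if len(series) < 2:
        raise DegenerateInputError("need at least 2 beats to resample")
    gaps = np.diff(series.t)
    if gaps.max() > GAP_WARN_S:
        warnings.warn(
            f"largest inter-beat gap is {gaps.max():.1f} s; interpolation "
            "across it may be unreliable",
            stacklevel=2,
        )
    n = int(np.floor((series.t[-1] - series.t[0]) * fs)) + 1
    grid = series.t[0] + np.arange(n) / fs
    x = np.interp(grid, series.t, series.hr)
    return UniformSeries(fs=float(fs), x=x, t0=float(series.t[0]))


def hr_summary(
    series: BeatSeries, ann: AnnotationTrack
) -> tuple[float, float, float, float]:
    """Per-state heart-rate summary over the raw beats.

    Returns ``(mean_hr_sleep, mean_hr_awake, sd_sleep, sd_awake)`` in bpm;
    a state with no beats yields ``nan`` for its statistics.
    """
    sleep = ann.is_sleep(series.t)
    hr = series.hr

    def _stats(mask):
        if not mask.any():
            return float("nan"), float("nan")
        vals = hr[mask]
        return float(vals.mean()), float(vals.std())

    mean_s, sd_s = _stats(sleep)
    mean_a, sd_a = _stats(~sleep)
    return mean_s, mean_a, sd_s, sd_a


def save_uniform(series: UniformSeries, path) -> None:
    """Write a :class:`UniformSeries` to an ``.npz`` container (lossless)."""
    np.savez(path, fs=series.fs, x=series.x, t0=series.t0)


def load_uniform(path) -> UniformSeries:
    with np.load(path) as z:
        return UniformSeries(fs=float(z["fs"]), x=z["x"].copy(), t0=float(z["t0"]))


def preprocess_recording(
    rr_path,
    dialect: str = "rr-only",
    lo: float = HR_LO,
    hi: float = HR_HI,
    fs: float = 2.0,
) -> tuple[UniformSeries, float]:
    """Convenience: load, filter and resample in one call.

    Returns the uniform series and the artifact-removed fraction.
    """
    beats = load_rr(rr_path, dialect=dialect)
    beats, removed = filter_hr(beats, lo=lo, hi=hi)
    return resample_uniform(beats, fs=fs), removed
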