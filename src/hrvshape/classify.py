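"""Vigilance tracks, sleep-onset detection and cohort statistics.

The best shapelet's split labels every 2-min segment sleep or awake (a
binary consciousness track).  Averaging the votes of many randomly drawn
shapelets — random level, random start offset anywhere in the recording —
yields a continuous vigilance score between 0 (sleep) and 1 (awake).
The onset of sleep is operationalized as the start of the qualifying run of
at least five consecutive sleep segments (>= 10 min) nearest to the
self-reported lights-off time.  The separation statistic (difference of the
two class-mean distances from the best shapelet) quantifies how strongly a
subject's heart activity differs between states, and is regressed on age
separately per sex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal, stats

from .distance import DistanceVector, normalize, sliding_distances
from .exceptions import (
    DegenerateInputError,
    ParameterError,
    PipelineError,
)
from .preprocess import AnnotationTrack, UniformSeries, preprocess_recording
from .shapelets import Segment, pool_for_series, segmentize
from .split import SplitResult, best_shapelet, optimal_split

__all__ = [
    "ConsciousnessTrack",
    "OnsetEstimate",
    "SeparationStat",
    "classify_binary",
    "ensemble_score",
    "smooth_track",
    "detect_onset",
    "separation_statistic",
    "age_regression",
    "run_pipeline",
]

SEGMENT_LEN_S = 120.0
SHAPELET_LEVELS = (1, 2, 3)


@dataclass(frozen=True)
class ConsciousnessTrack:
    """Per-segment vigilance: 0 = sleep, 1 = awake.

    Binary tracks take values in {0, 1}; ensemble tracks are continuous
    scores in [0, 1] (the fraction of classifiers voting awake).
    """

    values: np.ndarray
    start_s: np.ndarray
    kind: str = "binary"  # "binary" | "continuous"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any((v < 0) | (v > 1)):
            raise ParameterError("track values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def is_sleep(self) -> np.ndarray:
        """Binary state with ties at the 0.5 threshold resolved to sleep
        (the safety-first reading for vigilance alarms)."""
        return self.values <= 0.5

    def binarize(self, threshold: float = 0.5) -> "ConsciousnessTrack":
        return ConsciousnessTrack(
            values=(self.values > threshold).astype(float),
            start_s=self.start_s,
            kind="binary",
        )

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class OnsetEstimate:
    """Estimated time of falling asleep (None when no qualifying run)."""

    onset_s: float | None
    self_reported_s: float
    delta_min: float | None  # signed estimated - self-reported, minutes

    @property
    def found(self) -> bool:
        return self.onset_s is not None


@dataclass(frozen=True)
class SeparationStat:
    """Separation between the two class peaks of the best shapelet's
    distance histogram — the discriminative power of a subject's heart
    activity for distinguishing sleep from awake."""

    value: float
    age: float | None = None
    sex: str | None = None


def classify_binary(
    dv: DistanceVector, split: SplitResult, start_s: np.ndarray | None = None
) -> ConsciousnessTrack:
    """Binary sleep/awake track from one shapelet's split: a segment is
    sleep iff its class's majority self-reported label is sleep."""
    sleep = split.sleep_class_mask
    if start_s is None:
        start_s = np.arange(len(dv)) * SEGMENT_LEN_S
    return ConsciousnessTrack(
        values=(~sleep).astype(float), start_s=np.asarray(start_s, float),
        kind="binary",
    )


def _draw_random_window(
    rng: np.random.Generator, u: UniformSeries, seg_samples: int
) -> np.ndarray:
    """A random shapelet: random level, random start offset anywhere in the
    recording (not restricted to the half-length grid), never extending
    past the recording end."""
    level = rng.integers(1, len(SHAPELET_LEVELS) + 1)
    length = seg_samples // 2**level
    start = rng.integers(0, len(u.x) - length + 1)
    return u.x[start : start + length]


def ensemble_score(
    u: UniformSeries,
    labels: np.ndarray,
    n: int = 50,
    rng: np.random.Generator | int | None = None,
    bin_frac: float = 0.01,
    segments: Sequence[Segment] | None = None,
) -> ConsciousnessTrack:
    """Continuous vigilance track averaged over ``n`` random shapelets.

    Each classifier is an independently drawn shapelet with its own optimal
    split; the per-segment score is the fraction of classifiers voting
    awake.  Reproducible for a given ``rng`` seed.
    """
    if n < 1:
        raise ParameterError(f"ensemble size must be >= 1, got {n}")
    rng = np.random.default_rng(rng)
    if segments is None:
        segments = segmentize(u)
    seg_samples = len(segments[0].samples)
    votes_awake = np.zeros(len(segments))
    drawn = 0
    attempts = 0
    while drawn < n:
        attempts += 1
        if attempts > 20 * n:
            raise DegenerateInputError(
                "could not draw enough shapelets admitting a split"
            )
        window = _draw_random_window(rng, u, seg_samples)
        dv = sliding_distances(window, segments)
        try:
            split = optimal_split(dv, labels, bin_frac=bin_frac)
        except DegenerateInputError:
            continue
        votes_awake += ~split.sleep_class_mask
        drawn += 1
    return ConsciousnessTrack(
        values=votes_awake / n,
        start_s=np.array([s.start_s for s in segments]),
        kind="continuous",
    )


def smooth_track(
    values: np.ndarray,
    order: int = 2,
    cutoff_s: float = 1800.0,
    sample_spacing_s: float = SEGMENT_LEN_S,
) -> np.ndarray:
    """Zero-phase low-pass Butterworth smoothing for display.

    Default order 2 with a 30-min cutoff on the per-segment track.  Never
    feeds classification; too-short inputs pass through with a warning.
    """
    x = np.asarray(values, dtype=float)
    wn = 2.0 * sample_spacing_s / cutoff_s
    b, a = signal.butter(order, min(wn, 0.99))
    padlen = 3 * max(len(a), len(b))
    if len(x) <= max(order, padlen):
        warnings.warn(
            f"track of length {len(x)} too short to smooth; returning input",
            stacklevel=2,
        )
        return x.copy()
    return signal.filtfilt(b, a, x)


def detect_onset(
    track: ConsciousnessTrack,
    self_reported_s: float,
    min_run: int = 5,
    threshold: float = 0.5,
) -> OnsetEstimate:
    """Start of the qualifying sleep run nearest the self-reported time.

    A qualifying run is >= ``min_run`` consecutive sleep segments
    (>= 10 min at the defaults).  Continuous tracks are thresholded first
    (score <= ``threshold`` counts as sleep).  Among qualifying runs the
    one whose start is nearest in time to ``self_reported_s`` wins; an
    exact tie resolves to the earlier run.  Returns an explicit no-onset
    result when no run qualifies.
    """
    if min_run < 1:
        raise ParameterError("min_run must be >= 1")
    sleep = track.values <= threshold
    starts = []
    i = 0
    n = len(sleep)
    while i < n:
        if sleep[i]:
            j = i
            while j < n and sleep[j]:
                j += 1
            if j - i >= min_run:
                starts.append(track.start_s[i])
            i = j
        else:
            i += 1
    if not starts:
        return OnsetEstimate(None, float(self_reported_s), None)
    starts = np.asarray(starts, dtype=float)
    dist = np.abs(starts - self_reported_s)
    onset = float(starts[int(np.argmin(dist))])  # argmin takes earliest tie
    return OnsetEstimate(
        onset_s=onset,
        self_reported_s=float(self_reported_s),
        delta_min=(onset - self_reported_s) / 60.0,
    )


def separation_statistic(
    dv: DistanceVector,
    split: SplitResult,
    age: float | None = None,
    sex: str | None = None,
) -> SeparationStat:
    """Separation between the two peaks of the best shapelet's distance
    histogram: mean delta of the far class (B, above the threshold) minus
    the near class (A, which holds the shapelet's own zero-distance
    segment), hence non-negative.  When the best shapelet is a sleep
    pattern this equals the awake-majority minus sleep-majority class
    means.  Undefined (NaN) when either class is empty."""
    a = split.class_a
    if not a.any() or a.all():
        return SeparationStat(value=float("nan"), age=age, sex=sex)
    value = float(dv.delta[~a].mean() - dv.delta[a].mean())
    return SeparationStat(value=value, age=age, sex=sex)


def age_regression(stats_list: Sequence[SeparationStat]) -> dict:
    """Ordinary least squares of the separation statistic on age,
    stratified by sex.  Returns per-sex dicts with slope, intercept, r2,
    p-value and n."""
    out = {}
    for sex in sorted({s.sex for s in stats_list if s.sex is not None}):
        pts = [
            s for s in stats_list
            if s.sex == sex and s.age is not None and np.isfinite(s.value)
        ]
        if len(pts) < 3:
            raise ParameterError(
                f"need >= 3 subjects for sex {sex!r}, got {len(pts)}"
            )
        ages = np.array([s.age for s in pts], float)
        vals = np.array([s.value for s in pts], float)
        fit = stats.linregress(ages, vals)
        out[sex] = {
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "r2": float(fit.rvalue**2),
            "p": float(fit.pvalue),
            "n": len(pts),
        }
    return out


def run_pipeline(rr_path, ann_path, config: dict | None = None) -> dict:
    """End-to-end analysis of one recording: preprocess, segment, find the
    best shapelet, classify, score the ensemble, detect onset and compute
    the separation statistic.  Returns a JSON-serializable report."""
    cfg = {
        "fs": 2.0,
        "lo": 40.0,
        "hi": 180.0,
        "bin_frac": 0.01,
        "sampler": 200,
        "ensemble_n": 50,
        "min_run": 5,
        "threshold": 0.5,
        "seed": 0,
    }
    cfg.update(config or {})
    rng = np.random.default_rng(cfg["seed"])

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    u, removed = _stage(
        "preprocess", preprocess_recording, rr_path,
        lo=cfg["lo"], hi=cfg["hi"], fs=cfg["fs"],
    )
    ann = _stage("annotation", AnnotationTrack.from_json, ann_path)
    if not ann.sleep_intervals:
        raise PipelineError(
            "stage 'annotation' failed: no self-reported sleep interval; "
            "the split search requires both labels"
        )
    un = _stage("normalize", normalize, u)
    segments = _stage("segmentize", segmentize, un)
    starts = np.array([s.start_s for s in segments])
    labels = ann.segment_labels(starts, SEGMENT_LEN_S)
    pool = pool_for_series(segments)
    best = _stage(
        "best_shapelet", best_shapelet, pool, segments, labels,
        bin_frac=cfg["bin_frac"], sampler=cfg["sampler"], rng=rng,
    )
    track = classify_binary(best.dv, best.split, start_s=starts)
    ens = _stage(
        "ensemble", ensemble_score, un, labels,
        n=cfg["ensemble_n"], rng=rng, bin_frac=cfg["bin_frac"],
        segments=segments,
    )
    onset = detect_onset(
        ens, ann.sleep_intervals[0][0],
        min_run=cfg["min_run"], threshold=cfg["threshold"],
    )
    sep = separation_statistic(best.dv, best.split)
    agreement_selfreport = float((track.is_sleep == labels).mean())
    sh = best.shapelet
    return {
        "config": cfg,
        "n_segments": len(segments),
        "removed_fraction": removed,
        "best_shapelet": {
            "id": sh.shapelet_id,
            "segment": sh.parent,
            "level": sh.spec.level,
            "set": sh.spec.set,
            "position": sh.spec.position,
            "start_s": sh.start_s,
            "length_s": len(sh.samples) / cfg["fs"],
        },
        "split": {
            "threshold": best.split.threshold,
            "ig_bits": best.split.ig,
            "majority_map": best.split.majority_map,
            "n_sleep": best.split.n_sleep,
            "n_awake": best.split.n_awake,
        },
        "agreement_with_selfreport": agreement_selfreport,
        "onset": {
            "onset_s": onset.onset_s,
            "self_reported_s": onset.self_reported_s,
            "delta_min": onset.delta_min,
        },
        "separation": sep.value,
        "binary_track": track.values.tolist(),
        "ensemble_track": ens.values.tolist(),
        "segment_start_s": starts.tolist(),
    }
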