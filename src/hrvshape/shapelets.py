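"""Segmentation and the three-level shapelet pool.

The uniform heart-rate series is cut into non-overlapping 2-min segments,
the unit of classification.  Each segment is then decomposed into a pool of
shapelets at three dyadic levels — halves (60 s), quarters (30 s) and
eighths (15 s) — plus, at every level, an additional set shifted by half a
shapelet length so that patterns straddling the main tile boundaries are
still represented.  Per segment this yields 2+1, 4+3 and 8+7 shapelets at
levels 1-3, i.e. 25 in total.  A level-3 shapelet (15 s) spans roughly 3-4
respiration cycles of ~4 s, the time scale of respiratory sinus arrhythmia.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .exceptions import DegenerateInputError, ParameterError
from .preprocess import UniformSeries

__all__ = [
    "Segment",
    "Shapelet",
    "ShapeletSpec",
    "DEFAULT_SELECTOR",
    "segmentize",
    "build_pool",
    "pool_for_series",
    "select_shapelet",
    "pool_counts",
]

SEGMENT_LEN_S = 120.0
DEFAULT_LEVELS = (1, 2, 3)


@dataclass(frozen=True)
class Segment:
    """A 2-min chunk of the uniform series."""

    index: int
    start_s: float
    samples: np.ndarray
    fs: float

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class ShapeletSpec:
    """Address of a shapelet within its segment: dyadic level, main or
    half-shifted set, and 1-based position within the set."""

    level: int
    set: str  # "main" | "shifted"
    position: int

    def __post_init__(self) -> None:
        if self.set not in ("main", "shifted"):
            raise ParameterError(f"set must be 'main' or 'shifted', got {self.set!r}")
        if self.level < 1:
            raise ParameterError(f"level must be >= 1, got {self.level}")
        n = 2**self.level if self.set == "main" else 2**self.level - 1
        if not 1 <= self.position <= n:
            raise IndexError(
                f"position {self.position} out of range 1..{n} for "
                f"level {self.level} {self.set} set"
            )


#: the canonical single-shapelet choice: last main quarter of each segment
DEFAULT_SELECTOR = ShapeletSpec(level=2, set="main", position=4)


@dataclass(frozen=True)
class Shapelet:
    """A short sub-window of a segment, used as a pattern template."""

    parent: int
    spec: ShapeletSpec
    samples: np.ndarray
    start_s: float  # absolute start time in seconds

    @property
    def level(self) -> int:
        return self.spec.level

    @property
    def shapelet_id(self) -> str:
        s = self.spec
        return f"seg{self.parent}:L{s.level}:{s.set}:{s.position}"

    def __len__(self) -> int:
        return len(self.samples)


def segmentize(
    u: UniformSeries, seg_len_s: float = SEGMENT_LEN_S
) -> list[Segment]:
    """Tile the recording with non-overlapping ``seg_len_s`` windows.

    Segment ``i`` covers ``[i*seg_len_s, (i+1)*seg_len_s)`` relative to the
    series start; a trailing partial window is dropped.
    """
    if seg_len_s <= 0:
        raise ParameterError("segment length must be positive")
    samples_per_seg = int(round(seg_len_s * u.fs))
    if len(u.x) < samples_per_seg:
        raise DegenerateInputError(
            f"recording ({len(u.x)/u.fs:.0f} s) is shorter than one "
            f"segment ({seg_len_s:.0f} s)"
        )
    n_seg = len(u.x) // samples_per_seg
    return [
        Segment(
            index=i,
            start_s=u.t0 + i * seg_len_s,
            samples=u.x[i * samples_per_seg : (i + 1) * samples_per_seg],
            fs=u.fs,
        )
        for i in range(n_seg)
    ]


def _window(seg: Segment, spec: ShapeletSpec) -> tuple[np.ndarray, float]:
    """Sample window and absolute start time for a spec within a segment."""
    n = len(seg.samples)
    length = n // 2**spec.level
    half = length // 2
    if spec.set == "main":
        start = (spec.position - 1) * length
    else:
        start = (spec.position - 1) * length + half
    return seg.samples[start : start + length], seg.start_s + start / seg.fs


def select_shapelet(seg: Segment, spec: ShapeletSpec = DEFAULT_SELECTOR) -> Shapelet:
    """Extract the shapelet addressed by ``spec`` from a segment.

    The default is the last main quarter (level 2), covering the final 30 s
    of the segment.
    """
    if len(seg.samples) % 2**spec.level:
        raise ParameterError(
            f"segment sample count {len(seg.samples)} is not divisible by "
            f"2^{spec.level}"
        )
    samples, start_s = _window(seg, spec)
    return Shapelet(parent=seg.index, spec=spec, samples=samples, start_s=start_s)


def build_pool(
    seg: Segment, levels: Sequence[int] = DEFAULT_LEVELS
) -> list[Shapelet]:
    """All main and half-shifted shapelets of a segment.

    With the default levels (1, 2, 3) this yields 25 shapelets:
    2+1 at level 1, 4+3 at level 2, 8+7 at level 3.  Ordering is
    level-minor, main set before shifted, position ascending.
    """
    max_level = max(levels)
    if len(seg.samples) % 2**max_level:
        raise ParameterError(
            f"segment sample count {len(seg.samples)} must be divisible by "
            f"2^{max_level}; choose fs so that 120*fs is a multiple of "
            f"{2**max_level}"
        )
    out = []
    for level in levels:
        for set_ in ("main", "shifted"):
            n = 2**level if set_ == "main" else 2**level - 1
            for pos in range(1, n + 1):
                out.append(
                    select_shapelet(seg, ShapeletSpec(level, set_, pos))
                )
    return out


def pool_for_series(
    segments: Iterable[Segment], levels: Sequence[int] = DEFAULT_LEVELS
) -> Iterator[Shapelet]:
    """Enumerate the full pool across segments in a stable order:
    segment-major, then level, main before shifted, position ascending."""
    segments = list(segments)
    if not segments:
        raise DegenerateInputError("no segments")
    for seg in segments:
        yield from build_pool(seg, levels=levels)


def pool_counts(levels: Sequence[int] = DEFAULT_LEVELS) -> dict[int, tuple[int, int]]:
    """(main, shifted) shapelet counts per level; sums to 25 for levels 1-3."""
    return {lv: (2**lv, 2**lv - 1) for lv in levels}
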