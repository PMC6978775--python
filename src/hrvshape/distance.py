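"""Shapelet-to-segment distances.

Two windows of equal length are compared with the squared Euclidean
distance D (sum of squared pointwise differences, no square root and no
length normalization — short shapelets therefore find small distances more
easily, a property the classification relies on rather than corrects).
The shapelet-to-segment distance delta slides the shapelet along the
segment one sample at a time and keeps the minimum D over all alignments;
ties go to the earliest offset.

Heart rate is min-max normalized to [0, 1] over the whole recording before
any distance is computed, so distances are invariant under positive affine
transforms of raw HR and comparable across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ContractError, DegenerateInputError
from .preprocess import UniformSeries
from .shapelets import (
    DEFAULT_SELECTOR,
    Segment,
    Shapelet,
    ShapeletSpec,
    select_shapelet,
)

__all__ = [
    "DistanceVector",
    "DistanceMatrix",
    "normalize",
    "distance_D",
    "delta",
    "distance_vector",
    "sliding_distances",
    "distance_matrix",
]


@dataclass(frozen=True)
class DistanceVector:
    """delta from one shapelet to every segment, with best-match offsets."""

    shapelet_id: str
    delta: np.ndarray  # per-segment minimal distance
    offset: np.ndarray  # per-segment best-match start index

    def __len__(self) -> int:
        return len(self.delta)


@dataclass(frozen=True)
class DistanceMatrix:
    """All-to-all segment distances via an equivalently positioned shapelet
    per row.  ``M[i, j]`` is the distance from segment *i*'s shapelet to
    segment *j*; the matrix is not exactly symmetric, and downstream
    consumers use the symmetrized form ``(M + M.T)/2``."""

    M: np.ndarray
    selector: ShapeletSpec

    @property
    def n(self) -> int:
        return self.M.shape[0]

    @property
    def symmetric(self) -> np.ndarray:
        return (self.M + self.M.T) / 2.0

    @property
    def asymmetry(self) -> float:
        """max |M - M.T| / max(M); near zero in practice."""
        mx = self.M.max()
        if mx == 0:
            return 0.0
        return float(np.abs(self.M - self.M.T).max() / mx)


def normalize(u: UniformSeries) -> UniformSeries:
    """Global per-recording min-max scaling of HR to [0, 1].

    One affine map for the whole recording, never per segment, so relative
    amplitudes between segments are preserved.
    """
    lo, hi = float(u.x.min()), float(u.x.max())
    if hi <= lo:
        raise DegenerateInputError("constant recording cannot be normalized")
    return UniformSeries(fs=u.fs, x=(u.x - lo) / (hi - lo), t0=u.t0)


def distance_D(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Euclidean distance between equal-length windows:
    ``sum((a - b)**2)``.  Zero iff the windows are identical."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise ContractError(
            f"windows must be 1-D and of equal length, got {a.shape} vs {b.shape}"
        )
    d = a - b
    return float(d @ d)


def _as_samples(obj) -> np.ndarray:
    if isinstance(obj, (Shapelet, Segment)):
        return obj.samples
    return np.asarray(obj, dtype=float)


def delta(S, T, stride: int = 1) -> tuple[float, int]:
    """Minimal sliding distance from shapelet ``S`` to segment ``T``.

    ``S`` is shifted along ``T`` one sample at a time (or ``stride`` samples
    in the approximate mode); at each alignment D is measured and the
    minimum kept.  Returns ``(delta, offset)`` with ties broken toward the
    smallest offset.
    """
    s = _as_samples(S)
    t = _as_samples(T)
    if len(s) > len(t):
        raise ContractError(
            f"shapelet (len {len(s)}) longer than segment (len {len(t)})"
        )
    d = _sliding_ssd(t[None, :], s)[0, ::stride]
    k = int(np.argmin(d))
    return float(d[k]), k * stride


def _sliding_ssd(X: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Sum-of-squared-differences of ``s`` against every length-|s| window
    of each row of ``X``; returns shape (n_rows, n_positions).

    Uses the expansion ||w - s||^2 = ||w||^2 - 2 w.s + ||s||^2 with a
    sliding-window view, then clips tiny negative round-off to zero.
    """
    L = len(s)
    W = np.lib.stride_tricks.sliding_window_view(X, L, axis=1)
    dots = np.einsum("ijk,k->ij", W, s)
    sq = np.cumsum(np.concatenate([np.zeros((X.shape[0], 1)), X**2], axis=1), axis=1)
    wnorm = sq[:, L:] - sq[:, :-L]
    out = wnorm - 2.0 * dots + float(s @ s)
    np.maximum(out, 0.0, out=out)
    return out


def distance_vector(S: Shapelet, segments: Sequence[Segment]) -> DistanceVector:
    """delta from one shapelet to all segments, order-aligned with
    segment index.  The entry for the shapelet's own parent segment is
    exactly zero (it matches itself at its extraction point)."""
    segs = list(segments)
    X = np.stack([seg.samples for seg in segs])
    d = _sliding_ssd(X, np.asarray(S.samples, dtype=float))
    off = np.argmin(d, axis=1)
    return DistanceVector(
        shapelet_id=S.shapelet_id,
        delta=d[np.arange(len(segs)), off],
        offset=off,
    )


def sliding_distances(samples: np.ndarray, segments: Sequence[Segment]) -> DistanceVector:
    """Like :func:`distance_vector` but for a raw sample window that need
    not sit on the shapelet grid (used by the random-shapelet ensemble)."""
    X = np.stack([seg.samples for seg in segments])
    d = _sliding_ssd(X, np.asarray(samples, dtype=float))
    off = np.argmin(d, axis=1)
    return DistanceVector(
        shapelet_id="adhoc",
        delta=d[np.arange(X.shape[0]), off],
        offset=off,
    )


def distance_matrix(
    segments: Sequence[Segment], selector: ShapeletSpec = DEFAULT_SELECTOR
) -> DistanceMatrix:
    """All-to-all distance matrix: row *i* holds the distances from segment
    *i*'s selector shapelet (default: last main quarter of level 2) to all
    segments.  The diagonal is identically zero."""
    segs = list(segments)
    if len(segs) < 2:
        raise DegenerateInputError("need at least 2 segments for a matrix")
    X = np.stack([seg.samples for seg in segs])
    rows = []
    for seg in segs:
        s = select_shapelet(seg, selector).samples
        rows.append(_sliding_ssd(X, np.asarray(s, dtype=float)).min(axis=1))
    M = np.stack(rows)
    np.fill_diagonal(M, 0.0)
    return DistanceMatrix(M=M, selector=selector)
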