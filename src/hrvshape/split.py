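"""Information-gain split-point search.

The distances from one shapelet to every segment form a histogram that is
typically bimodal: one peak of segments similar to the shapelet (same
vigilance state) and one of dissimilar segments.  A split point — a distance
threshold laid between two histogram bins — divides segments into class A
(delta below the threshold) and class B.  Each class is assigned the
majority of its members' self-reported labels, and the split is scored by
information gain in bits:

    IG = E(labels) - n_awake/n_total * E_awake - n_sleep/n_total * E_sleep

where E is the binary entropy, E(labels) the entropy of the self-reported
sleep/awake proportions over all segments, and E_awake / E_sleep the
entropies of correctly- vs mis-classified members within the awake- and
sleep-majority classes.  The optimal split of a shapelet maximizes IG over
the tentative split points (interior histogram edges); the best shapelet is
the pool member whose optimal split attains the maximal IG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .distance import DistanceVector, distance_vector
from .exceptions import DegenerateInputError, ParameterError
from .shapelets import Segment, Shapelet

__all__ = [
    "DistanceHistogram",
    "SplitResult",
    "BestShapeletResult",
    "histogram",
    "entropy",
    "information_gain",
    "optimal_split",
    "best_shapelet",
    "bin_sensitivity",
]

DEFAULT_BIN_FRAC = 0.01


@dataclass(frozen=True)
class DistanceHistogram:
    edges: np.ndarray
    counts: np.ndarray
    bin_frac: float

    @property
    def split_candidates(self) -> np.ndarray:
        """Tentative split points: the interior bin edges."""
        return self.edges[1:-1]


@dataclass(frozen=True)
class SplitResult:
    """A distance threshold with its information gain and the induced
    two-class labeling of segments."""

    threshold: float
    ig: float
    class_a: np.ndarray  # True where delta < threshold
    #: majority self-reported label per class: {"A": "sleep"|"awake", "B": ...}
    majority_map: dict
    n_sleep: int  # size of the sleep-majority class
    n_awake: int  # size of the awake-majority class
    n_total: int
    degenerate: bool = False  # both classes share one majority label

    @property
    def sleep_class_mask(self) -> np.ndarray:
        """True for segments in the sleep-majority class."""
        return self.class_a if self.majority_map["A"] == "sleep" else ~self.class_a


@dataclass(frozen=True)
class BestShapeletResult:
    shapelet: Shapelet
    split: SplitResult
    dv: DistanceVector
    ig_rank: int = 1


def histogram(
    dv: DistanceVector | np.ndarray, bin_frac: float = DEFAULT_BIN_FRAC
) -> DistanceHistogram:
    """Histogram of one shapelet's distances with bins of width
    ``bin_frac * (max - min)`` covering [min, max]."""
    d = dv.delta if isinstance(dv, DistanceVector) else np.asarray(dv, float)
    lo, hi = float(d.min()), float(d.max())
    if hi <= lo:
        raise DegenerateInputError("all distances identical; no split possible")
    if not 0 < bin_frac <= 1:
        raise ParameterError(f"bin_frac must be in (0, 1], got {bin_frac}")
    n_bins = max(int(round(1.0 / bin_frac)), 2)
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    return DistanceHistogram(edges=edges, counts=counts, bin_frac=bin_frac)


def entropy(pA: float) -> float:
    """Binary entropy in bits; 0*log2(0) is taken as 0."""
    if not 0.0 <= pA <= 1.0:
        raise ParameterError(f"proportion must lie in [0, 1], got {pA}")
    pB = 1.0 - pA
    e = 0.0
    if pA > 0:
        e -= pA * math.log2(pA)
    if pB > 0:
        e -= pB * math.log2(pB)
    return e


def _labels_array(labels, n: int) -> np.ndarray:
    """Coerce labels to a boolean is_sleep array of length n."""
    arr = np.asarray(labels)
    if arr.dtype != bool:
        arr = arr.astype(bool)
    if len(arr) != n:
        raise ParameterError(
            f"labels cover {len(arr)} segments but distances cover {n}"
        )
    return arr


def information_gain(
    dv: DistanceVector | np.ndarray,
    labels: np.ndarray,
    threshold: float,
    variant: str = "majority-class",
) -> SplitResult:
    """Score one tentative split point against the self-reported labels.

    Class A holds segments with ``delta < threshold``, class B the rest.
    ``variant="majority-class"`` (default) computes the after-split
    entropies over correctly- vs mis-classified members within each
    majority class; ``variant="self-report"`` computes them within the
    self-reported sleep and awake stages instead.
    """
    d = dv.delta if isinstance(dv, DistanceVector) else np.asarray(dv, float)
    is_sleep = _labels_array(labels, len(d))
    if is_sleep.all() or not is_sleep.any():
        raise DegenerateInputError(
            "self-report labels are all one state; information gain is undefined"
        )
    n_total = len(d)
    class_a = d < threshold

    e_before = entropy(is_sleep.mean())

    def _majority(mask: np.ndarray) -> str:
        if not mask.any():
            return "empty"
        return "sleep" if is_sleep[mask].mean() >= 0.5 else "awake"

    maj_a, maj_b = _majority(class_a), _majority(~class_a)
    majority_map = {"A": maj_a, "B": maj_b}
    degenerate = maj_a == maj_b and maj_a != "empty"

    # identify the sleep-majority and awake-majority classes
    masks = {"A": class_a, "B": ~class_a}
    sleep_mask = np.zeros(n_total, bool)
    awake_mask = np.zeros(n_total, bool)
    for key, maj in majority_map.items():
        if maj == "sleep":
            sleep_mask |= masks[key]
        elif maj == "awake":
            awake_mask |= masks[key]

    if variant == "majority-class":
        # entropy of correct vs misclassified within each majority class
        def _class_entropy(mask, want_sleep):
            if not mask.any():
                return 0.0, 0
            frac_correct = (is_sleep[mask] == want_sleep).mean()
            return entropy(frac_correct), int(mask.sum())

        e_sleep, n_sleep = _class_entropy(sleep_mask, True)
        e_awake, n_awake = _class_entropy(awake_mask, False)
    elif variant == "self-report":
        # entropy of correct vs misclassified within each self-reported stage
        def _stage_entropy(stage_mask, correct_mask):
            if not stage_mask.any():
                return 0.0, 0
            frac = correct_mask[stage_mask].mean()
            return entropy(frac), int(stage_mask.sum())

        e_sleep, n_sleep = _stage_entropy(is_sleep, sleep_mask)
        e_awake, n_awake = _stage_entropy(~is_sleep, awake_mask)
    else:
        raise ParameterError(f"unknown variant {variant!r}")

    ig = e_before - n_awake / n_total * e_awake - n_sleep / n_total * e_sleep
    return SplitResult(
        threshold=float(threshold),
        ig=float(ig),
        class_a=class_a,
        majority_map=majority_map,
        n_sleep=n_sleep,
        n_awake=n_awake,
        n_total=n_total,
        degenerate=degenerate,
    )


def optimal_split(
    dv: DistanceVector | np.ndarray,
    labels: np.ndarray,
    bin_frac: float = DEFAULT_BIN_FRAC,
    variant: str = "majority-class",
    dense_scan: bool = False,
) -> SplitResult:
    """Maximal-IG split point for one shapelet's distance vector.

    Tentative split points are the interior histogram edges (or, with
    ``dense_scan``, every midpoint between consecutive sorted distances).
    Ties are broken toward the smallest threshold.
    """
    d = dv.delta if isinstance(dv, DistanceVector) else np.asarray(dv, float)
    if dense_scan:
        u = np.unique(d)
        candidates = (u[:-1] + u[1:]) / 2.0
    else:
        candidates = histogram(dv, bin_frac=bin_frac).split_candidates
    best = None
    for thr in candidates:
        res = information_gain(d, labels, thr, variant=variant)
        if best is None or res.ig > best.ig + 1e-12:
            best = res
    if best is None:
        raise DegenerateInputError("no tentative split points")
    return best


def best_shapelet(
    pool: Iterable[Shapelet],
    segments: Sequence[Segment],
    labels: np.ndarray,
    bin_frac: float = DEFAULT_BIN_FRAC,
    sampler: str | int = "all",
    rng: np.random.Generator | int | None = None,
    variant: str = "majority-class",
) -> BestShapeletResult:
    """The pool member whose optimal split attains the maximal IG.

    ``sampler="all"`` scans every candidate; an integer k draws k pool
    members uniformly without replacement (the practical mode for a full
    24-h pool of ~18 000 shapelets).  Ties keep the earlier pool member
    (earlier segment, lower level first, main before shifted, lower
    position), i.e. the first maximum in enumeration order.
    """
    candidates = list(pool)
    if not candidates:
        raise DegenerateInputError("empty shapelet pool")
    if sampler != "all":
        k = int(sampler)
        if k < 1:
            raise ParameterError("sampler k must be >= 1")
        rng = np.random.default_rng(rng)
        if k < len(candidates):
            idx = rng.choice(len(candidates), size=k, replace=False)
            candidates = [candidates[i] for i in np.sort(idx)]
    def _tie_key(sh: Shapelet):
        # earlier segment, higher level, main before shifted, lower position
        return (sh.parent, -sh.spec.level, sh.spec.set != "main", sh.spec.position)

    best: BestShapeletResult | None = None
    for sh in candidates:
        dv = distance_vector(sh, segments)
        try:
            split = optimal_split(dv, labels, bin_frac=bin_frac, variant=variant)
        except DegenerateInputError:
            continue
        if (
            best is None
            or split.ig > best.split.ig + 1e-12
            or (
                abs(split.ig - best.split.ig) <= 1e-12
                and _tie_key(sh) < _tie_key(best.shapelet)
            )
        ):
            best = BestShapeletResult(shapelet=sh, split=split, dv=dv)
    if best is None:
        raise DegenerateInputError("no candidate shapelet admitted a split")
    return best


def bin_sensitivity(
    dv: DistanceVector | np.ndarray,
    labels: np.ndarray,
    fracs: Sequence[float] = (0.01, 0.02, 0.03, 0.1, 0.2, 0.3),
    fine_coarse_boundary: float = 0.05,
) -> tuple[list[tuple[float, float, float]], float, float]:
    """Robustness of the optimal threshold to histogram bin size.

    Returns ``(table, levene_W, levene_p)`` where the table rows are
    ``(bin_frac, threshold, ig)`` and the Levene statistic compares the
    variance of thresholds between the fine (< boundary) and coarse bin
    groups.  A large p-value indicates bin size plays little role.
    """
    table = []
    for frac in fracs:
        res = optimal_split(dv, labels, bin_frac=frac)
        table.append((float(frac), res.threshold, res.ig))
    fine = [thr for frac, thr, _ in table if frac < fine_coarse_boundary]
    coarse = [thr for frac, thr, _ in table if frac >= fine_coarse_boundary]
    if len(fine) < 2 or len(coarse) < 2:
        return table, float("nan"), float("nan")
    if np.var(fine) == 0 and np.var(coarse) == 0:
        return table, 0.0, 1.0  # identical thresholds everywhere
    w, p = stats.levene(fine, coarse)
    return table, float(w), float(p)
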