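"""Plot helpers: distance-matrix heat map and vigilance-track overlays.

Dark cells in the heat map mean small distance (similar heart activity);
track plots overlay the classified state on the self-reported windows.
"""

from __future__ import annotations

import numpy as np

from .classify import ConsciousnessTrack, smooth_track
from .distance import DistanceMatrix
from .preprocess import AnnotationTrack


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_distance_matrix(dm: DistanceMatrix, path, title: str = "") -> None:
    """Heat map of the symmetrized all-to-all segment distances."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(6, 5))
    n = dm.n
    hours = n * 2.0 / 60.0
    im = ax.imshow(
        dm.symmetric, origin="lower", cmap="viridis",
        extent=(0, hours, 0, hours),
    )
    ax.set_xlabel("time (h)")
    ax.set_ylabel("time (h)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="distance (dark = similar)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_track(
    track: ConsciousnessTrack,
    path,
    annotation: AnnotationTrack | None = None,
    distances: np.ndarray | None = None,
    title: str = "",
) -> None:
    """Vigilance track over time with the self-report overlay; optionally
    the raw best-shapelet distances with their Butterworth smoothing."""
    plt = _mpl()
    n_rows = 2 if distances is not None else 1
    fig, axes = plt.subplots(n_rows, 1, figsize=(8, 3 * n_rows), squeeze=False)
    hours = track.start_s / 3600.0
    ax = axes[0][0]
    ax.plot(hours, track.values, "r-", lw=1, label="classified (1=awake)")
    if annotation is not None:
        for a, b in annotation.sleep_intervals:
            ax.axvspan(a / 3600.0, b / 3600.0, color="green", alpha=0.15)
        ax.plot([], [], color="green", alpha=0.4, lw=6, label="self-reported sleep")
    ax.set_ylabel("consciousness")
    ax.set_ylim(-0.05, 1.05)
    ax.legend(loc="center right", fontsize=8)
    if title:
        ax.set_title(title)
    if distances is not None:
        ax2 = axes[1][0]
        ax2.plot(hours, distances, "b-", lw=0.8, label="distance from best shapelet")
        ax2.plot(hours, smooth_track(distances), "k-", lw=1.5, label="smoothed")
        ax2.set_ylabel("distance")
        ax2.legend(fontsize=8)
    axes[-1][0].set_xlabel("time (h)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
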