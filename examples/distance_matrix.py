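"""All-to-all segment distance matrix of a synthetic recording.

Every 2-min segment contributes one row: the sliding distances from its
last level-2 quarter (the 30-s window ending the segment) to all other
segments.  Sleep segments resemble each other, so the matrix shows a dark
sleep block against brighter awake regions.
"""

import numpy as np

import hrvshape as hs

cfg = hs.SynthConfig(
    duration_h=6.0,
    schedule=(("awake", 0.0, 4 * 3600.0), ("sleep", 4 * 3600.0, 6 * 3600.0)),
)
beats, annotation, truth = hs.generate_recording(cfg, rng=3)
uniform = hs.normalize(hs.resample_uniform(hs.filter_hr(beats)[0]))
segments = hs.segmentize(uniform)

dm = hs.distance_matrix(segments)  # default selector: level 2, main, pos 4
starts = np.array([s.start_s for s in segments])
asleep = truth.segment_labels(starts)

S = dm.symmetric
within = np.concatenate([S[np.ix_(asleep, asleep)].ravel(),
                         S[np.ix_(~asleep, ~asleep)].ravel()])
between = S[np.ix_(asleep, ~asleep)].ravel()
print(f"{dm.n} x {dm.n} matrix, asymmetry {dm.asymmetry:.3f} (symmetrized)")
print(f"mean within-state distance : {within.mean():6.2f}")
print(f"mean between-state distance: {between.mean():6.2f}")

# Between-state distances dominate within-state ones; that contrast is the
# raw material for the split-point search.  To render the heat map:
#   from hrvshape.viz import plot_distance_matrix
#   plot_distance_matrix(dm, "matrix.png")
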