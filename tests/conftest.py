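import numpy as np
import pytest

import hrvshape as hs


@pytest.fixture(scope="session")
def short_cfg():
    """2-h two-regime recording: 1 h awake then 1 h sleep, slight
    self-report offset, no naps."""
    return hs.SynthConfig(
        duration_h=2.0,
        schedule=(("awake", 0.0, 3600.0), ("sleep", 3600.0, 7200.0)),
        annotation_offset_min=-4.0,
        artifact_rate=0.0,
    )


@pytest.fixture(scope="session")
def short_recording(short_cfg):
    return hs.generate_recording(short_cfg, rng=42)


@pytest.fixture(scope="session")
def short_segments(short_recording):
    """Preprocessed and segmented short recording plus labels and truth."""
    beats, ann, truth = short_recording
    filtered, _ = hs.filter_hr(beats)
    un = hs.normalize(hs.resample_uniform(filtered))
    segs = hs.segmentize(un)
    starts = np.array([s.start_s for s in segs])
    labels = ann.segment_labels(starts, 120.0)
    gt = truth.segment_labels(starts)
    return {
        "uniform": un,
        "segments": segs,
        "starts": starts,
        "labels": labels,
        "truth": gt,
        "annotation": ann,
        "ground_truth": truth,
    }


def brute_force_delta(s, t):
    """Independent oracle: exhaustive all-alignment sliding minimum of the
    sum of squared differences, written as explicit loops."""
    s = np.asarray(s, float)
    t = np.asarray(t, float)
    best = None
    best_off = 0
    for off in range(len(t) - len(s) + 1):
        d = 0.0
        for i in range(len(s)):
            d += (s[i] - t[off + i]) ** 2
        if best is None or d < best:
            best, best_off = d, off
    return best, best_off
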