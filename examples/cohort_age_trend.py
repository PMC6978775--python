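"""Recover an injected age trend from a synthetic cohort.

Male subjects are generated with a sleep/awake heart-rate contrast that
weakens with age (shallower nocturnal dip, smaller sleep RSA).  For each
subject the pipeline computes the separation statistic — the gap between
the two peaks of the best shapelet's distance histogram — which is then
regressed on age per sex.  Short 2.5-h recordings keep the example quick.
"""

import numpy as np

import hrvshape as hs

base = hs.SynthConfig(
    duration_h=2.5,
    schedule=(("awake", 0.0, 5400.0), ("sleep", 5400.0, 9000.0)),
    annotation_offset_min=-4.0,
)
subjects = hs.generate_cohort(
    n_subjects=14, rng=5, male_fraction=1.0, base_config=base
)

stats = []
for s in subjects:
    uniform = hs.normalize(hs.resample_uniform(hs.filter_hr(s.beats)[0]))
    segments = hs.segmentize(uniform)
    starts = np.array([x.start_s for x in segments])
    labels = s.annotation.segment_labels(starts, 120.0)
    best = hs.best_shapelet(
        hs.pool_for_series(segments), segments, labels, sampler=300, rng=s.seed
    )
    stat = hs.separation_statistic(best.dv, best.split, age=s.age, sex=s.sex)
    stats.append(stat)
    print(f"subject {s.subject_id:2d}  age {s.age:4.0f}  separation {stat.value:6.2f}")

fit = hs.age_regression(stats)["M"]
print(f"\nOLS separation ~ age (males): slope {fit['slope']:+.3f} per year, "
      f"R^2 {fit['r2']:.2f}, p {fit['p']:.3f}, n {fit['n']}")

# A negative slope recovers the injected decline: older male subjects'
# heart activity discriminates sleep from awake less sharply.
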