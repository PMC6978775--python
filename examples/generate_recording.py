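"""Generate a synthetic 24-h RR recording and inspect its preprocessing.

Builds a day with one nocturnal sleep block, a 20-min afternoon nap,
injected artifact beats and an offset self-report annotation, then runs
artifact filtering and per-state heart-rate summaries.
"""

import hrvshape as hs

cfg = hs.SynthConfig(duration_h=24.0)
beats, annotation, truth = hs.generate_recording(cfg, rng=1)
print(f"beats emitted over 24 h: {len(beats)}")

filtered, removed = hs.filter_hr(beats)
print(f"artifact filter removed {removed:.2%} of beats (40-180 bpm bounds)")

mean_sleep, mean_awake, sd_sleep, sd_awake = hs.hr_summary(beats, annotation)
print(f"mean HR asleep: {mean_sleep:5.1f} bpm (sd {sd_sleep:.1f})")
print(f"mean HR awake : {mean_awake:5.1f} bpm (sd {sd_awake:.1f})")

# The sleep mean sits ~20 bpm below the awake mean: the nocturnal dip the
# classifier exploits.  The removed fraction tracks the configured 0.63%
# artifact rate because clean beats never leave the plausible band.
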