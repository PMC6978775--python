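{
 "config": {
  "fs": 2.0,
  "lo": 40.0,
  "hi": 180.0,
  "bin_frac": 0.01,
  "sampler": 50,
  "ensemble_n": 10,
  "min_run": 5,
  "threshold": 0.5,
  "seed": 1
 },
 "n_segments": 59,
 "removed_fraction": 0.007059396299902598,
 "best_shapelet": {
  "id": "seg1:L3:main:5",
  "segment": 1,
  "level": 3,
  "set": "main",
  "position": 5,
  "start_s": 180.77911070599998,
  "length_s": 15.0
 },
 "split": {
  "threshold": 9.185324806475696,
  "ig_bits": 0.818459939357626,
  "majority_map": {
   "A": "awake",
   "B": "sleep"
  },
  "n_sleep": 28,
  "n_awake": 31
 },
 "agreement_with_selfreport": 0.9661016949152542,
 "onset": {
  "onset_s": 3600.779110706,
  "self_reported_s": 3360.0,
  "delta_min": 4.012985178433337
 },
 "separation": 10.23249743614956,
 "binary_track": [
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  1.0
 ],
 "ensemble_track": [
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.5
 ],
 "segment_start_s": [
  0.7791107060000001,
  120.779110706,
  240.779110706,
  360.779110706,
  480.779110706,
  600.779110706,
  720.779110706,
  840.779110706,
  960.779110706,
  1080.779110706,
  1200.779110706,
  1320.779110706,
  1440.779110706,
  1560.779110706,
  1680.779110706,
  1800.779110706,
  1920.779110706,
  2040.779110706,
  2160.779110706,
  2280.779110706,
  2400.779110706,
  2520.779110706,
  2640.779110706,
  2760.779110706,
  2880.779110706,
  3000.779110706,
  3120.779110706,
  3240.779110706,
  3360.779110706,
  3480.779110706,
  3600.779110706,
  3720.779110706,
  3840.779110706,
  3960.779110706,
  4080.779110706,
  4200.779110706,
  4320.779110706,
  4440.779110706,
  4560.779110706,
  4680.779110706,
  4800.779110706,
  4920.779110706,
  5040.779110706,
  5160.779110706,
  5280.779110706,
  5400.779110706,
  5520.779110706,
  5640.779110706,
  5760.779110706,
  5880.779110706,
  6000.779110706,
  6120.779110706,
  6240.779110706,
  6360.779110706,
  6480.779110706,
  6600.779110706,
  6720.779110706,
  6840.779110706,
  6960.779110706
 ]
}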