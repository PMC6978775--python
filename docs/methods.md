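# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `hrvshape`, and what the synthetic experiments do and do
not demonstrate.

## Signal model and preprocessing

The raw observation is a sequence of RR intervals in milliseconds.
Instantaneous heart rate is HR = 60000/RR; beats with HR outside
[40, 180] bpm are treated as artifacts and dropped (both bounds inclusive,
configurable). Timestamps of retained beats are kept, so removal leaves
gaps in the beat train.

Shapelet comparison slides one window along another *point by point*, which
requires a shared sample grid; beat trains are irregular. We therefore
linearly interpolate HR onto a uniform grid at **fs = 2 Hz** before
segmentation. 2 Hz keeps the 2-min segment at 240 samples (divisible by 8,
so all three shapelet levels tile exactly), resolves the ~0.25 Hz
respiratory modulation with margin, and keeps a full day at 172 800
samples. Gaps left by artifact removal are bridged by the same
interpolation; a warning is emitted when any gap exceeds 5 s, since a
linear bridge across a long gap is a guess. With realistic artifact rates
(~0.6%) such gaps are rare, which is why we interpolate rather than
exclude segments.

Amplitudes are min–max scaled to [0, 1] **once per recording** (never per
segment). This makes distances dimensionless, comparable across subjects,
and invariant under positive affine transforms of raw HR. A per-segment
scaling would destroy exactly the between-segment amplitude differences
(the nocturnal dip) that the classifier exploits. One consequence worth
knowing: the normalization range itself depends on the signal's extremes,
so changes that widen the range (e.g. stronger sleep RSA) shrink all
normalized distances — see "Separation statistic" below.

Time is measured in seconds from the first beat; intervals are half-open
[start, end). Segment boundaries inherit the grid origin t₀ = RR₀/1000.

## Segments and the shapelet pool

Segments are non-overlapping 2-min windows; a trailing partial window is
dropped (a 24-h recording yields exactly 720). Each segment's pool holds,
at levels 1–3, the 2/4/8 main tiles of 60/30/15 s plus 1/3/7 half-shifted
copies — 25 shapelets per segment. Deeper levels are supported
(`build_pool(levels=...)`) but default off: below 15 s a window no longer
spans the ~3–4 respiration cycles (~4 s each) that make a pattern
state-specific. The all-to-all distance matrix uses, per segment, the last
main quarter of level 2 (the final 30 s of the segment) as its
representative shapelet; "last main quarter" is our reading of the
half-ambiguous canonical choice and is configurable via `ShapeletSpec`.

## Distances

`distance_D` is the plain sum of squared pointwise differences — no square
root, no length normalization. Both omissions are deliberate: the method's
decision machinery only ever compares distances from the *same* shapelet,
where a monotone transform or a common length factor changes nothing, and
the length dependence (shorter shapelets find smaller minima) is treated
as a property, not a defect. A sqrt variant would only relabel the
histogram axis. `delta` is the minimum of D over all alignments of the
shapelet inside the segment, ties to the earliest offset. The sliding
search is computed with a vectorized window-norm expansion
(‖w‖² − 2w·s + ‖s‖²); tiny negative round-off is clipped to zero, so a
shapelet's distance to its own parent segment is 0 to ~1e−12. A `stride`
parameter coarsens the alignment grid for speed; stride 1 (exact) is the
default and the reference for every test.

The all-to-all matrix is asymmetric by construction (row *i* uses segment
*i*'s shapelet); downstream consumers receive the arithmetic-mean
symmetrization, and `DistanceMatrix.asymmetry` reports max|M−Mᵀ|/max M.

## Split points and information gain

Distances from one shapelet to all segments are binned into a histogram
covering [min, max] with bin width = `bin_frac` × range; tentative split
points are the interior edges. Default `bin_frac` = 0.01 (1% bins, 99
candidate thresholds); a `dense_scan` option tests every midpoint between
consecutive distinct distances instead. The threshold enters as
δ < threshold → class A.

The before-split entropy is that of the **self-reported label
proportions** over all segments, and the after-split terms are the
entropies of correctly- vs mis-classified members within the awake- and
sleep-majority classes, weighted by class size. This is the standard
decision-stump information gain; it guarantees 0 ≤ IG ≤ E(labels) with
equality exactly at a perfect split, and IG = 0 when a class is empty.
An alternative reading — computing the after-split entropies within the
self-reported stages rather than within the induced classes — is
implemented behind `variant="self-report"`; on perfect splits the two
coincide. All-sleep or all-awake label tracks raise an error rather than
silently returning IG = 0. Ties among thresholds resolve to the smallest;
ties among shapelets to (earlier segment, higher level, main before
shifted, lower position).

`bin_sensitivity` re-runs the optimal split at 1/2/3% and 10/20/30% bins
and reports a Levene equality-of-variances statistic between the two
threshold groups, as a robustness diagnostic.

The exhaustive pool of a full day (18 000 shapelets × 720 distance
vectors) is supported but slow on one core; `best_shapelet(sampler=k)`
scores k pool members drawn uniformly without replacement (k = 200 in the
pipeline default), which on well-separated data loses almost no
information gain relative to the exhaustive scan (tested against it on
2-h instances).

## Tracks, onset, separation

The best shapelet's split yields the binary track: a segment is asleep iff
its class's majority self-reported label is sleep. The ensemble track
averages `n = 50` classifiers, each an independently drawn window — random
level 1–3, random start anywhere on the sample grid (not just the
half-shift lattice), never extending past the recording end — with its own
optimal split; the score is the fraction voting awake. Scores are
thresholded at 0.5 before onset detection, ties counting as sleep (the
safety-first reading for a vigilance alarm, consistent with the method's
deliberate bias toward false sleep positives).

Onset of sleep: among maximal runs of ≥ 5 consecutive sleep segments
(≥ 10 min), the run whose start lies nearest in time to the self-reported
lights-off wins; an exact tie resolves to the earlier run (again
safety-first). No qualifying run yields an explicit no-onset result, not
an exception. Butterworth smoothing (order 2, 30-min cutoff, zero-phase
`filtfilt`) exists for display only and never feeds classification; its
parameters were chosen for a legible overnight trace.

The separation statistic is the gap between the two peaks of the best
shapelet's distance histogram: mean δ of the far class (above the
threshold) minus the near class (which contains the shapelet's own
zero-distance parent), hence non-negative. When the best shapelet is a
sleep pattern this equals the awake-class minus sleep-class mean. We use
the far-minus-near form because the shapelet's own state is arbitrary; a
signed awake-minus-sleep convention flips sign whenever an awake pattern
wins and would corrupt any cross-subject comparison. Per-sex ordinary
least squares of separation on age uses `scipy.stats.linregress`.

## The synthetic generator

`generate_recording` emits beats iteratively: the next beat follows after
RR = 60000/HR(t) ms, where

HR(t) = hr_base(state) + circadian_amp·sin(2πt/24 h + φ)
        + rsa_amp(state)·sin(φ_resp(t)) + N(0, noise_sd),

and the RSA phase φ_resp integrates 2π·f_resp(state), staying continuous
through state changes. Defaults: awake/sleep base 78/58 bpm (a ~20 bpm
nocturnal dip), RSA amplitude 1.5/5.0 bpm at 0.30/0.25 Hz, circadian
amplitude 3 bpm, beat-level noise SD 1 bpm. The default day holds one 8-h
nocturnal sleep block (15 h after start), one 20-min afternoon nap, and a
self-report annotation shifted 10 min early at both edges; sleep blocks of
≤ 30 min count as naps and are omitted from the self-report, so annotation
and truth deliberately disagree on ~20 of 720 segments. Artifact beats
(HR uniformly in 20–39 or 181–240 bpm) are injected at 0.63%; clean beats
are clipped to the plausible band, so the artifact filter's removal
fraction directly measures the injected rate. An optional pre-sleep
"relaxation ramp" blends all state parameters linearly from awake to sleep
values over `ramp_min` minutes before each main sleep onset while the true
state remains awake — the scenario under which the onset detector is
expected to fire early.

`generate_cohort` draws per-subject seeds from a master seed and mirrors a
75-subject workplace sample (40 males 16–57, 35 females 16–56). The male
aging trend weakens the sleep/awake contrast on two axes: sleep RSA
amplitude falls from 5.0 to 3.5 bpm and the nocturnal dip shallows by 40%
across 16→57 years; female parameters stay flat. The dip component
matters: under per-recording min–max normalization, *reducing only the RSA
amplitude shrinks the normalization range and thereby inflates normalized
distances*, which can cancel or even invert the intended decline of the
separation statistic. The contrast (dip) knob drives the statistic in the
physiologically expected direction regardless.

What the generator does *not* emulate: sleep-stage microstructure
(REM/non-REM), baroreflex or other closed-loop cardiovascular dynamics,
movement artifacts with realistic temporal clustering, or respiratory-rate
variability within a state. Passing the recovery tests therefore shows the
machinery is correct and sensitive under idealized two-state physiology —
not that real recordings will separate as cleanly.

## Problem sizes and numerical conventions

The test-suite and the reproduction script keep single-CPU runtimes short
by choice of problem size, not by changing the method: recovery and
conservatism experiments use full 24-h recordings over 20 seeds with
k = 200/150 candidate sampling; oracle-equivalence checks use hundreds of
random window pairs up to length 64, where exhaustive search is exact and
fast; the cohort regression uses 40 male subjects (the full male sample
size) with 2.5-h recordings — at much smaller cohorts the slope's sign is
not reliably recovered, because between-subject variance in the separation
statistic is large (the winning shapelet's level sets the distance scale,
and no length normalization is applied, faithfully to the method).

Numerical conventions: 0·log₂0 = 0; sliding-distance round-off clipped at
zero; histogram construction requires ≥ 2 distinct distances; constant
recordings, all-artifact recordings, sub-2-min recordings and one-state
label tracks raise typed errors (`DegenerateInputError` etc.) rather than
returning silent defaults.

## Known limitations

- The classifier needs both label states in the self-report; it cannot run
  fully unsupervised (the split search is label-guided by design).
- The separation statistic's scale mixes shapelet levels across subjects;
  cross-subject regressions carry that variance.
- Onset detection is anchored to the self-report ("nearest qualifying
  run"); a grossly wrong self-report drags the estimate with it.
- The min–max normalization couples distance scales to recording extremes;
  a single surviving artifact at the range boundary rescales all
  distances.
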