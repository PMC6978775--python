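"""Synthetic RR-interval recordings with known sleep/awake structure.

The generator emulates the phenomenology of ambulatory 24-h heart-beat
recordings that the pipeline is designed for:

* lower baseline heart rate during sleep than awake (defaults 58 vs 78 bpm);
* respiratory sinus arrhythmia (RSA) — a sinusoidal modulation of heart
  rate at the respiration frequency — much stronger during sleep
  (5.0 bpm at 0.25 Hz) than awake (1.5 bpm at 0.30 Hz);
* a slow circadian drift, beat-level Gaussian noise, and occasional
  artifact beats outside the 40-180 bpm band;
* naps/arousals as short sleep islands inside the day, and a self-report
  annotation that is deliberately offset from the true transitions, so the
  labels handed to the pipeline only partially match the truth.

Beats are emitted iteratively — the next beat follows the current one after
RR = 60000/HR(t) ms — so the RR sequence is internally consistent with the
underlying instantaneous heart-rate profile.  The RSA oscillation carries a
running phase accumulator, keeping it continuous through state changes and
through the optional pre-sleep "relaxation ramp" during which all
state-dependent parameters glide from awake toward sleep values while the
true state remains awake.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ParameterError
from .preprocess import AnnotationTrack, BeatSeries

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "CohortSubject",
    "default_schedule",
    "generate_recording",
    "generate_cohort",
    "write_rr_file",
]

DAY_S = 86400.0
#: sleep blocks no longer than this (30 min) are treated as naps and
#: omitted from the self-report annotation
NAP_MAX_S = 1800.0


def default_schedule(
    duration_h: float = 24.0,
    sleep_start_h: float | None = None,
    sleep_dur_h: float | None = None,
    naps: tuple | None = None,
) -> tuple:
    """Awake/sleep schedule tiling [0, duration]: one main nocturnal sleep
    block plus optional ``(start_h, dur_min)`` daytime naps.

    The default anchors describe a full day (sleep 15 h after the
    recording starts, for 8 h, nap at 6 h); recordings shorter than 24 h
    scale those anchors proportionally so a sleep block always exists.
    """
    scale = min(duration_h / 24.0, 1.0)
    if sleep_start_h is None:
        sleep_start_h = 15.0 * scale
    if sleep_dur_h is None:
        sleep_dur_h = 8.0 * scale
    if naps is None:
        naps = ((6.0 * scale, 20.0),)
    dur_s = duration_h * 3600.0
    marks = [(0.0, "awake")]
    for start_h, dur_min in naps:
        a, b = start_h * 3600.0, start_h * 3600.0 + dur_min * 60.0
        if b < dur_s:
            marks += [(a, "sleep"), (b, "awake")]
    a = sleep_start_h * 3600.0
    b = min(a + sleep_dur_h * 3600.0, dur_s)
    if a < dur_s:
        marks += [(a, "sleep")]
        if b < dur_s:
            marks += [(b, "awake")]
    marks.sort()
    sched = []
    for (t0, state), (t1, _) in zip(marks, marks[1:] + [(dur_s, "end")]):
        if t1 > t0:
            sched.append((state, t0, t1))
    return tuple(sched)


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; the defaults describe a healthy adult's 24-h
    recording with one nocturnal sleep block and one 20-min afternoon nap."""

    duration_h: float = 24.0
    schedule: tuple = None  # (state, start_s, end_s) tiles; built if None
    hr_base_awake: float = 78.0
    hr_base_sleep: float = 58.0
    rsa_amp_awake: float = 1.5
    rsa_amp_sleep: float = 5.0
    f_resp_awake: float = 0.30
    f_resp_sleep: float = 0.25
    circadian_amp: float = 3.0
    circadian_phase: float = 0.0
    noise_sd: float = 1.0
    artifact_rate: float = 0.0063
    annotation_offset_min: float = -10.0
    ramp_min: float = 0.0

    def __post_init__(self) -> None:
        if self.schedule is None:
            object.__setattr__(
                self, "schedule", default_schedule(self.duration_h)
            )
        dur_s = self.duration_h * 3600.0
        sched = tuple(self.schedule)
        if not sched or abs(sched[0][1]) > 1e-9 or abs(sched[-1][2] - dur_s) > 1e-6:
            raise ParameterError("schedule must tile [0, duration]")
        for (s0, a0, b0), (s1, a1, b1) in zip(sched, sched[1:]):
            if abs(b0 - a1) > 1e-6:
                raise ParameterError("schedule intervals must be contiguous")
        for amp in (self.rsa_amp_awake, self.rsa_amp_sleep, self.circadian_amp):
            if amp < 0:
                raise ParameterError("amplitudes must be non-negative")
        object.__setattr__(self, "schedule", sched)

    def state_at(self, t: float) -> str:
        for state, a, b in self.schedule:
            if a <= t < b:
                return state
        return self.schedule[-1][0]

    @property
    def main_sleep_intervals(self) -> tuple:
        """Sleep blocks long enough to be self-reported (naps excluded)."""
        return tuple(
            (a, b) for state, a, b in self.schedule
            if state == "sleep" and (b - a) > NAP_MAX_S
        )


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did: the true state schedule, the true
    onsets of (main) sleep, and the offset annotation the pipeline sees."""

    schedule: tuple
    true_onsets_s: tuple
    annotation: AnnotationTrack

    def state_at(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.full(t.shape, False)
        for state, a, b in self.schedule:
            if state == "sleep":
                out |= (t >= a) & (t < b)
        return out

    def segment_labels(self, starts_s, seg_len_s: float = 120.0) -> np.ndarray:
        """True sleep/awake per segment by midpoint membership."""
        return self.state_at(np.asarray(starts_s, float) + seg_len_s / 2.0)


def _param_profile(cfg: SynthConfig):
    """Per-state parameter lookup with the optional pre-sleep ramp.

    Returns a callable t -> (hr_base, rsa_amp, f_resp).  During the
    ``ramp_min`` window before each main sleep onset the parameters blend
    linearly from awake to sleep values (the true state stays awake).
    """
    awake = (cfg.hr_base_awake, cfg.rsa_amp_awake, cfg.f_resp_awake)
    asleep = (cfg.hr_base_sleep, cfg.rsa_amp_sleep, cfg.f_resp_sleep)
    ramp_s = cfg.ramp_min * 60.0
    ramps = [(a - ramp_s, a) for a, _ in cfg.main_sleep_intervals] if ramp_s > 0 else []

    def params(t: float):
        if cfg.state_at(t) == "sleep":
            return asleep
        for r0, r1 in ramps:
            if r0 <= t < r1:
                w = (t - r0) / (r1 - r0)
                return tuple((1 - w) * x + w * y for x, y in zip(awake, asleep))
        return awake

    return params


def generate_recording(
    cfg: SynthConfig, rng: np.random.Generator | int | None = None
) -> tuple[BeatSeries, AnnotationTrack, GroundTruth]:
    """Emit a beat-to-beat recording under ``cfg``.

    Instantaneous heart rate is
    ``HR(t) = hr_base(state) + circadian_amp*sin(2*pi*t/24h + phase)
    + rsa_amp(state)*sin(phi(t)) + N(0, noise_sd)`` with the RSA phase
    ``phi`` integrating ``2*pi*f_resp(state)``.  Beats follow each other at
    ``RR = 60000/HR`` ms; artifact beats with HR outside 40-180 bpm are
    injected at ``artifact_rate``.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(rng)
    params = _param_profile(cfg)
    dur_s = cfg.duration_h * 3600.0
    omega_c = 2.0 * math.pi / DAY_S

    rr_list: list[float] = []
    t = 0.0
    phi = 0.0
    while t < dur_s:
        base, amp, f = params(t)
        hr = (
            base
            + cfg.circadian_amp * math.sin(omega_c * t + cfg.circadian_phase)
            + amp * math.sin(phi)
            + rng.normal(0.0, cfg.noise_sd)
        )
        hr = min(max(hr, 41.0), 179.0)  # clean beats stay inside the band
        if cfg.artifact_rate > 0 and rng.random() < cfg.artifact_rate:
            hr = rng.uniform(20.0, 39.0) if rng.random() < 0.5 else rng.uniform(181.0, 240.0)
        rr_ms = 60000.0 / hr
        rr_list.append(rr_ms)
        dt = rr_ms / 1000.0
        phi += 2.0 * math.pi * f * dt
        t += dt

    rr = np.asarray(rr_list)
    beats = BeatSeries(t=np.cumsum(rr) / 1000.0, rr=rr)

    off_s = cfg.annotation_offset_min * 60.0
    reported = []
    for a, b in cfg.main_sleep_intervals:
        ra = min(max(a + off_s, 0.0), dur_s)
        rb = min(max(b + off_s, 0.0), dur_s)
        if rb > ra:
            reported.append((ra, rb))
    annotation = AnnotationTrack(sleep_intervals=tuple(reported))
    truth = GroundTruth(
        schedule=cfg.schedule,
        true_onsets_s=tuple(a for a, _ in cfg.main_sleep_intervals),
        annotation=annotation,
    )
    return beats, annotation, truth


@dataclass(frozen=True)
class CohortSubject:
    subject_id: int
    age: float
    sex: str  # "M" | "F"
    config: SynthConfig
    seed: int
    beats: BeatSeries = field(repr=False, default=None)
    annotation: AnnotationTrack = field(repr=False, default=None)
    truth: GroundTruth = field(repr=False, default=None)


def _age_dependent_config(base: SynthConfig, age: float, sex: str) -> SynthConfig:
    """Inject the cohort trend for males: the sleep/awake contrast weakens
    with age — sleep RSA amplitude declines and the nocturnal heart-rate
    dip shallows — so the separation statistic decreases with age.
    Female parameters stay flat."""
    if sex == "M":
        frac = min(max((age - 16.0) / 41.0, 0.0), 1.0)
        amp = base.rsa_amp_sleep - 1.5 * frac
        dip = base.hr_base_awake - base.hr_base_sleep
        hr_sleep = base.hr_base_awake - dip * (1.0 - 0.4 * frac)
        return replace(base, rsa_amp_sleep=amp, hr_base_sleep=hr_sleep)
    return base


def generate_cohort(
    n_subjects: int = 75,
    rng: np.random.Generator | int | None = None,
    male_fraction: float = 40 / 75,
    age_range_m: tuple = (16, 57),
    age_range_f: tuple = (16, 56),
    base_config: SynthConfig | None = None,
    generate: bool = True,
) -> list[CohortSubject]:
    """A synthetic cohort mirroring a workplace-assessment study sample
    (default 75 subjects: 40 male aged 16-57, 35 female aged 16-56).

    Per-subject seeds are derived from the master seed, so ``n_subjects=1``
    reproduces exactly the single recording generated with the derived
    seed.  With ``generate=False`` only demographics and configs are
    returned (recordings can be produced later from the stored seeds).
    """
    if n_subjects < 1:
        raise ParameterError("need at least one subject")
    master = np.random.default_rng(rng)
    seed_seq = np.random.SeedSequence(int(master.integers(0, 2**31 - 1)))
    children = seed_seq.spawn(n_subjects)
    base = base_config or SynthConfig()
    n_male = int(round(male_fraction * n_subjects))
    subjects = []
    for i, child in enumerate(children):
        sub_rng = np.random.default_rng(child)
        sex = "M" if i < n_male else "F"
        lo, hi = age_range_m if sex == "M" else age_range_f
        age = float(sub_rng.integers(lo, hi + 1))
        cfg = _age_dependent_config(base, age, sex)
        seed = int(sub_rng.integers(0, 2**31 - 1))
        beats = ann = truth = None
        if generate:
            beats, ann, truth = generate_recording(cfg, rng=seed)
        subjects.append(
            CohortSubject(
                subject_id=i, age=age, sex=sex, config=cfg, seed=seed,
                beats=beats, annotation=ann, truth=truth,
            )
        )
    return subjects


def write_rr_file(beats: BeatSeries, path) -> None:
    """Write the rr-only dialect read by :func:`hrvshape.preprocess.load_rr`."""
    with open(path, "w") as fh:
        for rr in beats.rr:
            fh.write(f"{rr:.6f}\n")
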