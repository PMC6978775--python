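import json

import numpy as np
import pytest

import hrvshape as hs
from hrvshape.exceptions import ParameterError, PipelineError


def _toy_split(deltas, labels, threshold):
    dv = hs.DistanceVector(
        shapelet_id="toy", delta=np.asarray(deltas, float),
        offset=np.zeros(len(deltas), int),
    )
    return dv, hs.information_gain(dv, labels, threshold)


class TestClassifyBinary:
    def test_perfect_separation_recovers_labels(self):
        labels = np.array([True] * 4 + [False] * 4)
        dv, split = _toy_split([0.1] * 4 + [0.9] * 4, labels, 0.5)
        track = hs.classify_binary(dv, split)
        np.testing.assert_array_equal(track.is_sleep, labels)
        assert set(track.values) <= {0.0, 1.0}

    def test_extreme_threshold_gives_single_state(self):
        labels = np.array([True] * 4 + [False] * 4)
        dv, split = _toy_split([0.1] * 4 + [0.9] * 4, labels, 2.0)
        track = hs.classify_binary(dv, split)
        assert len(set(track.values)) == 1

    def test_best_shapelet_track_matches_ground_truth(self, short_segments):
        segs = short_segments["segments"]
        res = hs.best_shapelet(
            hs.pool_for_series(segs), segs, short_segments["labels"]
        )
        track = hs.classify_binary(
            res.dv, res.split, start_s=short_segments["starts"]
        )
        assert (track.is_sleep == short_segments["truth"]).mean() >= 0.95


class TestEnsembleScore:
    def test_single_classifier_is_binary(self, short_segments):
        ens = hs.ensemble_score(
            short_segments["uniform"], short_segments["labels"],
            n=1, rng=0, segments=short_segments["segments"],
        )
        assert set(np.unique(ens.values)) <= {0.0, 1.0}

    def test_scores_bounded_and_reproducible(self, short_segments):
        kw = dict(n=10, segments=short_segments["segments"])
        a = hs.ensemble_score(
            short_segments["uniform"], short_segments["labels"], rng=7, **kw
        )
        b = hs.ensemble_score(
            short_segments["uniform"], short_segments["labels"], rng=7, **kw
        )
        np.testing.assert_array_equal(a.values, b.values)
        assert a.values.min() >= 0.0 and a.values.max() <= 1.0

    def test_two_regime_scores_separate_states(self, short_segments):
        ens = hs.ensemble_score(
            short_segments["uniform"], short_segments["labels"],
            n=50, rng=3, segments=short_segments["segments"],
        )
        gt = short_segments["truth"]
        assert ens.values[gt].mean() < 0.2
        assert ens.values[~gt].mean() > 0.8

    def test_threshold_half_agrees_with_majority_vote(self, short_segments):
        ens = hs.ensemble_score(
            short_segments["uniform"], short_segments["labels"],
            n=11, rng=5, segments=short_segments["segments"],
        )
        # odd ensemble -> no ties; sleep iff fewer than half vote awake
        majority_sleep = ens.values * 11 < 5.5
        np.testing.assert_array_equal(ens.is_sleep, majority_sleep)

    def test_invalid_n(self, short_segments):
        with pytest.raises(ParameterError):
            hs.ensemble_score(
                short_segments["uniform"], short_segments["labels"], n=0
            )


class TestSmoothTrack:
    def test_constant_unchanged(self):
        x = np.full(100, 0.7)
        np.testing.assert_allclose(hs.smooth_track(x), x, atol=1e-9)

    def test_reduces_white_noise_variance(self):
        x = np.random.default_rng(0).normal(size=500)
        assert hs.smooth_track(x).var() < x.var()

    def test_step_response_overshoot_bounded(self):
        x = np.concatenate([np.zeros(200), np.ones(200)])
        y = hs.smooth_track(x)
        assert y.max() <= 1.15
        assert y.min() >= -0.15

    def test_short_input_passes_through_with_warning(self):
        x = np.array([0.0, 1.0, 0.5])
        with pytest.warns(UserWarning):
            y = hs.smooth_track(x)
        np.testing.assert_array_equal(y, x)


class TestDetectOnset:
    @staticmethod
    def _track(sleep_mask):
        sleep_mask = np.asarray(sleep_mask, bool)
        return hs.ConsciousnessTrack(
            values=(~sleep_mask).astype(float),
            start_s=np.arange(len(sleep_mask)) * 120.0,
        )

    def test_single_qualifying_run(self):
        track = self._track([False] * 10 + [True] * 6 + [False] * 4)
        est = hs.detect_onset(track, self_reported_s=0.0)
        assert est.found
        assert est.onset_s == pytest.approx(10 * 120.0)

    def test_short_run_gives_no_onset(self):
        track = self._track([False] * 10 + [True] * 4 + [False] * 6)
        est = hs.detect_onset(track, self_reported_s=1200.0)
        assert not est.found
        assert est.onset_s is None and est.delta_min is None

    def test_minimum_qualifying_run_is_five_segments(self):
        base = [False] * 10
        for run, found in [(4, False), (5, True)]:
            track = self._track(base + [True] * run + [False] * 5)
            assert hs.detect_onset(track, 1200.0).found is found

    def test_nearest_run_wins(self):
        sleep = [True] * 6 + [False] * 10 + [True] * 6
        track = self._track(sleep)
        # self-report just after the second run's start
        est = hs.detect_onset(track, self_reported_s=16 * 120.0 + 30)
        assert est.onset_s == pytest.approx(16 * 120.0)
        # self-report at the very start: first run wins
        est2 = hs.detect_onset(track, self_reported_s=0.0)
        assert est2.onset_s == pytest.approx(0.0)

    def test_equidistant_tie_resolves_earlier(self):
        sleep = [True] * 5 + [False] * 10 + [True] * 5
        track = self._track(sleep)
        mid = (0.0 + 15 * 120.0) / 2.0
        est = hs.detect_onset(track, self_reported_s=mid)
        assert est.onset_s == pytest.approx(0.0)

    def test_onset_lies_on_segment_boundary(self, short_segments):
        segs = short_segments["segments"]
        res = hs.best_shapelet(
            hs.pool_for_series(segs), segs, short_segments["labels"]
        )
        track = hs.classify_binary(res.dv, res.split, short_segments["starts"])
        ann = short_segments["annotation"]
        est = hs.detect_onset(track, ann.sleep_intervals[0][0])
        assert est.found
        assert est.onset_s in set(short_segments["starts"])

    def test_continuous_track_thresholded_first(self):
        vals = np.array([0.9] * 8 + [0.1] * 6 + [0.9] * 4)
        track = hs.ConsciousnessTrack(
            values=vals, start_s=np.arange(len(vals)) * 120.0, kind="continuous"
        )
        est = hs.detect_onset(track, self_reported_s=8 * 120.0)
        assert est.onset_s == pytest.approx(8 * 120.0)


class TestSeparation:
    def test_difference_of_class_means(self):
        labels = np.array([True, True, False, False])
        dv, split = _toy_split([0.1, 0.1, 0.5, 0.5], labels, 0.3)
        stat = hs.separation_statistic(dv, split)
        assert stat.value == pytest.approx(0.4)

    def test_identical_means_give_zero(self):
        labels = np.array([True, False])
        dv, split = _toy_split([0.2, 0.2 + 1e-15], labels, 0.2 + 5e-16)
        stat = hs.separation_statistic(dv, split)
        assert stat.value == pytest.approx(0.0, abs=1e-12)

    def test_empty_class_is_nan(self):
        labels = np.array([True, True, False, False])
        dv, split = _toy_split([0.1, 0.1, 0.5, 0.5], labels, 2.0)
        assert np.isnan(hs.separation_statistic(dv, split).value)

    def test_grows_with_sleep_awake_contrast(self):
        # sweeping the nocturnal heart-rate dip upward makes sleep more
        # distinctive, so the peak separation must increase monotonically
        values = []
        for base_sleep in (70.0, 64.0, 58.0):
            cfg = hs.SynthConfig(
                duration_h=2.0,
                schedule=(("awake", 0.0, 3600.0), ("sleep", 3600.0, 7200.0)),
                hr_base_sleep=base_sleep,
                annotation_offset_min=0.0,
                artifact_rate=0.0,
            )
            beats, ann, _ = hs.generate_recording(cfg, rng=9)
            un = hs.normalize(hs.resample_uniform(hs.filter_hr(beats)[0]))
            segs = hs.segmentize(un)
            starts = np.array([s.start_s for s in segs])
            labels = ann.segment_labels(starts, 120.0)
            res = hs.best_shapelet(hs.pool_for_series(segs), segs, labels)
            values.append(hs.separation_statistic(res.dv, res.split).value)
        assert values[0] < values[1] < values[2]


class TestAgeRegression:
    def test_collinear_points_give_unit_r2(self):
        stats = [
            hs.SeparationStat(value=10.0 - 0.1 * a, age=a, sex="M")
            for a in (20, 30, 40, 50)
        ]
        out = hs.age_regression(stats)
        assert out["M"]["r2"] == pytest.approx(1.0)
        assert out["M"]["slope"] == pytest.approx(-0.1)

    def test_permuted_ages_kill_correlation(self):
        rng = np.random.default_rng(0)
        ages = np.linspace(20, 60, 40)
        values = 10.0 - 0.1 * ages + rng.normal(0, 0.1, 40)
        perm = rng.permutation(40)
        stats = [
            hs.SeparationStat(value=values[i], age=ages[perm[i]], sex="F")
            for i in range(40)
        ]
        out = hs.age_regression(stats)
        assert out["F"]["r2"] < 0.2

    def test_too_few_points(self):
        stats = [hs.SeparationStat(value=1.0, age=30, sex="M")] * 2
        with pytest.raises(ParameterError):
            hs.age_regression(stats)

    def test_stratified_by_sex(self):
        stats = [
            hs.SeparationStat(value=5.0 - 0.05 * a, age=a, sex="M")
            for a in (20, 30, 40)
        ] + [
            hs.SeparationStat(value=3.0 + 0.0 * a, age=a, sex="F")
            for a in (20, 30, 40)
        ]
        out = hs.age_regression(stats)
        assert out["M"]["slope"] < -0.01
        assert out["F"]["slope"] == pytest.approx(0.0, abs=1e-9)


class TestRunPipeline:
    @pytest.fixture(scope="class")
    def fixture_files(self, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("pipeline")
        cfg = hs.SynthConfig(
            duration_h=2.0,
            schedule=(("awake", 0.0, 3600.0), ("sleep", 3600.0, 7200.0)),
            annotation_offset_min=-4.0,
        )
        beats, ann, _ = hs.generate_recording(cfg, rng=123)
        rr = tmp / "rr.txt"
        annp = tmp / "ann.json"
        hs.write_rr_file(beats, rr)
        ann.to_json(annp)
        return rr, annp

    def test_report_schema_and_determinism(self, fixture_files):
        rr, annp = fixture_files
        cfg = {"sampler": 50, "ensemble_n": 10, "seed": 1}
        rep1 = hs.run_pipeline(rr, annp, cfg)
        rep2 = hs.run_pipeline(rr, annp, cfg)
        assert rep1 == rep2
        assert rep1["n_segments"] == 59
        assert 0.0 <= rep1["split"]["ig_bits"] <= 1.0
        json.dumps(rep1)  # JSON-serializable

    def test_matches_golden_report(self, fixture_files):
        # frozen output of this pipeline on the same fixed-seed fixture;
        # guards against silent behavioural drift
        import pathlib

        rr, annp = fixture_files
        rep = hs.run_pipeline(rr, annp, {"sampler": 50, "ensemble_n": 10, "seed": 1})
        golden = json.loads(
            (pathlib.Path(__file__).parent / "data" / "golden_report.json").read_text()
        )

        def compare(a, b, key=""):
            if isinstance(a, dict):
                assert set(a) == set(b), key
                for k in a:
                    compare(a[k], b[k], key + "." + str(k))
            elif isinstance(a, list):
                assert len(a) == len(b), key
                for x, y in zip(a, b):
                    compare(x, y, key)
            elif isinstance(a, float):
                assert a == pytest.approx(b, rel=1e-9, abs=1e-9), key
            else:
                assert a == b, key

        compare(rep, golden)

    def test_missing_annotation_stops_with_stage_name(self, fixture_files, tmp_path):
        rr, _ = fixture_files
        with pytest.raises(PipelineError, match="annotation"):
            hs.run_pipeline(rr, tmp_path / "missing.json", {"sampler": 10})

    def test_empty_annotation_rejected(self, fixture_files, tmp_path):
        rr, _ = fixture_files
        empty = tmp_path / "empty.json"
        empty.write_text('{"sleep": []}')
        with pytest.raises(PipelineError, match="annotation"):
            hs.run_pipeline(rr, empty, {"sampler": 10})

    def test_truncated_recording_completes(self, fixture_files, tmp_path):
        rr, annp = fixture_files
        lines = rr.read_text().splitlines()
        part = tmp_path / "part.txt"
        part.write_text("\n".join(lines[: 3 * len(lines) // 4]) + "\n")
        rep = hs.run_pipeline(part, annp, {"sampler": 30, "ensemble_n": 5})
        assert rep["n_segments"] < 59
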