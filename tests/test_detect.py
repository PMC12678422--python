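import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lthrm import (
    AnnotationSet,
    PreprocessedRecording,
    WindowClassifier,
    postprocess_trace,
    rolling_inference,
)
from lthrm.detect import (
    InferenceTrace,
    build_training_set,
    extract_runs,
    negative_intervals,
    windows_to_arrays,
)


def brute_detections(s, smooth_w=20, threshold=0.2):
    """Run extraction oracle: scan the smoothed trace directly."""
    if len(s) < smooth_w:
        return []
    s_hat = np.array(
        [np.mean(s[j : j + smooth_w]) for j in range(len(s) - smooth_w + 1)]
    )
    active = s_hat > threshold
    out = []
    j = 0
    while j < len(active):
        if active[j]:
            k = j
            while k + 1 < len(active) and active[k + 1]:
                k += 1
            span = s[j : k + 1]
            out.append(j + int(np.argmax(span)))
            j = k + 1
        else:
            j += 1
    return out


def _trace(s, stride=1):
    s = np.asarray(s, dtype=float)
    return InferenceTrace(
        patient_id="p", o=(s > 0).astype(float), c=np.abs(s), s=s, stride=stride
    )


class TestTrainingSetConstruction:
    def test_interval_arithmetic_with_guard(self):
        """Two annotated swallows in a 5000-sample recording leave exactly
        two guarded negative intervals, each holding two windows."""
        starts = np.array([1000, 3000])
        iv = negative_intervals(starts, t=5000)
        assert iv == [(1750, 2750), (3750, 5000)]
        values = np.arange(36 * 5000, dtype=float).reshape(36, 5000)
        prep = PreprocessedRecording("p1", values, values)
        wins = build_training_set(
            [prep], [AnnotationSet("p1", starts)], balance=False
        )
        pos = [w for w in wins if w.label == 1]
        neg = [w for w in wins if w.label == 0]
        assert [w.origin[1] for w in pos] == [1000, 3000]
        assert [w.origin[1] for w in neg] == [1750, 2250, 3750, 4250]

    def test_no_annotations_tiles_whole_recording(self):
        values = np.zeros((36, 2000))
        prep = PreprocessedRecording("p1", values, values)
        wins = build_training_set([prep], [AnnotationSet("p1", [])])
        assert all(w.label == 0 for w in wins)
        assert len(wins) == 4

    def test_small_gap_yields_no_negative(self):
        # gap of 600 samples: 600 - 500 < 2 * 250
        iv = negative_intervals(np.array([0, 1100]), t=1100 + 500)
        assert iv == []

    def test_window_past_end_skipped(self, caplog):
        values = np.zeros((36, 1200))
        prep = PreprocessedRecording("p1", values, values)
        wins = build_training_set([prep], [AnnotationSet("p1", [900])])
        assert all(w.label == 0 for w in wins)

    def test_balancing_is_seeded(self, small_cohort):
        a = build_training_set(small_cohort["preps"], small_cohort["anns"], seed=3)
        b = build_training_set(small_cohort["preps"], small_cohort["anns"], seed=3)
        assert [w.origin for w in a] == [w.origin for w in b]
        n_pos = sum(w.label for w in a)
        assert n_pos == len(a) - n_pos  # balanced


class TestWindowClassifier:
    def test_single_class_rejected(self, rng):
        X = rng.random((10, 36, 500))
        with pytest.raises(ValueError, match="both"):
            WindowClassifier().fit(X, np.ones(10))

    def test_unknown_backbone_rejected(self, rng):
        X = rng.random((4, 36, 500))
        with pytest.raises(ValueError, match="backbone"):
            WindowClassifier(backbone="mobilenet").fit(X, [0, 1, 0, 1])

    def test_separates_synthetic_classes(self, small_cohort):
        wins = build_training_set(
            small_cohort["preps"][:4], small_cohort["anns"][:4], seed=0
        )
        X, y = windows_to_arrays(wins)
        clf = WindowClassifier(random_state=0).fit(X, y)
        assert clf.training_log_["train_accuracy"] >= 0.95
        # and on held-out patients of the same cohort
        held = build_training_set(
            small_cohort["preps"][4:], small_cohort["anns"][4:], seed=0
        )
        Xh, yh = windows_to_arrays(held)
        assert (clf.predict(Xh) == yh).mean() >= 0.9

    def test_same_seed_reproduces_training(self, small_cohort):
        wins = build_training_set(
            small_cohort["preps"][:2], small_cohort["anns"][:2], seed=0
        )
        X, y = windows_to_arrays(wins)
        a = WindowClassifier(random_state=7).fit(X, y)
        b = WindowClassifier(random_state=7).fit(X, y)
        assert a.training_log_["final_loss"] == b.training_log_["final_loss"]

    def test_probabilities_sum_to_one(self, trained_detector, rng):
        p = trained_detector.classifier_.predict_proba(rng.random((3, 36, 500)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0)


class TestRollingInference:
    def test_single_window_boundary(self, trained_detector):
        values = np.full((36, 500), 30.0)
        prep = PreprocessedRecording("p", values, values)
        trace = rolling_inference(trained_detector.classifier_, prep, stride=1)
        assert len(trace.s) == 1

    def test_too_short_rejected(self, trained_detector):
        values = np.zeros((36, 499))
        prep = PreprocessedRecording("p", values, values)
        with pytest.raises(ValueError, match="short"):
            rolling_inference(trained_detector.classifier_, prep)

    def test_stride_reexpansion_length(self, trained_detector):
        values = np.full((36, 5000), 30.0)
        prep = PreprocessedRecording("p", values, values)
        trace = rolling_inference(trained_detector.classifier_, prep, stride=10)
        assert len(trace.s) == 4501  # 451 raw windows re-expanded

    def test_flat_baseline_yields_no_signal(self, trained_detector, small_cohort):
        # a swallow-free stretch of real synthetic background
        prep = small_cohort["preps"][0]
        ann = small_cohort["anns"][0]
        gap_start = int(ann.starts[0]) + 700
        values = prep.values[:, gap_start : gap_start + 800]
        flat = PreprocessedRecording("p", values, values)
        trace = rolling_inference(trained_detector.classifier_, flat, stride=5)
        det = postprocess_trace(trace)
        assert len(det) == 0

    def test_s_zero_where_o_zero(self, trained_detector, small_cohort):
        trace = trained_detector.predict_trace(small_cohort["preps"][4])
        assert np.all(trace.s[trace.o == 0] == 0)
        assert np.all((trace.c >= 0) & (trace.c <= 1))


class TestPostprocess:
    def test_all_zero_trace(self):
        det = postprocess_trace(_trace(np.zeros(100)))
        assert len(det) == 0

    def test_plateau_run_span_and_argmax(self):
        """A 0.9-plateau on [100, 139] activates smoothed indices [85, 135]
        and the predicted start is the first raw maximum at 100."""
        s = np.zeros(300)
        s[100:140] = 0.9
        trace = _trace(s)
        det = postprocess_trace(trace)
        runs = extract_runs(trace.s_b)
        assert runs == [(85, 135)]
        assert list(det.predicted_starts) == [100]
        np.testing.assert_allclose(det.confidences, [0.9])

    def test_two_plateaus_two_detections(self):
        s = np.zeros(2000)
        s[100:140] = 0.9
        s[1100:1140] = 0.9
        det = postprocess_trace(_trace(s))
        assert list(det.predicted_starts) == [100, 1100]

    def test_matches_run_extraction_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(20, 400))
            s = rng.random(n) * (rng.random(n) > 0.6)
            det = postprocess_trace(_trace(s))
            assert list(det.predicted_starts) == brute_detections(s)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.sampled_from([0.0, 0.1, 0.5, 0.9]), min_size=20, max_size=80))
    def test_oracle_equivalence_property(self, values):
        s = np.array(values)
        det = postprocess_trace(_trace(s))
        assert list(det.predicted_starts) == brute_detections(s)

    def test_trace_shorter_than_smoothing_window(self):
        det = postprocess_trace(_trace(np.ones(5)))
        assert len(det) == 0


def test_detector_finds_swallows_on_held_out_patient(trained_detector, small_cohort):
    from lthrm import MatchSpec, match_detections

    prep = small_cohort["preps"][5]
    ann = small_cohort["anns"][5]
    res = trained_detector.predict(prep)
    m = match_detections(ann.starts, res.predicted_starts, MatchSpec(d=400))
    assert m.recall >= 0.9
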