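"""Alignment/contact classification rules and confusion-matrix metrics,
cross-checked against scikit-learn and hand-computed tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score

from satpose import assess
from satpose.assess import (
    ConfusionSummary,
    classify_alignment,
    classify_contact,
    confusion,
    f1_from_precision_recall,
    reference_posture,
    sweep_thresholds,
    sweep_to_frame,
)
from satpose.kinematics import HEAD_TRUNK_SEGMENTS, SEGMENT_NAMES, SegmentAngleFrame
from satpose.landmarks import KeypointSet, PointFeatureName

P = PointFeatureName


def _frame(vals):
    return SegmentAngleFrame({s: v for s, v in zip(SEGMENT_NAMES, vals)})


def _kp(elbow, wrist, asis=(30.0, 40.0)):
    coords = np.arange(26, dtype=float).reshape(13, 2) + 100
    coords[10] = (10.0, 10.0)  # shoulder, irrelevant
    coords[11] = elbow
    coords[12] = wrist
    coords[8] = asis
    return KeypointSet(coords)


class TestReferencePosture:
    def test_constant_stream(self):
        stream = [_frame([12.0] * 10)] * 5
        ref = reference_posture(stream, "childA")
        assert all(ref[s] == pytest.approx(12.0) for s in SEGMENT_NAMES)

    def test_symmetric_sessions_average_to_zero(self):
        stream = [_frame([10.0] * 10)] * 4 + [_frame([-10.0] * 10)] * 4
        ref = reference_posture(stream)
        assert all(ref[s] == pytest.approx(0.0) for s in SEGMENT_NAMES)

    def test_matches_mean_oracle(self, rng):
        vals = rng.uniform(-40, 40, size=(50, 10))
        stream = [_frame(v) for v in vals]
        ref = reference_posture(stream)
        for i, s in enumerate(SEGMENT_NAMES):
            assert ref[s] == pytest.approx(vals[:, i].mean(), abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            reference_posture([])


class TestClassifyAlignment:
    def _ref(self):
        return assess.ReferencePosture("x", {s: 0.0 for s in SEGMENT_NAMES})

    def test_boundary_is_strictly_more_than(self):
        ref = self._ref()
        at = [_frame([20.0] * 10)]
        above = [_frame([20.1] * 10)]
        assert not classify_alignment(at, ref, 20.0).any()
        assert classify_alignment(above, ref, 20.0).all()

    def test_deviation_is_circular(self):
        ref = assess.ReferencePosture("x", {s: 179.0 for s in SEGMENT_NAMES})
        stream = [_frame([-179.0] * 10)]  # 2 degrees away, not 358
        assert not classify_alignment(stream, ref, 5.0).any()

    def test_positive_threshold_required(self):
        with pytest.raises(ValueError):
            classify_alignment([_frame([0.0] * 10)], self._ref(), 0.0)

    def test_label_positive_count_non_increasing_in_threshold(self, rng):
        vals = rng.uniform(-45, 45, size=(200, 10))
        stream = [_frame(v) for v in vals]
        ref = self._ref()
        counts = [
            classify_alignment(stream, ref, thr).sum() for thr in range(1, 41)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestClassifyContact:
    def test_no_contact_when_clear(self):
        kp = _kp(elbow=(31.0, 20.0), wrist=(35.0, 39.0))
        assert classify_contact(kp, (30.0, 40.0)) == (False, False, False)

    def test_elbow_left_of_asis_is_contact(self):
        kp = _kp(elbow=(29.0, 20.0), wrist=(35.0, 39.0))
        assert classify_contact(kp, (30.0, 40.0)) == (True, False, True)

    def test_wrist_below_asis_is_contact(self):
        kp = _kp(elbow=(31.0, 20.0), wrist=(35.0, 41.0))
        assert classify_contact(kp, (30.0, 40.0)) == (False, True, True)

    def test_exact_tie_is_negative(self):
        kp = _kp(elbow=(30.0, 20.0), wrist=(35.0, 40.0))
        assert classify_contact(kp, (30.0, 40.0)) == (False, False, False)

    def test_facing_right_flips_elbow_rule(self):
        kp = _kp(elbow=(29.0, 20.0), wrist=(35.0, 39.0))
        assert classify_contact(kp, (30.0, 40.0), facing="right") == (
            False, False, False,
        )
        kp2 = _kp(elbow=(31.0, 20.0), wrist=(35.0, 39.0))
        assert classify_contact(kp2, (30.0, 40.0), facing="right")[0]


class TestConfusion:
    def test_hand_computed_balanced_table(self):
        cs = ConfusionSummary(tp=1, fp=1, tn=1, fn=1)
        assert cs.accuracy == pytest.approx(50.0)
        assert cs.precision == pytest.approx(50.0)
        assert cs.recall == pytest.approx(50.0)
        assert cs.f1 == pytest.approx(50.0)

    def test_perfect_prediction(self, rng):
        truth = rng.uniform(size=300) < 0.3
        cs = confusion(truth, truth)
        assert cs.accuracy == 100.0
        assert cs.f1 == pytest.approx(100.0)

    def test_against_sklearn_oracle(self, rng):
        truth = rng.uniform(size=500) < 0.25
        pred = truth ^ (rng.uniform(size=500) < 0.2)
        cs = confusion(pred, truth)
        assert cs.accuracy == pytest.approx(100 * accuracy_score(truth, pred))
        assert cs.precision == pytest.approx(100 * precision_score(truth, pred))
        assert cs.recall == pytest.approx(100 * recall_score(truth, pred))
        assert cs.f1 == pytest.approx(100 * f1_score(truth, pred))

    def test_undefined_precision_flagged(self):
        cs = confusion(np.zeros(10, bool), np.array([True] * 3 + [False] * 7))
        assert not cs.precision_defined
        assert cs.precision == 0.0
        assert cs.f1 == 0.0

    @settings(derandomize=True, max_examples=60)
    @given(
        tp=st.integers(0, 500), fp=st.integers(0, 500),
        tn=st.integers(0, 500), fn=st.integers(0, 500),
    )
    def test_metric_identities(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        cs = ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)
        assert cs.n == tp + fp + tn + fn
        if cs.recall_defined:
            assert cs.tpr + cs.fnr == pytest.approx(100.0)
        if cs.n_negative:
            assert cs.fpr + cs.tnr == pytest.approx(100.0)
        if cs.precision + cs.recall > 0:
            assert cs.f1 == pytest.approx(
                2 * cs.precision * cs.recall / (cs.precision + cs.recall)
            )
        assert 0.0 <= cs.accuracy <= 100.0


class TestSweep:
    def _streams(self, rng, n=300, noise=3.0):
        vals = rng.uniform(-40, 40, size=(n, 10))
        lab = [_frame(v) for v in vals]
        pred = [_frame(v + rng.normal(0, noise, 10)) for v in vals]
        return pred, lab

    def test_structure_and_thresholds(self, rng):
        pred, lab = self._streams(rng, n=50)
        ref = reference_posture(lab)
        sweep = sweep_thresholds(pred, lab, ref, thresholds=range(1, 41))
        assert set(sweep) == set(HEAD_TRUNK_SEGMENTS)
        for by_thr in sweep.values():
            assert sorted(by_thr) == list(range(1, 41))
            for cs in by_thr.values():
                assert cs.n == 50
        df = sweep_to_frame(sweep)
        assert len(df) == 8 * 40
        assert {"segment", "threshold", "f1", "accuracy"} <= set(df.columns)

    def test_exact_agreement_on_ground_truth(self, rng):
        _, lab = self._streams(rng, n=80)
        ref = reference_posture(lab)
        sweep = sweep_thresholds(lab, lab, ref, thresholds=[5, 15, 25])
        for by_thr in sweep.values():
            for cs in by_thr.values():
                assert cs.fp == 0 and cs.fn == 0

    def test_f1_degrades_smoothly_with_keypoint_noise(self, rng):
        # property: more perturbation -> lower (never higher) agreement
        vals = rng.uniform(-40, 40, size=(400, 10))
        lab = [_frame(v) for v in vals]
        ref = reference_posture(lab)
        f1s = []
        for noise in (0.0, 2.0, 8.0):
            pred = [_frame(v + rng.normal(0, noise, 10)) for v in vals]
            pc = classify_alignment(pred, ref, 15.0)
            tc = classify_alignment(lab, ref, 15.0)
            f1s.append(confusion(pc, tc).f1)
        assert f1s[0] == pytest.approx(100.0)
        assert f1s[0] > f1s[1] > f1s[2]
        assert f1s[2] > 0.0


def test_f1_from_precision_recall():
    assert f1_from_precision_recall(83.2, 77.9) == pytest.approx(80.5, abs=0.05)
    assert f1_from_precision_recall(0.0, 0.0) == 0.0
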