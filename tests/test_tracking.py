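"""Preprocessing, detection gating, Kalman filtering and the dual-mode loop."""

import numpy as np
import pytest

import fluorosynth as fs
from fluorosynth.tracking import Detection, KalmanFilterCV, TrackState, merge_duplicates


def det_at(x, y, size=10.0, conf=0.9):
    half = size / 2
    poly = np.array([[x - half, y - half], [x + half, y - half],
                     [x + half, y + half], [x - half, y + half]])
    return Detection(polygon=poly, confidence=conf)


class TestPreprocess:
    def test_identity_config(self, background):
        out = fs.preprocess(background, fs.PreprocessConfig())
        np.testing.assert_array_equal(out, background)

    def test_constant_frame_survives_equalization(self):
        img = np.full((64, 64), 42, np.uint8)
        out = fs.preprocess(img, fs.PreprocessConfig(equalize=True))
        np.testing.assert_array_equal(out, img)

    def test_equalized_output_spans_full_range(self, background):
        out = fs.preprocess(background, fs.PreprocessConfig(equalize=True))
        assert out.min() == 0 and out.max() == 255

    def test_contrast_gain(self):
        img = np.full((8, 8), 100, np.uint8)
        out = fs.preprocess(img, fs.PreprocessConfig(contrast=1.5))
        assert (out == 150).all()


class TestFilterDetections:
    def setup_method(self):
        self.state = TrackState(position=np.array([100.0, 100.0]),
                                velocity=np.zeros(2))
        self.gates = fs.GateConfig(min_confidence=0.5, max_step=30.0,
                                   width_range=(2, 50), length_range=(2, 50))

    def test_low_confidence_rejected(self):
        out = fs.filter_detections([det_at(100, 100, conf=0.2)], self.state, self.gates)
        assert out is None

    def test_distant_detection_rejected(self):
        out = fs.filter_detections([det_at(200, 100)], self.state, self.gates)
        assert out is None

    def test_nearest_survivor_selected(self):
        d5 = det_at(105, 100)
        d12 = det_at(100, 112)
        out = fs.filter_detections([d12, d5], self.state, self.gates)
        assert out is d5

    def test_geometric_gate(self):
        out = fs.filter_detections([det_at(100, 100, size=80)], self.state, self.gates)
        assert out is None

    def test_coasting_widens_temporal_gate(self):
        # 100 px away: rejected fresh, accepted after widening x(1 + 0.5*5)
        far = det_at(100, 195)
        assert fs.filter_detections([far], self.state, self.gates) is None
        coasting = TrackState(position=self.state.position, velocity=np.zeros(2),
                              frames_since_detection=5)
        assert fs.filter_detections([far], coasting, self.gates) is far

    def test_centreline_gate(self):
        gates = fs.GateConfig(min_confidence=0.5, max_step=30.0,
                              max_centreline_distance=5.0)
        line = np.array([[0.0, 100.0], [300.0, 100.0]])
        on_line = det_at(100, 102)
        off_line = det_at(100, 120)
        assert fs.filter_detections([on_line], self.state, gates, centreline=line) is on_line
        assert fs.filter_detections([off_line], self.state, gates, centreline=line) is None

    def test_history_escalates_confidence_threshold(self):
        poor = TrackState(position=np.array([100.0, 100.0]), velocity=np.zeros(2))
        for flag in [False] * 8 + [True, True]:
            poor.history.append(flag)
        # 0.6 passes the base 0.5 threshold but not the escalated 0.75
        d = det_at(100, 100, conf=0.6)
        gates = fs.GateConfig(min_confidence=0.5, min_history_rate=0.3,
                              escalation_factor=1.5)
        assert fs.filter_detections([d], poor, gates) is None
        healthy = TrackState(position=np.array([100.0, 100.0]), velocity=np.zeros(2))
        for _ in range(10):
            healthy.history.append(True)
        assert fs.filter_detections([d], healthy, gates) is d


class TestKalman:
    def test_converges_on_constant_velocity_path(self):
        state = TrackState(position=np.array([0.0, 0.0]), velocity=np.zeros(2))
        for t in range(1, 15):
            truth = np.array([2.0 * t, 1.0 * t])
            state = fs.kalman_step(state, truth)
        assert np.linalg.norm(state.position - np.array([28.0, 14.0])) < 0.5

    def test_coasts_linearly_through_dropout(self):
        state = TrackState(position=np.array([0.0, 0.0]), velocity=np.zeros(2))
        for t in range(1, 5):
            state = fs.kalman_step(state, np.array([2.0 * t, 0.0]))
        for t in range(5, 9):  # measurements withheld
            state = fs.kalman_step(state, None)
        assert abs(state.position[0] - 16.0) < 2.0
        assert state.frames_since_detection == 4

    def test_stationary_fixed_point(self):
        state = TrackState(position=np.array([5.0, 5.0]), velocity=np.zeros(2))
        z = np.array([10.0, 20.0])
        for _ in range(30):
            state = fs.kalman_step(state, z)
        assert np.linalg.norm(state.position - z) < 0.1

    def test_non_finite_measurement_treated_as_missing(self):
        state = TrackState(position=np.array([0.0, 0.0]), velocity=np.zeros(2))
        out = fs.kalman_step(state, np.array([np.nan, 1.0]))
        assert out.frames_since_detection == 1

    def test_covariance_stays_symmetric_psd(self, rng):
        kf = KalmanFilterCV()
        state = TrackState(position=np.zeros(2), velocity=np.zeros(2))
        for i in range(2000):
            z = rng.normal(0, 50, 2) if rng.random() > 0.3 else None
            conf = float(rng.uniform(0.05, 1.0))
            state = fs.kalman_step(state, z, confidence=conf, kf=kf)
            P = state.covariance
            assert np.allclose(P, P.T, atol=1e-9)
            assert np.linalg.eigvalsh(P).min() > -1e-9

    def test_low_confidence_pulls_less(self):
        kf = KalmanFilterCV()
        base = TrackState(position=np.array([0.0, 0.0]), velocity=np.zeros(2),
                          covariance=np.eye(4))
        z = np.array([10.0, 0.0])
        strong = fs.kalman_step(base, z, confidence=1.0, kf=kf)
        weak = fs.kalman_step(base, z, confidence=0.1, kf=kf)
        assert weak.position[0] < strong.position[0]


class TestMergeDuplicates:
    def test_overlapping_duplicates_keep_max_confidence(self):
        a = det_at(100, 100, conf=0.9)
        b = det_at(101, 100, conf=0.7)  # IoU ~0.82 with a
        kept = merge_duplicates([b, a])
        assert len(kept) == 1 and kept[0].confidence == 0.9

    def test_distinct_detections_survive(self):
        kept = merge_duplicates([det_at(50, 50), det_at(150, 150)])
        assert len(kept) == 2


class TestTrackSequence:
    def test_perfect_detector_yields_full_lsr(self, short_sequence):
        det = fs.mock_detector(fs.MockDetectorSpec(), short_sequence)
        res = fs.track_sequence(short_sequence.frames, det, fs.GateConfig())
        assert res.lsr == 1.0
        assert res.detection_lsr == 1.0

    def test_detection_lsr_counts_accepted_frames_only(self, short_sequence):
        """Drop exactly the 3rd frame's detections: 59/60 accepted."""
        base = fs.mock_detector(fs.MockDetectorSpec(), short_sequence)

        def detector(img, idx, origin):
            return [] if idx == 2 else base(img, idx, origin)

        res = fs.track_sequence(short_sequence.frames, detector, fs.GateConfig())
        assert res.detection_lsr == pytest.approx(59 / 60)
        assert res.lsr == 1.0  # the gap is Kalman-interpolated

    def test_mode_protocol(self, short_sequence):
        """LOCAL only after an accepted detection; GLOBAL re-entry after the
        coast budget is exhausted."""
        gates = fs.GateConfig(max_coast_frames=3)
        base = fs.mock_detector(fs.MockDetectorSpec(), short_sequence)
        dropout = set(range(10, 20))

        def detector(img, idx, origin):
            return [] if idx in dropout else base(img, idx, origin)

        res = fs.track_sequence(short_sequence.frames, detector, gates)
        assert res.modes[0] == "GLOBAL"  # confirmation pending on frame 0
        assert res.localized[0]  # ... but retroactively localized once confirmed
        assert res.modes[1] == "LOCAL"  # track confirmed
        assert res.modes[11] == "LOCAL"  # still coasting
        assert res.modes[13] == "GLOBAL"  # 3 misses exhausted the budget
        # reacquisition needs a two-frame confirmation again: frame 20 is
        # pending (retroactively localized), frame 21 back in LOCAL mode
        assert res.modes[21] == "LOCAL"
        assert res.localized[20] and res.localized[21]

    def test_perfect_detector_tracks_ground_truth(self, short_sequence):
        det = fs.mock_detector(fs.MockDetectorSpec(), short_sequence)
        res = fs.track_sequence(short_sequence.frames, det, fs.GateConfig())
        # after convergence the Kalman estimate follows the true path closely
        err = np.linalg.norm(res.positions[10:] - short_sequence.true_positions[10:], axis=1)
        assert err.max() < 2.0

    def test_clutter_never_perturbs_state(self, short_sequence):
        """False positives beyond max_step leave the trajectory untouched."""
        clean_det = fs.mock_detector(fs.MockDetectorSpec(), short_sequence)
        res_clean = fs.track_sequence(short_sequence.frames, clean_det, fs.GateConfig())

        base = fs.mock_detector(fs.MockDetectorSpec(), short_sequence)

        def cluttered(img, idx, origin):
            out = base(img, idx, origin)
            if idx > 0:  # far clutter, > max_step from any prediction
                out = out + [det_at(10, 10, conf=0.99)]
            return out

        res = fs.track_sequence(short_sequence.frames, cluttered, fs.GateConfig())
        np.testing.assert_allclose(res.positions[1:], res_clean.positions[1:], atol=1e-9)

    def test_detector_failure_counts_as_miss(self, short_sequence):
        def flaky(img, idx, origin):
            if idx == 5:
                raise RuntimeError("detector crashed")
            return fs.mock_detector(fs.MockDetectorSpec(), short_sequence)(img, idx, origin)

        res = fs.track_sequence(short_sequence.frames, flaky, fs.GateConfig())
        assert res.detection_localized[5] is False

    def test_track_log_csv(self, tmp_path, short_sequence):
        det = fs.mock_detector(fs.MockDetectorSpec(), short_sequence)
        res = fs.track_sequence(short_sequence.frames, det, fs.GateConfig())
        path = tmp_path / "log.csv"
        res.to_csv(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "frame,x,y,mode,localized"
        assert len(lines) == 61
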