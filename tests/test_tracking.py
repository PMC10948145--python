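"""Centroid tracking: linking, gap closing, kinematics."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from apodetect.pipeline import Detection
from apodetect.proposal import RoiBox
from apodetect.tracking import Track, track, track_kinematics


def det_at(x, y, t, prob=0.99, e=20):
    x0, y0 = int(round(x - e / 2)), int(round(y - e / 2))
    return Detection(t=t, box=RoiBox(t=t, x_min=x0, y_min=y0,
                                     x_max=x0 + e, y_max=y0 + e), prob=prob)


class TestTrackLinking:
    def test_static_object_gives_one_track(self):
        dets = [det_at(40, 40, t) for t in range(5)]
        tracks = track(dets)
        assert len(tracks) == 1 and len(tracks[0]) == 5

    def test_gap_of_two_frames_keeps_identity(self):
        dets = [det_at(40, 40, 0), det_at(40, 40, 1),
                det_at(45, 40, 4), det_at(45, 40, 5)]  # 2 missing frames, 5 px away
        tracks = track(dets, gap=3, dist_threshold=10)
        assert len(tracks) == 1 and len(tracks[0]) == 4

    def test_gap_of_four_frames_breaks_identity(self):
        dets = [det_at(40, 40, 0), det_at(40, 40, 1),
                det_at(42, 40, 6), det_at(42, 40, 7)]  # 4 missing frames
        tracks = track(dets, gap=3, dist_threshold=10)
        assert len(tracks) == 2

    def test_distance_threshold_blocks_linking(self):
        dets = [det_at(40, 40, 0), det_at(40, 40, 1),
                det_at(60, 40, 2), det_at(60, 40, 3)]  # 20 px jump
        tracks = track(dets, dist_threshold=10)
        assert len(tracks) == 2

    def test_short_tracks_are_discarded(self):
        dets = [det_at(10, 10, 0), det_at(80, 80, 3)]  # two singletons
        assert track(dets) == []

    def test_parallel_trajectories_match_optimal_assignment(self):
        """Well-separated parallel tracks: greedy equals the per-frame
        Hungarian assignment, with zero identity switches."""
        dets = []
        for t in range(10):
            dets.append(det_at(30 + 2 * t, 40, t))
            dets.append(det_at(30 + 2 * t, 90, t))  # 50 px apart
        tracks = track(dets, dist_threshold=10)
        assert len(tracks) == 2
        for tr in tracks:
            ys = {d.box.center[1] for d in tr.detections}
            assert len(ys) == 1  # never switches row

        # oracle: frame-by-frame optimal assignment
        prev = None
        for t in range(1, 10):
            cur = [d for d in dets if d.t == t]
            pre = [d for d in dets if d.t == t - 1]
            cost = np.array([[np.hypot(c.box.center[0] - p.box.center[0],
                                       c.box.center[1] - p.box.center[1])
                              for c in cur] for p in pre])
            ri, ci = linear_sum_assignment(cost)
            for i, j in zip(ri, ci):
                assert pre[i].box.center[1] == cur[j].box.center[1]

    def test_no_detection_is_shared_between_tracks(self, rng):
        dets = []
        for t in range(15):
            for _ in range(rng.integers(0, 5)):
                dets.append(det_at(float(rng.uniform(10, 190)),
                                   float(rng.uniform(10, 190)), t))
        tracks = track(dets)
        seen = set()
        for tr in tracks:
            frames = [d.t for d in tr.detections]
            assert frames == sorted(frames) and len(set(frames)) == len(frames)
            assert all(np.diff(frames) <= 3 + 1)
            assert len(tr) >= 2
            for d in tr.detections:
                assert id(d) not in seen
                seen.add(id(d))


class TestTrackKinematics:
    def test_static_track_has_zero_speed(self):
        pts = np.array([[5.0, 5.0]] * 6)
        out = track_kinematics(pts, frame_interval=1.0)
        np.testing.assert_array_equal(out["speed"], np.zeros(5))

    def test_constant_velocity_speed_in_physical_units(self):
        pts = np.array([[3.0 * t, 0.0] for t in range(5)])
        out = track_kinematics(pts, frame_interval=1.0, pixel_size=1.0)
        np.testing.assert_allclose(out["speed"], 3.0)

    def test_distance_to_reference_decreases_for_converging_track(self):
        pts = np.array([[50.0 - 4 * t, 50.0] for t in range(8)])
        out = track_kinematics(pts, reference_point=(10.0, 50.0))
        d = out["distance_to_reference"]
        assert (np.diff(d) < 0).all()

    def test_single_point_track_rejected(self):
        with pytest.raises(ValueError, match="length"):
            track_kinematics(np.array([[1.0, 2.0]]))

    def test_track_object_event_summary(self):
        dets = [det_at(40, 40 + t, t) for t in range(5)]
        (tr,) = track(dets)
        assert tr.event_time == 0
        x, y = tr.event_location
        assert x == 40 and y == 42
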