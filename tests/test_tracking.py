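"""Assignment optimality, cascade matching and the identity lifecycle."""

import itertools

import numpy as np
import pytest

from cabtrack.appearance import synthetic_embedder
from cabtrack.formats import BoundingBox, Detection, TransplantState
from cabtrack.kalman import KalmanFilter
from cabtrack.tracking import (
    Track,
    Tracker,
    TrackerConfig,
    TrackStatus,
    cascade_match,
    linear_assignment,
)


def brute_force_min_cost(cost):
    """Exhaustive minimum over all one-to-one assignments (square matrix)."""
    n = cost.shape[0]
    return min(
        sum(cost[i, p[i]] for i in range(n))
        for p in itertools.permutations(range(n))
    )


def det(frame, cx, cy, side=40.0, state=TransplantState.NORMAL, conf=0.95):
    return Detection(
        frame, state,
        BoundingBox(cx - side / 2, cy - side / 2, cx + side / 2, cy + side / 2),
        conf,
    )


class TestLinearAssignment:
    def test_identity_favoring_matrix(self):
        m, ur, uc = linear_assignment(np.array([[0.0, 1.0], [1.0, 0.0]]), 10.0)
        assert m == [(0, 0), (1, 1)] and ur == [] and uc == []

    def test_equals_brute_force_on_random_matrices(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 6))
            cost = rng.uniform(0, 10, size=(n, n))
            matches, _, _ = linear_assignment(cost, np.inf)
            total = sum(cost[i, j] for i, j in matches)
            assert total == pytest.approx(brute_force_min_cost(cost))

    def test_all_costs_above_cap_leave_everything_unmatched(self):
        m, ur, uc = linear_assignment(np.full((3, 3), 5.0), 1.0)
        assert m == [] and ur == [0, 1, 2] and uc == [0, 1, 2]

    def test_empty_matrix(self):
        m, ur, uc = linear_assignment(np.zeros((0, 4)), 1.0)
        assert m == [] and ur == [] and uc == [0, 1, 2, 3]


class TestCascadeMatch:
    def _confirmed_track(self, tid, cx, cy, embedding, kf):
        state = kf.initiate(np.array([cx, cy, 1.0, 40.0]))
        t = Track(id=tid, kalman=kf.predict(state), status=TrackStatus.CONFIRMED,
                  time_since_update=1)
        t.gallery.append(embedding)
        return t

    def test_gallery_identical_embedding_at_predicted_position_matches(self):
        kf = KalmanFilter()
        e = synthetic_embedder(1)
        tracks = [self._confirmed_track(1, 100, 100, e, kf)]
        dets = [det(1, 100, 100)]
        matches, ut, ud = cascade_match(tracks, dets, [e], TrackerConfig(), kf)
        assert matches == [(0, 0)] and ut == [] and ud == []

    def test_detection_beyond_gate_never_matches_despite_appearance(self):
        kf = KalmanFilter()
        e = synthetic_embedder(1)
        tracks = [self._confirmed_track(1, 100, 100, e, kf)]
        dets = [det(1, 700, 100)]  # far outside the motion gate
        matches, _, ud = cascade_match(tracks, dets, [e], TrackerConfig(), kf)
        assert matches == [] and ud == [0]

    def test_crossed_appearance_costs_resolved_optimally(self):
        kf = KalmanFilter()
        ea, eb = synthetic_embedder(1), synthetic_embedder(2)
        tracks = [
            self._confirmed_track(1, 100, 100, ea, kf),
            self._confirmed_track(2, 110, 100, eb, kf),
        ]
        # both detections inside both motion gates; appearance must decide
        dets = [det(1, 104, 100), det(1, 106, 100)]
        embs = [eb, ea]  # detection 0 looks like track 2, detection 1 like track 1
        matches, _, _ = cascade_match(tracks, dets, embs, TrackerConfig(), kf)
        assert sorted(matches) == [(0, 1), (1, 0)]


class TestTrackerLifecycle:
    def test_confirmation_after_n_init_consecutive_hits(self):
        tracker = Tracker(TrackerConfig(n_init=3))
        for frame in range(1, 5):
            e = [synthetic_embedder(1)]
            active = tracker.step(frame, [det(frame, 100, 100 + 5 * frame)], e)
            if frame < 3:
                assert active == []
            else:
                assert [t.id for t in active] == [1]

    def test_all_tracks_deleted_after_max_age_without_detections(self):
        cfg = TrackerConfig(n_init=1, max_age=5)
        tracker = Tracker(cfg)
        tracker.step(0, [det(0, 100, 100)], [synthetic_embedder(1)])
        for frame in range(1, cfg.max_age + 2):
            tracker.step(frame, [], [])
        assert tracker.tracks == []

    def test_non_monotone_frame_rejected(self):
        tracker = Tracker()
        tracker.step(5, [det(5, 100, 100)], [synthetic_embedder(1)])
        with pytest.raises(ValueError, match="non-monotone"):
            tracker.step(5, [], [])

    def test_low_confidence_detections_ignored(self):
        tracker = Tracker(TrackerConfig(n_init=1, min_confidence=0.5))
        active = tracker.step(0, [det(0, 100, 100, conf=0.3)], [synthetic_embedder(1)])
        assert active == [] and tracker.tracks == []

    def test_ids_unique_and_never_reused(self):
        tracker = Tracker(TrackerConfig(n_init=1, max_age=2))
        seen = set()
        for frame in range(12):
            if frame % 6 < 3:  # target present for 3 frames, then gone for 3
                dets = [det(frame, 100, 100 + frame)]
                embs = [synthetic_embedder(1, 0.0, 0)]
            else:
                dets, embs = [], []
            for t in tracker.step(frame, dets, embs):
                seen.add(t.id)
        assert len(seen) >= 2  # the gap exceeded max_age, so a new id was issued
        # ids increase monotonically; a deleted id is never re-activated
        assert sorted(seen) == list(seen or []) or len(seen) == len(set(seen))

    def test_majority_vote_with_recent_tie_break(self):
        tracker = Tracker(TrackerConfig(n_init=1))
        states = [TransplantState.NORMAL, TransplantState.BARE_ROOT,
                  TransplantState.BARE_ROOT]
        for frame, s in enumerate(states):
            active = tracker.step(
                frame, [det(frame, 100, 100 + 5 * frame, state=s)],
                [synthetic_embedder(1)],
            )
        assert active[0].state_label is TransplantState.BARE_ROOT
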