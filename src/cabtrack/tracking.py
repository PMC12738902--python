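"""Tracking-by-detection: gated appearance/IoU association and identity lifecycle.

The tracker follows the classic appearance-augmented SORT design. Per frame:

1. every track's motion state is propagated by the Kalman filter;
2. confirmed tracks are matched to detections in a *cascade* — rounds ordered
   by frames-since-last-update, so recently seen tracks get priority — using
   the minimum cosine distance between the detection embedding and the
   track's appearance gallery, with pairs failing the Mahalanobis motion gate
   (or the cosine threshold) forbidden;
3. leftovers plus tentative tracks are matched greedily-optimally on
   ``1 - IoU``;
4. matched tracks update, unmatched detections spawn tentative tracks,
   tracks unseen for more than ``max_age`` frames are deleted.

A track's class label is the majority vote of its matched detection labels,
ties broken by the most recent label.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import scipy.optimize

from .formats import BoundingBox, Detection, TransplantState
from .kalman import CHI2_GATE_4DOF, KalmanFilter, KalmanState

INFTY_COST = 1e5


@dataclass
class TrackerConfig:
    max_cosine_distance: float = 0.2
    gating_threshold: float = CHI2_GATE_4DOF
    iou_threshold: float = 0.3
    max_age: int = 30
    n_init: int = 3
    nn_budget: int = 100
    min_confidence: float = 0.5

    def __post_init__(self) -> None:
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        for name in ("max_cosine_distance", "gating_threshold", "iou_threshold",
                     "max_age", "nn_budget"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def linear_assignment(
    cost_matrix: np.ndarray, max_cost: float
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Minimum-cost one-to-one assignment with a per-pair cost cap.

    Returns ``(matches, unmatched_rows, unmatched_cols)``. Pairs whose cost
    exceeds ``max_cost`` are dropped from the optimal assignment and their
    row/column reported unmatched. An empty matrix yields no matches.
    """
    cost_matrix = np.atleast_2d(np.asarray(cost_matrix, dtype=float))
    if cost_matrix.size == 0:
        return [], list(range(cost_matrix.shape[0])), list(range(cost_matrix.shape[1]))
    if not np.all(np.isfinite(cost_matrix)):
        raise ValueError("cost matrix must be finite; use a large cap cost instead")
    rows, cols = scipy.optimize.linear_sum_assignment(cost_matrix)
    matches, unmatched_rows, unmatched_cols = [], [], []
    matched_r, matched_c = set(), set()
    for r, c in zip(rows, cols):
        if cost_matrix[r, c] > max_cost:
            continue
        matches.append((int(r), int(c)))
        matched_r.add(int(r))
        matched_c.add(int(c))
    unmatched_rows = [r for r in range(cost_matrix.shape[0]) if r not in matched_r]
    unmatched_cols = [c for c in range(cost_matrix.shape[1]) if c not in matched_c]
    return matches, unmatched_rows, unmatched_cols


class TrackStatus(Enum):
    TENTATIVE = "tentative"
    CONFIRMED = "confirmed"
    DELETED = "deleted"


@dataclass
class Track:
    """One tracked identity: motion state, appearance gallery, class votes."""

    id: int
    kalman: KalmanState
    status: TrackStatus = TrackStatus.TENTATIVE
    gallery: deque = field(default_factory=deque)  # ring buffer of embeddings
    class_votes: Counter = field(default_factory=Counter)
    last_label: TransplantState | None = None
    hits: int = 1
    time_since_update: int = 0

    @property
    def state_label(self) -> TransplantState:
        """Majority vote over matched detection labels; ties -> most recent."""
        if not self.class_votes:
            raise ValueError(f"track {self.id} has no class votes")
        top = self.class_votes.most_common()
        best = [s for s, n in top if n == top[0][1]]
        if len(best) == 1:
            return best[0]
        return self.last_label if self.last_label in best else best[0]

    def to_box(self) -> BoundingBox:
        cx, cy, a, h = self.kalman.mean[:4]
        return BoundingBox.from_xyah(cx, cy, max(a, 1e-6), max(h, 1e-6))

    def appearance_cost(self, embedding: np.ndarray) -> float:
        if not self.gallery:
            return INFTY_COST
        gallery = np.asarray(self.gallery)
        return float(np.min(1.0 - gallery @ np.asarray(embedding)))


def _iou_cost(tracks: list[Track], detections: list[Detection]) -> np.ndarray:
    from .formats import iou

    cost = np.ones((len(tracks), len(detections)))
    for i, t in enumerate(tracks):
        tb = t.to_box()
        for j, d in enumerate(detections):
            cost[i, j] = 1.0 - iou(tb, d.box)
    return cost


def cascade_match(
    tracks: list[Track],
    detections: list[Detection],
    embeddings: list[np.ndarray],
    config: TrackerConfig,
    kf: KalmanFilter,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Appearance association in rounds of increasing track staleness.

    ``tracks`` are the confirmed tracks. Within each round the appearance
    cost matrix (min cosine distance to gallery) is solved optimally, with
    entries failing the Mahalanobis gate or the cosine threshold capped out.
    Returns (matches, unmatched_track_idx, unmatched_det_idx).
    """
    unmatched_dets = list(range(len(detections)))
    matches: list[tuple[int, int]] = []
    if detections:
        measurements = np.array([d.box.to_xyah() for d in detections])
    for age in range(1, config.max_age + 1):
        if not unmatched_dets:
            break
        round_tracks = [i for i, t in enumerate(tracks) if t.time_since_update == age]
        if not round_tracks:
            continue
        cost = np.full((len(round_tracks), len(unmatched_dets)), INFTY_COST)
        for ri, ti in enumerate(round_tracks):
            gate = kf.gating_distance(tracks[ti].kalman, measurements[unmatched_dets])
            for rj, dj in enumerate(unmatched_dets):
                c = tracks[ti].appearance_cost(embeddings[dj])
                if c > config.max_cosine_distance or gate[rj] > config.gating_threshold:
                    c = INFTY_COST
                cost[ri, rj] = c
        m, _, _ = linear_assignment(cost, config.max_cosine_distance)
        for ri, rj in m:
            matches.append((round_tracks[ri], unmatched_dets[rj]))
        for _, rj in sorted(m, key=lambda p: -p[1]):
            unmatched_dets.pop(rj)
    matched_tracks = {i for i, _ in matches}
    unmatched_tracks = [i for i in range(len(tracks)) if i not in matched_tracks]
    return matches, unmatched_tracks, unmatched_dets


class Tracker:
    """Online multi-object tracker over per-frame classified detections."""

    def __init__(
        self,
        config: TrackerConfig | None = None,
        kf: KalmanFilter | None = None,
    ) -> None:
        self.config = config or TrackerConfig()
        self.kf = kf or KalmanFilter()
        self.tracks: list[Track] = []
        self._next_id = 1
        self._last_frame: int | None = None

    def step(
        self,
        frame: int,
        detections: list[Detection],
        embeddings: list[np.ndarray] | None = None,
    ) -> list[Track]:
        """Advance one frame; returns the active confirmed tracks.

        All detections must carry ``frame``; the index must be strictly
        greater than the previous step's. ``embeddings`` aligns with
        ``detections``; when ``None`` the appearance cascade is skipped and
        association falls back to gated IoU only.
        """
        if self._last_frame is not None and frame <= self._last_frame:
            raise ValueError(
                f"non-monotone frame index {frame} (last was {self._last_frame})"
            )
        if any(d.frame != frame for d in detections):
            raise ValueError("all detections must belong to the stepped frame")
        self._last_frame = frame

        keep = [i for i, d in enumerate(detections)
                if d.confidence >= self.config.min_confidence]
        detections = [detections[i] for i in keep]
        if embeddings is not None:
            embeddings = [embeddings[i] for i in keep]

        for t in self.tracks:
            t.kalman = self.kf.predict(t.kalman)
            t.time_since_update += 1

        confirmed = [t for t in self.tracks if t.status is TrackStatus.CONFIRMED]
        tentative = [t for t in self.tracks if t.status is TrackStatus.TENTATIVE]

        if embeddings is not None and confirmed:
            matches_a, unmatched_confirmed, unmatched_dets = cascade_match(
                confirmed, detections, embeddings, self.config, self.kf
            )
        else:
            matches_a, unmatched_confirmed, unmatched_dets = (
                [], list(range(len(confirmed))), list(range(len(detections)))
            )
        matched_pairs = [(confirmed[i], j) for i, j in matches_a]

        # IoU stage: tentative tracks plus confirmed ones missed only this frame
        iou_tracks = tentative + [
            confirmed[i] for i in unmatched_confirmed
            if confirmed[i].time_since_update == 1
        ]
        stale = [confirmed[i] for i in unmatched_confirmed
                 if confirmed[i].time_since_update > 1]
        remaining = [detections[j] for j in unmatched_dets]
        cost = _iou_cost(iou_tracks, remaining)
        # motion gate also applies to the IoU stage
        if len(iou_tracks) and len(remaining):
            meas = np.array([d.box.to_xyah() for d in remaining])
            for i, t in enumerate(iou_tracks):
                gate = self.kf.gating_distance(t.kalman, meas)
                cost[i, gate > self.config.gating_threshold] = INFTY_COST
        matches_b, unmatched_iou, unmatched_rem = linear_assignment(
            cost, 1.0 - self.config.iou_threshold
        )
        # translate indices over `remaining` back into the detection list
        matched_pairs += [(iou_tracks[i], unmatched_dets[j]) for i, j in matches_b]
        final_unmatched_dets = [unmatched_dets[j] for j in unmatched_rem]
        missed_tracks = stale + [iou_tracks[i] for i in unmatched_iou]

        for track, j in matched_pairs:
            det = detections[j]
            track.kalman = self.kf.update(track.kalman, np.array(det.box.to_xyah()))
            if embeddings is not None:
                track.gallery.append(embeddings[j])
                while len(track.gallery) > self.config.nn_budget:
                    track.gallery.popleft()
            track.class_votes[det.state] += 1
            track.last_label = det.state
            track.hits += 1
            track.time_since_update = 0
            if track.status is TrackStatus.TENTATIVE and track.hits >= self.config.n_init:
                track.status = TrackStatus.CONFIRMED

        for track in missed_tracks:
            if track.status is TrackStatus.TENTATIVE:
                track.status = TrackStatus.DELETED
            elif track.time_since_update > self.config.max_age:
                track.status = TrackStatus.DELETED

        for j in final_unmatched_dets:
            self._initiate(detections[j],
                           embeddings[j] if embeddings is not None else None)

        self.tracks = [t for t in self.tracks if t.status is not TrackStatus.DELETED]
        return [t for t in self.tracks
                if t.status is TrackStatus.CONFIRMED and t.time_since_update == 0]

    def _initiate(self, det: Detection, embedding: np.ndarray | None) -> None:
        state = self.kf.initiate(np.array(det.box.to_xyah()))
        track = Track(id=self._next_id, kalman=state)
        self._next_id += 1
        if embedding is not None:
            track.gallery.append(embedding)
        track.class_votes[det.state] += 1
        track.last_label = det.state
        if self.config.n_init <= 1:
            track.status = TrackStatus.CONFIRMED
        self.tracks.append(track)
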