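"""Link per-frame detections into event tracks by centroid distance.

Greedy nearest-neighbor assignment: at each frame, candidate
(track, detection) pairs within the distance threshold are processed in
increasing distance order (ties broken by lower track id, then lower
detection index); unmatched detections open new tracks; a track not
updated for more than ``gap`` frames closes; tracks with fewer than two
detections are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .pipeline import Detection

__all__ = ["Track", "track", "track_kinematics"]


@dataclass
class Track:
    """A time-ordered sequence of detections sharing an identity."""

    track_id: int
    detections: List[Detection] = field(default_factory=list)

    @property
    def start_t(self) -> int:
        return self.detections[0].t

    @property
    def end_t(self) -> int:
        return self.detections[-1].t

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def centroids(self) -> np.ndarray:
        return np.array([d.box.center for d in self.detections])

    @property
    def event_time(self) -> int:
        """Event time for evaluation: the track's first frame."""
        return self.start_t

    @property
    def event_location(self) -> Tuple[float, float]:
        """Event location for evaluation: the median of the centroids."""
        c = self.centroids
        return float(np.median(c[:, 0])), float(np.median(c[:, 1]))


def track(
    detections: Sequence[Detection],
    gap: int = 3,
    dist_threshold: float = 10.0,
) -> List[Track]:
    """Link detections into tracks; see module docstring for the rules."""
    by_frame: Dict[int, List[Detection]] = {}
    for d in detections:
        by_frame.setdefault(d.t, []).append(d)

    next_id = 0
    live: List[Track] = []
    done: List[Track] = []
    for t in sorted(by_frame):
        # a track may be missing for at most `gap` consecutive frames:
        # reappearing after m missing frames keeps the identity iff m <= gap
        still_live = []
        for tr in live:
            if t - tr.end_t > gap + 1:
                done.append(tr)
            else:
                still_live.append(tr)
        live = still_live

        dets = by_frame[t]
        pairs = []
        for ti, tr in enumerate(live):
            lx, ly = tr.detections[-1].box.center
            for di, d in enumerate(dets):
                cx, cy = d.box.center
                dist = float(np.hypot(cx - lx, cy - ly))
                if dist <= dist_threshold:
                    pairs.append((dist, tr.track_id, di, ti))
        pairs.sort()
        used_tracks, used_dets = set(), set()
        for dist, tid, di, ti in pairs:
            if ti in used_tracks or di in used_dets:
                continue
            live[ti].detections.append(dets[di])
            used_tracks.add(ti)
            used_dets.add(di)
        for di, d in enumerate(dets):
            if di not in used_dets:
                live.append(Track(track_id=next_id, detections=[d]))
                next_id += 1

    done.extend(live)
    kept = [tr for tr in done if len(tr) >= 2]
    kept.sort(key=lambda tr: (tr.start_t, tr.track_id))
    return kept


def track_kinematics(
    trajectory,
    frame_interval: float = 1.0,
    pixel_size: Optional[float] = None,
    reference_point: Optional[Tuple[float, float]] = None,
) -> dict:
    """Per-step speed and (optionally) distance-to-reference series.

    ``trajectory`` is a :class:`Track` or an (n, 2) array of centroids.
    Speeds are micrometres/minute when ``pixel_size`` is given, else
    pixels/frame (with ``frame_interval`` = 1).  Distances are in the
    same spatial unit.
    """
    if isinstance(trajectory, Track):
        pts = trajectory.centroids
    else:
        pts = np.asarray(trajectory, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("trajectory must be (n, 2) centroids")
    scale = pixel_size if pixel_size is not None else 1.0
    out = {}
    if len(pts) < 2:
        raise ValueError("speed needs a trajectory of length >= 2")
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1) * scale
    out["speed"] = steps / frame_interval
    if reference_point is not None:
        ref = np.asarray(reference_point, dtype=float)
        out["distance_to_reference"] = np.linalg.norm(pts - ref, axis=1) * scale
    return out
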