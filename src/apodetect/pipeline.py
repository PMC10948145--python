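"""Full-movie inference: proposal -> clip -> classify -> threshold -> NMS.

For every frame the proposer emits candidate boxes; each box yields a
fixed 59 x 59 clip centered on the box centroid, cut from a temporal
window of ``window_frames`` frames around the current frame (clamped at
movie edges by replication) and uniformly subsampled to the classifier's
K input frames.  Boxes whose apoptosis probability reaches the threshold
survive greedy per-frame non-maximum suppression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .data import extract_clip
from .io import Timelapse
from .proposal import ProposalConfig, RoiBox, propose

__all__ = [
    "PipelineConfig", "Detection", "window_indices", "detect", "nms",
    "probability_heatmap", "cumulative_counts",
]


@dataclass
class PipelineConfig:
    """Deployment settings.

    ``prob_threshold`` defaults to the stringent in-vitro value 0.995
    (use 0.95 for the in-vivo regime); the temporal window of nine frames
    matches the expected duration of the morphological event.
    """

    window_frames: int = 9
    clip_len: int = 5
    prob_threshold: float = 0.995
    nms_overlap: float = 0.1
    proposal: ProposalConfig = field(default_factory=ProposalConfig)
    batch_size: int = 512

    def __post_init__(self) -> None:
        if not 0 < self.prob_threshold < 1:
            raise ValueError("prob_threshold must be in (0, 1)")
        if not 0 <= self.nms_overlap <= 1:
            raise ValueError("nms_overlap must be in [0, 1]")


@dataclass
class Detection:
    """A positive classification localized in space (box) and time (frame)."""

    t: int
    box: RoiBox
    prob: float

    @property
    def center(self):
        return self.box.center


def window_indices(t: int, window: int = 9, K: int = 5, T: int = 10**9) -> np.ndarray:
    """K frame indices subsampled from the window of ``window`` frames
    centered on t, clamped to [0, T-1] by edge replication; first and last
    of the (clamped) window are always included."""
    if not 0 <= t < T:
        raise ValueError(f"t={t} outside [0, {T})")
    half = window // 2
    ts = np.clip(np.arange(t - half, t - half + window), 0, T - 1)
    sel = np.floor(np.linspace(0, window - 1, K) + 0.5).astype(int)
    return ts[sel]


def nms(detections: Sequence[Detection], overlap_threshold: float = 0.1) -> List[Detection]:
    """Greedy non-maximum suppression within one frame.

    Detections are visited in decreasing probability (ties broken by
    input order); a kept box suppresses every remaining box whose IoU
    with it is strictly greater than ``overlap_threshold``.
    """
    if not detections:
        return []
    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i].prob, i))
    kept: List[Detection] = []
    suppressed = set()
    for i in order:
        if i in suppressed:
            continue
        kept.append(detections[i])
        for j in order:
            if j == i or j in suppressed:
                continue
            if detections[i].box.iou(detections[j].box) > overlap_threshold:
                suppressed.add(j)
    return kept


def detect(movie: Timelapse, model, cfg: Optional[PipelineConfig] = None) -> List[Detection]:
    """Run the full detection pipeline over a movie.

    The movie must be 8-bit (run :func:`~apodetect.io.normalize_to_uint8`
    first).  Returns per-frame detections, NMS-applied, sorted by frame
    then decreasing probability.
    """
    cfg = cfg or PipelineConfig()
    if movie.bit_depth != 8:
        raise ValueError("movie must be normalized to 8-bit before detection")
    frames = movie.frames
    T = frames.shape[0]

    candidates: List[RoiBox] = []
    clips: List[np.ndarray] = []
    for t in range(T):
        for box in propose(frames[t], cfg.proposal, t=t):
            cx, cy = box.center
            clips.append(extract_clip(frames, cx, cy, t,
                                      window=cfg.window_frames, K=cfg.clip_len))
            candidates.append(box)
    if not candidates:
        return []

    X = np.stack(clips)
    probs = np.concatenate([
        model.predict_proba(X[s:s + cfg.batch_size])[:, 1]
        for s in range(0, len(X), cfg.batch_size)
    ])

    by_frame = {}
    for box, p in zip(candidates, probs):
        if p >= cfg.prob_threshold:
            by_frame.setdefault(box.t, []).append(Detection(t=box.t, box=box, prob=float(p)))
    out: List[Detection] = []
    for t in sorted(by_frame):
        out.extend(sorted(nms(by_frame[t], cfg.nms_overlap),
                          key=lambda d: -d.prob))
    return out


def probability_heatmap(
    detections: Sequence[Detection],
    movie_shape,
    per_frame: bool = False,
    sigma_frac: float = 0.25,
) -> np.ndarray:
    """Gaussian-splat detection probabilities into a spatial map in [0, 1].

    Each detection spreads its probability over its box with a Gaussian
    weight (sigma = ``sigma_frac`` x box edge); the map aggregates over
    time by per-pixel maximum.  ``per_frame=True`` returns the (T, H, W)
    stack instead of the single aggregated map.
    """
    if len(movie_shape) == 3:
        T, H, W = movie_shape
    else:
        H, W = movie_shape
        T = (max(d.t for d in detections) + 1) if detections else 1
    stack = np.zeros((T, H, W), dtype=np.float32) if per_frame else None
    flat = np.zeros((H, W), dtype=np.float32)
    for d in detections:
        cx, cy = d.box.center
        sx = max(1.0, sigma_frac * d.box.width)
        sy = max(1.0, sigma_frac * d.box.height)
        ext = int(np.ceil(3 * max(sx, sy)))
        x0, x1 = max(0, int(cx) - ext), min(W, int(cx) + ext + 1)
        y0, y1 = max(0, int(cy) - ext), min(H, int(cy) + ext + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        ys, xs = np.mgrid[y0:y1, x0:x1]
        w = d.prob * np.exp(-0.5 * (((xs - cx) / sx) ** 2 + ((ys - cy) / sy) ** 2))
        if per_frame:
            np.maximum(stack[d.t, y0:y1, x0:x1], w, out=stack[d.t, y0:y1, x0:x1])
        np.maximum(flat[y0:y1, x0:x1], w, out=flat[y0:y1, x0:x1])
    out = stack if per_frame else flat
    return np.clip(out, 0.0, 1.0)


def cumulative_counts(events, T: Optional[int] = None) -> np.ndarray:
    """Nondecreasing per-frame cumulative event count.

    ``events`` may be tracks (counted at their first frame), detections,
    or any objects with a ``t`` attribute / plain frame integers.
    """
    times = []
    for e in events:
        if hasattr(e, "start_t"):
            times.append(e.start_t)
        elif hasattr(e, "t"):
            times.append(e.t)
        else:
            times.append(int(e))
    if T is None:
        T = (max(times) + 1) if times else 1
    counts = np.zeros(T, dtype=int)
    for t in times:
        counts[min(t, T - 1)] += 1
    return np.cumsum(counts)
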