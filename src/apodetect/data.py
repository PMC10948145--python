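"""Build labeled clip sequences from movies and annotations.

A *clip sequence* is the classifier's input unit: K grayscale 59 x 59
crops of the same spatial window at increasing frames.  This module
implements training-crop extraction around point annotations, the
loader's fixed-length uniform subsampling, frame-consistent 2D
augmentation, hard-negative mining, and train/validation assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi

from .io import EventAnnotation, Timelapse
from .proposal import RoiBox

__all__ = [
    "ClipSequence", "LoaderConfig", "CLIP_SIZE",
    "extract_clip", "extract_training_crops", "sample_fixed_length",
    "augment2d", "mine_hard_negatives", "assemble_training_set",
]

CLIP_SIZE = 59  # spatial size of classifier input crops (pixels)


@dataclass
class ClipSequence:
    """K stacked 59 x 59 crops with label and provenance."""

    frames: np.ndarray  # (K, 59, 59) uint8
    label: int
    center_t: int = 0
    source_box: Optional[RoiBox] = None
    movie_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (CLIP_SIZE, CLIP_SIZE):
            raise ValueError(
                f"clip frames must be (K, {CLIP_SIZE}, {CLIP_SIZE}); got {self.frames.shape}"
            )
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")

    @property
    def clip_len(self) -> int:
        return self.frames.shape[0]


@dataclass
class LoaderConfig:
    """Sampling and augmentation settings for the training loader."""

    clip_len: int = 5
    shift_frac: float = 0.1       # max |shift| as a fraction of crop size
    zoom_range: Tuple[float, float] = (0.9, 1.1)
    rotation_deg: float = 20.0    # max |rotation|
    flip_horizontal: bool = True
    flip_vertical: bool = True
    class_ratio: float = 1.0      # negatives per positive
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clip_len < 2:
            raise ValueError("clip_len must be >= 2")
        if self.class_ratio < 1:
            raise ValueError("class_ratio must be >= 1")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x) + 0.5).astype(int)


def _crop_padded(frame: np.ndarray, x: float, y: float, size: int = CLIP_SIZE) -> np.ndarray:
    """Crop a size x size window centered on (x, y), symmetric-padding borders."""
    H, W = frame.shape
    half = size // 2
    cx, cy = int(round(x)), int(round(y))
    x0, x1 = cx - half, cx - half + size
    y0, y1 = cy - half, cy - half + size
    pad_l, pad_t = max(0, -x0), max(0, -y0)
    pad_r, pad_b = max(0, x1 - W), max(0, y1 - H)
    sub = frame[max(0, y0):min(H, y1), max(0, x0):min(W, x1)]
    if pad_l or pad_r or pad_t or pad_b:
        sub = np.pad(sub, ((pad_t, pad_b), (pad_l, pad_r)), mode="symmetric")
    return sub


def sample_fixed_length(frames: np.ndarray, K: int = 5) -> np.ndarray:
    """Uniformly subsample a stack of frames to exactly K frames.

    Indices are ``round(linspace(0, L-1, K))`` with ties rounded up, so the
    first and last frames are always included when L >= K; shorter inputs
    repeat edge frames.
    """
    frames = np.asarray(frames)
    L = frames.shape[0]
    if L < 1:
        raise ValueError("input stack is empty")
    idx = _round_half_up(np.linspace(0, L - 1, K))
    return frames[idx]


def extract_clip(
    frames: np.ndarray,
    x: float,
    y: float,
    t_center: int,
    window: int = 9,
    K: int = 5,
    size: int = CLIP_SIZE,
) -> np.ndarray:
    """Cut the K x size x size clip around (x, y, t_center).

    The temporal window of ``window`` frames centered on ``t_center`` is
    clamped to the movie by edge replication, then uniformly subsampled to
    K frames (first and last included).
    """
    T = frames.shape[0]
    half = window // 2
    ts = np.clip(np.arange(t_center - half, t_center - half + window), 0, T - 1)
    sel = ts[_round_half_up(np.linspace(0, window - 1, K))]
    return np.stack([_crop_padded(frames[t], x, y, size) for t in sel])


def extract_training_crops(
    movie: Timelapse,
    annotations: Sequence[EventAnnotation],
    window_minutes: Tuple[float, float] = (-10.0, 50.0),
    n_steps: int = 7,
) -> List[ClipSequence]:
    """Extract fixed-location crop sequences around each annotation.

    For every annotation the 59 x 59 spatial window centered on (x, y) is
    cropped at ``n_steps`` frames whose times are linearly spaced over
    ``window_minutes`` relative to the annotated frame, converted to the
    nearest frame index and clamped to the movie; border crops are
    symmetric-padded.
    """
    T, H, W = movie.frames.shape
    if H < CLIP_SIZE or W < CLIP_SIZE:
        raise ValueError(f"movie frames {H}x{W} smaller than the {CLIP_SIZE} px crop")
    offsets_min = np.linspace(window_minutes[0], window_minutes[1], n_steps)
    frame_offsets = _round_half_up(offsets_min / movie.frame_interval)
    out = []
    for ann in annotations:
        ann.validate_against(movie)
        ts = np.clip(ann.t + frame_offsets, 0, T - 1)
        stack = np.stack([_crop_padded(movie.frames[t], ann.x, ann.y) for t in ts])
        out.append(
            ClipSequence(
                frames=stack, label=ann.label, center_t=ann.t, movie_id=movie.source_id
            )
        )
    return out


def augment2d(
    clip: ClipSequence,
    cfg: Optional[LoaderConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> ClipSequence:
    """Apply one random draw of shift / zoom / rotation / flips to a clip.

    The same geometric transform is applied to every frame, so temporal
    structure (and the label) is preserved.  Out-of-frame samples are
    filled by mirror (symmetric) boundary handling.
    """
    cfg = cfg or LoaderConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    K, H, W = clip.frames.shape

    shift = rng.uniform(-cfg.shift_frac, cfg.shift_frac, size=2) * (H, W)
    zoom = rng.uniform(*cfg.zoom_range) if cfg.zoom_range != (1.0, 1.0) else 1.0
    angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
    flip_h = cfg.flip_horizontal and rng.random() < 0.5
    flip_v = cfg.flip_vertical and rng.random() < 0.5

    identity = (
        shift[0] == 0 and shift[1] == 0 and zoom == 1.0 and angle == 0.0
        and not flip_h and not flip_v
    )
    if identity:
        return ClipSequence(clip.frames.copy(), clip.label, clip.center_t,
                            clip.source_box, clip.movie_id)

    theta = np.deg2rad(angle)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    mat = rot / zoom  # inverse mapping: output -> input
    center = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
    offset = center - mat @ (center + shift)

    out = np.empty_like(clip.frames)
    for k in range(K):
        f = clip.frames[k].astype(np.float32)
        if flip_h:
            f = f[:, ::-1]
        if flip_v:
            f = f[::-1, :]
        g = ndi.affine_transform(f, mat, offset=offset, order=1, mode="mirror")
        out[k] = np.clip(np.round(g), 0, 255).astype(clip.frames.dtype)
    return ClipSequence(out, clip.label, clip.center_t, clip.source_box, clip.movie_id)


def mine_hard_negatives(model, control_movies: Sequence[Timelapse], pipeline_config=None) -> List[ClipSequence]:
    """Collect label-0 clips from pipeline detections on event-free movies.

    Control movies contain no true events, so every detection the pipeline
    emits on them is a false positive; its clip is exported to enrich the
    negative class for retraining.
    """
    from .pipeline import PipelineConfig, detect

    cfg = pipeline_config or PipelineConfig()
    out = []
    for movie in control_movies:
        for det in detect(movie, model, cfg):
            cx, cy = det.box.center
            frames = extract_clip(
                movie.frames, cx, cy, det.t, window=cfg.window_frames, K=cfg.clip_len
            )
            out.append(
                ClipSequence(frames=frames, label=0, center_t=det.t,
                             source_box=det.box, movie_id=movie.source_id)
            )
    return out


def assemble_training_set(
    positives: Sequence[ClipSequence],
    negatives: Sequence[ClipSequence],
    ratio: float = 10.0,
    val_frac: float = 0.12,
    folds: Optional[int] = None,
    seed: int = 0,
):
    """Combine classes at a fixed negative:positive ratio and split.

    With ``folds=None`` returns ``(train, val)`` from a shuffled
    ``val_frac`` split.  With ``folds=k`` returns a list of k
    ``(train, val)`` pairs grouped by ``movie_id`` so no movie appears on
    both sides of a fold.
    """
    rng = np.random.default_rng(seed)
    n_neg = int(round(ratio * len(positives)))
    if n_neg > len(negatives):
        raise ValueError(
            f"need {n_neg} negatives for ratio {ratio}:1 but only {len(negatives)} available"
        )
    neg_idx = rng.permutation(len(negatives))[:n_neg]
    pool = list(positives) + [negatives[i] for i in neg_idx]

    if folds is None:
        order = rng.permutation(len(pool))
        n_val = int(round(val_frac * len(pool)))
        val = [pool[i] for i in order[:n_val]]
        train = [pool[i] for i in order[n_val:]]
        return train, val

    movie_ids = sorted({c.movie_id for c in pool})
    if len(movie_ids) < folds:
        raise ValueError(f"{folds}-fold split needs >= {folds} distinct movies")
    perm = [movie_ids[i] for i in rng.permutation(len(movie_ids))]
    groups = [set(perm[i::folds]) for i in range(folds)]
    splits = []
    for g in groups:
        val = [c for c in pool if c.movie_id in g]
        train = [c for c in pool if c.movie_id not in g]
        splits.append((train, val))
    return splits


def clips_to_arrays(clips: Sequence[ClipSequence]):
    """Stack clips into ``(X, y)`` arrays for the classifier."""
    X = np.stack([c.frames for c in clips])
    y = np.array([c.label for c in clips], dtype=np.int64)
    return X, y
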