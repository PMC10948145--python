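"""Candidate-region proposal per frame.

Two interchangeable proposers produce bounding boxes that may contain a
dying cell:

* ``selective_search`` — a graph-based over-segmentation (Felzenszwalb)
  followed by iterative merging of adjacent regions by intensity and size
  similarity, emitting one box per region at every merge level.  Movies are
  grayscale, so the similarity uses intensity and size terms only.
* ``blob`` — intensity threshold + connected components, each component
  dilated/clamped to a box with edges in the accepted range.  Deterministic
  and cheap; the default for large batch runs.

All proposals then pass a size filter (both edges within
``[min_edge, max_edge]`` pixels, inclusive) and a brightness filter (8-bit
mean intensity inside the box >= ``min_brightness``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.segmentation import felzenszwalb

__all__ = ["RoiBox", "ProposalConfig", "propose", "filter_boxes"]


@dataclass
class RoiBox:
    """A half-open bounding box ``[x_min, x_max) x [y_min, y_max)`` at frame t."""

    t: int
    x_min: int
    y_min: int
    x_max: int
    y_max: int
    mean_intensity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValueError("box must have positive width and height")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def center(self) -> Tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    @property
    def area(self) -> int:
        return self.width * self.height

    def iou(self, other: "RoiBox") -> float:
        ix = max(0, min(self.x_max, other.x_max) - max(self.x_min, other.x_min))
        iy = max(0, min(self.y_max, other.y_max) - max(self.y_min, other.y_min))
        inter = ix * iy
        if inter == 0:
            return 0.0
        return inter / (self.area + other.area - inter)


@dataclass
class ProposalConfig:
    """Settings for the per-frame region proposal stage."""

    method: str = "blob"  # "blob" | "selective_search"
    min_edge: int = 20
    max_edge: int = 40
    min_brightness: float = 40.0
    # blob proposer
    blob_threshold: Optional[float] = None  # None -> Otsu per frame
    blob_min_distance: int = 6              # min px between intensity peaks
    blob_smooth_sigma: float = 1.5
    # selective-search proposer
    fz_scale: float = 50.0
    fz_sigma: float = 0.8
    fz_min_size: int = 20
    similarity_floor: float = 0.75


def _clamp_box(cx: float, cy: float, edge_x: int, edge_y: int, H: int, W: int):
    """Center a box of the given edges on (cx, cy), shifted to stay in-frame."""
    edge_x, edge_y = min(edge_x, W), min(edge_y, H)
    x0 = int(round(cx - edge_x / 2.0))
    y0 = int(round(cy - edge_y / 2.0))
    x0 = max(0, min(x0, W - edge_x))
    y0 = max(0, min(y0, H - edge_y))
    return x0, y0, x0 + edge_x, y0 + edge_y


def _blob_boxes(frame: np.ndarray, t: int, cfg: ProposalConfig) -> List[RoiBox]:
    """Threshold + connected components, split by local intensity peaks.

    Confluent cells merge into one thresholded component, so a box per
    component would drift off either cell; instead each local maximum of
    the smoothed frame gets its own box, sized from its component's area
    share and clamped to the accepted edge range.
    """
    thr = cfg.blob_threshold
    if thr is None:
        vals = frame.ravel()
        if vals.max() == vals.min():
            return []
        thr = threshold_otsu(vals)
    mask = frame > thr
    if not mask.any():
        return []
    smooth = ndi.gaussian_filter(frame.astype(np.float32), cfg.blob_smooth_sigma)
    peaks = peak_local_max(smooth, min_distance=cfg.blob_min_distance,
                           threshold_abs=float(thr), exclude_border=False)
    if len(peaks) == 0:
        return []
    lab = cc_label(mask, connectivity=2)
    areas = np.bincount(lab.ravel())
    peak_labels = lab[peaks[:, 0], peaks[:, 1]]
    n_peaks_per_comp = np.bincount(peak_labels, minlength=areas.size)
    H, W = frame.shape
    boxes = []
    for (py, px), pl in zip(peaks, peak_labels):
        if pl == 0:
            share = cfg.min_edge ** 2
        else:
            share = areas[pl] / max(1, n_peaks_per_comp[pl])
        edge = int(np.clip(round(1.6 * np.sqrt(share)), cfg.min_edge, cfg.max_edge))
        bx0, by0, bx1, by1 = _clamp_box(float(px), float(py), edge, edge, H, W)
        boxes.append(RoiBox(t=t, x_min=bx0, y_min=by0, x_max=bx1, y_max=by1))
    return boxes


class _Region:
    __slots__ = ("size", "inten_sum", "bbox")

    def __init__(self, size, inten_sum, bbox):
        self.size = size
        self.inten_sum = inten_sum
        self.bbox = bbox  # (y0, x0, y1, x1)


def _region_similarity(a: _Region, b: _Region, n_pixels: int) -> float:
    sim_int = 1.0 - abs(a.inten_sum / a.size - b.inten_sum / b.size) / 255.0
    sim_size = 1.0 - (a.size + b.size) / n_pixels
    return 0.5 * (sim_int + sim_size)


def _selective_search_boxes(frame: np.ndarray, t: int, cfg: ProposalConfig) -> List[RoiBox]:
    img = frame.astype(np.float64) / 255.0
    seg = felzenszwalb(img, scale=cfg.fz_scale, sigma=cfg.fz_sigma,
                       min_size=cfg.fz_min_size, channel_axis=None)
    n_pixels = frame.size
    labels = np.unique(seg)
    regions = {}
    for lbl in labels:
        mask = seg == lbl
        ys, xs = np.nonzero(mask)
        regions[int(lbl)] = _Region(
            size=int(mask.sum()),
            inten_sum=float(frame[mask].sum()),
            bbox=(int(ys.min()), int(xs.min()), int(ys.max()) + 1, int(xs.max()) + 1),
        )
    # adjacency from 4-neighborhood label changes
    neighbors = {int(l): set() for l in labels}
    for a, b in ((seg[:, :-1], seg[:, 1:]), (seg[:-1, :], seg[1:, :])):
        diff = a != b
        for la, lb in zip(a[diff].ravel(), b[diff].ravel()):
            neighbors[int(la)].add(int(lb))
            neighbors[int(lb)].add(int(la))

    boxes = {r.bbox for r in regions.values()}
    next_label = int(labels.max()) + 1
    # iterative greedy merging of the most similar adjacent pair
    while True:
        best, best_sim = None, cfg.similarity_floor
        for la, nbrs in neighbors.items():
            for lb in nbrs:
                if lb <= la:
                    continue
                s = _region_similarity(regions[la], regions[lb], n_pixels)
                if s > best_sim:
                    best, best_sim = (la, lb), s
        if best is None:
            break
        la, lb = best
        ra, rb = regions.pop(la), regions.pop(lb)
        merged = _Region(
            size=ra.size + rb.size,
            inten_sum=ra.inten_sum + rb.inten_sum,
            bbox=(
                min(ra.bbox[0], rb.bbox[0]), min(ra.bbox[1], rb.bbox[1]),
                max(ra.bbox[2], rb.bbox[2]), max(ra.bbox[3], rb.bbox[3]),
            ),
        )
        regions[next_label] = merged
        merged_nbrs = (neighbors.pop(la) | neighbors.pop(lb)) - {la, lb}
        neighbors[next_label] = merged_nbrs
        for n in merged_nbrs:
            neighbors[n].discard(la)
            neighbors[n].discard(lb)
            neighbors[n].add(next_label)
        boxes.add(merged.bbox)
        next_label += 1

    out = []
    for (y0, x0, y1, x1) in sorted(boxes):
        out.append(RoiBox(t=t, x_min=x0, y_min=y0, x_max=x1, y_max=y1))
    return out


def filter_boxes(
    boxes: Sequence[RoiBox],
    frame: np.ndarray,
    min_edge: int = 20,
    max_edge: int = 40,
    min_brightness: float = 40.0,
) -> List[RoiBox]:
    """Keep boxes with both edges in ``[min_edge, max_edge]`` (inclusive) and
    8-bit mean intensity >= ``min_brightness``; order preserved."""
    H, W = frame.shape
    kept = []
    for b in boxes:
        if not (min_edge <= b.width <= max_edge and min_edge <= b.height <= max_edge):
            continue
        if b.x_min < 0 or b.y_min < 0 or b.x_max > W or b.y_max > H:
            continue
        mean = float(frame[b.y_min:b.y_max, b.x_min:b.x_max].mean())
        if mean < min_brightness:
            continue
        kept.append(RoiBox(b.t, b.x_min, b.y_min, b.x_max, b.y_max, mean_intensity=mean))
    return kept


def propose(frame: np.ndarray, params: Optional[ProposalConfig] = None, t: int = 0) -> List[RoiBox]:
    """Propose candidate boxes on a single 8-bit frame, deduplicated and filtered."""
    cfg = params or ProposalConfig()
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("frame must be 2D")
    if frame.dtype != np.uint8:
        raise ValueError("frame must be 8-bit (uint8); normalize the movie first")
    if cfg.method == "blob":
        raw = _blob_boxes(frame, t, cfg)
    elif cfg.method == "selective_search":
        raw = _selective_search_boxes(frame, t, cfg)
    else:
        raise ValueError(f"unknown proposal method {cfg.method!r}")
    # dedupe, preserving first occurrence
    seen, uniq = set(), []
    for b in raw:
        key = (b.x_min, b.y_min, b.x_max, b.y_max)
        if key not in seen:
            seen.add(key)
            uniq.append(b)
    return filter_boxes(uniq, frame, cfg.min_edge, cfg.max_edge, cfg.min_brightness)
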