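"""Scoring predicted events and tracks against ground truth.

Event-level matching is one-to-one greedy in increasing combined
spatiotemporal distance, accepting only pairs within both a spatial and a
temporal radius; TPR is the matched fraction of truth events and FPR the
unmatched fraction of predictions.  Track-level fidelity uses a
graph-edit (AOGM-style) cost normalized against the cost of building the
truth graph from scratch, as in the Cell Tracking Challenge TRA measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from skimage.filters import threshold_otsu

from .io import Timelapse
from .proposal import ProposalConfig, propose
from .tracking import Track

__all__ = [
    "MatchConfig", "EvaluationReport", "match_events", "nn_analysis",
    "temporal_offsets", "cumulative_correlation", "tra_score",
    "video_quality_score", "estimate_snr", "events_from_tracks",
    "QualityRanges", "combine_quality_components",
]


@dataclass
class MatchConfig:
    """Tolerances for event matching: a prediction counts as a true
    positive when within ``spatial_radius`` px and ``temporal_radius``
    frames of an unmatched truth event."""

    spatial_radius: float = 20.0
    temporal_radius: float = 5.0

    def __post_init__(self) -> None:
        if self.spatial_radius <= 0 or self.temporal_radius <= 0:
            raise ValueError("matching radii must be > 0")


@dataclass
class EvaluationReport:
    tpr: Optional[float]
    fpr: float
    matches: List[Tuple[int, int]]        # (prediction index, truth index)
    spatial_errors: np.ndarray            # px, one per match
    temporal_offsets: np.ndarray          # frames (pred - truth), one per match
    n_pred: int
    n_truth: int
    nn_distances: Optional[np.ndarray] = None
    pearson_r: Optional[float] = None
    tra: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "tpr": self.tpr,
            "fpr": self.fpr,
            "n_pred": self.n_pred,
            "n_truth": self.n_truth,
            "n_matches": len(self.matches),
            "mean_spatial_error_px": (float(np.mean(self.spatial_errors))
                                      if len(self.spatial_errors) else None),
            "mean_temporal_offset_frames": (float(np.mean(self.temporal_offsets))
                                            if len(self.temporal_offsets) else None),
            "mean_abs_temporal_offset_frames": (float(np.mean(np.abs(self.temporal_offsets)))
                                                if len(self.temporal_offsets) else None),
            "mean_nn_distance_px": (float(np.mean(self.nn_distances))
                                    if self.nn_distances is not None and len(self.nn_distances)
                                    else None),
            "pearson_r": self.pearson_r,
            "tra": self.tra,
        }


def _as_xyt(events) -> np.ndarray:
    """Coerce annotations / tracks / tuples to an (n, 3) array of (x, y, t)."""
    rows = []
    for e in events:
        if isinstance(e, Track):
            x, y = e.event_location
            rows.append((x, y, e.event_time))
        elif hasattr(e, "x"):
            rows.append((e.x, e.y, e.t))
        else:
            x, y, t = e
            rows.append((float(x), float(y), float(t)))
    return np.array(rows, dtype=float).reshape(-1, 3)


def events_from_tracks(tracks: Sequence[Track]) -> np.ndarray:
    """Each track as one event: median centroid at the first frame."""
    return _as_xyt(tracks)


def match_events(predicted, truth, cfg: Optional[MatchConfig] = None) -> EvaluationReport:
    """One-to-one greedy matching of predicted to truth (x, y, t) events.

    Candidate pairs within both radii are ranked by the combined distance
    ``spatial/spatial_radius + |dt|/temporal_radius`` and accepted
    greedily.  With empty truth the TPR is undefined and reported as
    ``None``; with no predictions the FPR is 0 by convention.
    """
    cfg = cfg or MatchConfig()
    P = _as_xyt(predicted)
    G = _as_xyt(truth)
    pairs = []
    for i in range(len(P)):
        ds = np.hypot(P[i, 0] - G[:, 0], P[i, 1] - G[:, 1]) if len(G) else np.array([])
        dt = np.abs(P[i, 2] - G[:, 2]) if len(G) else np.array([])
        ok = np.nonzero((ds <= cfg.spatial_radius) & (dt <= cfg.temporal_radius))[0]
        for j in ok:
            combined = ds[j] / cfg.spatial_radius + dt[j] / cfg.temporal_radius
            pairs.append((combined, i, int(j), ds[j], P[i, 2] - G[j, 2]))
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))
    used_p, used_g = set(), set()
    matches, serr, toff = [], [], []
    for _, i, j, d, off in pairs:
        if i in used_p or j in used_g:
            continue
        used_p.add(i)
        used_g.add(j)
        matches.append((i, j))
        serr.append(d)
        toff.append(off)
    tpr = None if len(G) == 0 else len(matches) / len(G)
    fpr = 0.0 if len(P) == 0 else (len(P) - len(matches)) / len(P)
    return EvaluationReport(
        tpr=tpr, fpr=fpr, matches=matches,
        spatial_errors=np.array(serr), temporal_offsets=np.array(toff),
        n_pred=len(P), n_truth=len(G),
    )


def nn_analysis(
    predictions, truth, frame_shape: Tuple[int, int],
    seed: int = 0, n_baseline_repeats: int = 1,
) -> dict:
    """Distance from every prediction to its nearest truth event, plus the
    same statistic for uniform-random points (the chance baseline)."""
    P = _as_xyt(predictions)
    G = _as_xyt(truth)
    if len(G) == 0:
        raise ValueError("nn_analysis needs non-empty truth")
    H, W = frame_shape

    def _nn(points):
        d = np.hypot(points[:, None, 0] - G[None, :, 0],
                     points[:, None, 1] - G[None, :, 1])
        return d.min(axis=1)

    rng = np.random.default_rng(seed)
    baseline = []
    for _ in range(n_baseline_repeats):
        rand = np.column_stack([rng.uniform(0, W, len(P)), rng.uniform(0, H, len(P))])
        baseline.append(_nn(rand) if len(P) else np.array([]))
    return {
        "distances": _nn(P[:, :2]) if len(P) else np.array([]),
        "baseline_distances": np.concatenate(baseline) if baseline else np.array([]),
    }


def temporal_offsets(report_or_matches) -> np.ndarray:
    """Signed frame differences (prediction - truth) of the matched pairs."""
    if isinstance(report_or_matches, EvaluationReport):
        return report_or_matches.temporal_offsets
    return np.array([p - t for p, t in report_or_matches], dtype=float)


def cumulative_correlation(pred_events, truth_events, T: Optional[int] = None):
    """Pearson r between the per-frame cumulative event-count curves.

    Returns ``nan`` when either curve has zero variance (undefined).
    """
    from .pipeline import cumulative_counts

    pt = _as_xyt(pred_events)[:, 2].astype(int) if len(list(pred_events)) else np.array([], int)
    gt = _as_xyt(truth_events)[:, 2].astype(int)
    if T is None:
        T = int(max(pt.max(initial=0), gt.max(initial=0))) + 1
    cp = cumulative_counts(list(pt), T)
    cg = cumulative_counts(list(gt), T)
    if cp.std() == 0 or cg.std() == 0:
        return float("nan")
    return float(np.corrcoef(cp, cg)[0, 1])


# ---------------------------------------------------------------------------
# TRA (AOGM-style graph edit distance)

#: default AOGM operation weights (node split, false-negative node,
#: false-positive node, redundant edge, missing edge, wrong-semantics edge)
AOGM_WEIGHTS = {"NS": 5.0, "FN": 10.0, "FP": 1.0, "ED": 1.0, "EA": 1.5, "EC": 1.0}


def _tracks_to_graph(tracks) -> Tuple[Dict[Tuple[int, int], Tuple[float, float]], set]:
    """Nodes keyed by (track_id, t) -> (x, y); edges between consecutive
    detections of one track."""
    nodes, edges = {}, set()
    for tr in tracks:
        if isinstance(tr, Track):
            items = [(tr.track_id, d.t) + d.box.center for d in tr.detections]
        else:  # (track_id, t, x, y) rows
            items = [tuple(r) for r in tr]
        items.sort(key=lambda r: r[1])
        prev = None
        for tid, t, x, y in items:
            nodes[(int(tid), int(t))] = (float(x), float(y))
            if prev is not None:
                edges.add((prev, (int(tid), int(t))))
            prev = (int(tid), int(t))
    return nodes, edges


def tra_score(
    pred_tracks, truth_tracks, match_radius: float = 10.0,
    weights: Optional[dict] = None,
) -> float:
    """Tracking accuracy TRA = max(0, 1 - AOGM / AOGM_empty).

    AOGM sums the weighted operations needed to edit the predicted track
    graph into the truth graph: unmatched truth nodes (FN), spurious
    predicted nodes (FP), missing edges (EA) and redundant edges (ED).
    Node correspondence is established per frame by minimum-cost
    one-to-one assignment within ``match_radius``.  ``AOGM_empty`` is the
    cost of building the truth graph from nothing (all FN + all EA).
    Track ids are never compared directly, so the measure is id-agnostic.
    """
    w = dict(AOGM_WEIGHTS)
    if weights:
        w.update(weights)
    gnodes, gedges = _tracks_to_graph(truth_tracks)
    pnodes, pedges = _tracks_to_graph(pred_tracks)
    if not gnodes:
        raise ValueError("empty truth track set")

    # per-frame one-to-one correspondence
    frames = sorted({t for _, t in gnodes} | {t for _, t in pnodes})
    p2g: Dict[Tuple[int, int], Tuple[int, int]] = {}
    for t in frames:
        gs = [k for k in gnodes if k[1] == t]
        ps = [k for k in pnodes if k[1] == t]
        if not gs or not ps:
            continue
        cost = np.full((len(ps), len(gs)), 1e9)
        for i, pk in enumerate(ps):
            for j, gk in enumerate(gs):
                d = np.hypot(pnodes[pk][0] - gnodes[gk][0],
                             pnodes[pk][1] - gnodes[gk][1])
                if d <= match_radius:
                    cost[i, j] = d
        ri, ci = linear_sum_assignment(cost)
        for i, j in zip(ri, ci):
            if cost[i, j] < 1e9:
                p2g[ps[i]] = gs[j]

    matched_g = set(p2g.values())
    n_fn = len(gnodes) - len(matched_g)
    n_fp = len(pnodes) - len(p2g)

    # edges: a truth edge is satisfied if both endpoints are matched by
    # predicted nodes joined by a predicted edge
    g2p = {g: p for p, g in p2g.items()}
    n_ea = 0
    for (u, v) in gedges:
        pu, pv = g2p.get(u), g2p.get(v)
        if pu is None or pv is None or (pu, pv) not in pedges:
            n_ea += 1
    n_ed = 0
    for (pu, pv) in pedges:
        gu, gv = p2g.get(pu), p2g.get(pv)
        if gu is None or gv is None or (gu, gv) not in gedges:
            n_ed += 1

    aogm = w["FN"] * n_fn + w["FP"] * n_fp + w["EA"] * n_ea + w["ED"] * n_ed
    aogm_empty = w["FN"] * len(gnodes) + w["EA"] * len(gedges)
    return float(max(0.0, 1.0 - aogm / aogm_empty))


# ---------------------------------------------------------------------------
# movie quality

SNR_CEILING = 100.0  # reported for an effectively noise-free background


def estimate_snr(movie: Timelapse, sample_frames: int = 10) -> float:
    """Mean foreground intensity / robust SD of the background.

    Foreground is segmented with an Otsu threshold over a uniform sample
    of frames.  The background noise scale is the median absolute
    deviation (x 1.4826) of the sub-threshold pixels, which is robust to
    the dim cell fringes that leak into the background class.  A
    near-noise-free background yields the documented ceiling value
    rather than infinity.
    """
    frames = movie.frames
    idx = np.unique(np.linspace(0, frames.shape[0] - 1, sample_frames).astype(int))
    sample = frames[idx].astype(np.float64)
    if sample.max() == sample.min():
        return 0.0
    thr = threshold_otsu(sample.ravel())
    fg = sample[sample > thr]
    bg = sample[sample <= thr]
    if fg.size == 0 or bg.size == 0:
        return 0.0
    bg_sd = 1.4826 * np.median(np.abs(bg - np.median(bg)))
    if bg_sd < 1e-9:
        return SNR_CEILING
    return float(min(fg.mean() / bg_sd, SNR_CEILING))


@dataclass
class QualityRanges:
    """Reference spans (worst, best) for each quality component, defaulting
    to mean +/- SD spans reported for intravital leukocyte movies
    (cell count 87 +/- 76, SNR 8.9 +/- 3.6, shortest cell distance
    21.2 +/- 15.4 um)."""

    cell_count: Tuple[float, float] = (163.0, 11.0)       # fewer is better
    snr: Tuple[float, float] = (5.3, 12.5)                # higher is better
    signal_fluctuation: Tuple[float, float] = (0.5, 0.0)  # lower is better
    min_cell_distance: Tuple[float, float] = (5.8, 36.6)  # larger is better
    saturation: Tuple[float, float] = (0.2, 0.0)          # lower is better


def _unit_scale(value: float, worst: float, best: float) -> float:
    if worst == best:
        return 1.0
    return float(np.clip((value - worst) / (best - worst), 0.0, 1.0))


def combine_quality_components(raw: dict, ranges: Optional[QualityRanges] = None):
    """Normalize raw component measurements over their reference ranges
    (oriented so higher = better) and average into the [0, 1] score."""
    ranges = ranges or QualityRanges()
    components = {
        name: _unit_scale(raw[name], *getattr(ranges, name))
        for name in ("cell_count", "snr", "signal_fluctuation",
                     "min_cell_distance", "saturation")
    }
    return float(np.mean(list(components.values()))), components


def video_quality_score(
    movie: Timelapse,
    ranges: Optional[QualityRanges] = None,
    proposal_config: Optional[ProposalConfig] = None,
) -> Tuple[float, dict]:
    """Combine measured movie properties into a score in [0, 1].

    Components (each min-max normalized over its reference range and
    oriented so higher = better, then averaged): mean per-frame cell
    count via blob detection, SNR, relative SD of the frame-mean signal
    over time, mean shortest inter-cell distance, and saturated-pixel
    fraction.
    """
    ranges = ranges or QualityRanges()
    pcfg = proposal_config or ProposalConfig(min_edge=3, max_edge=80, min_brightness=0)
    frames = movie.frames
    idx = np.unique(np.linspace(0, frames.shape[0] - 1, 5).astype(int))

    counts, min_dists = [], []
    for t in idx:
        boxes = propose(frames[t], pcfg, t=int(t))
        counts.append(len(boxes))
        if len(boxes) >= 2:
            pts = np.array([b.center for b in boxes])
            d = np.hypot(pts[:, None, 0] - pts[None, :, 0],
                         pts[:, None, 1] - pts[None, :, 1])
            np.fill_diagonal(d, np.inf)
            min_dists.append(float(d.min(axis=1).mean()))
    cell_count = float(np.mean(counts)) if counts else 0.0
    px = movie.pixel_size or 1.0
    min_dist = float(np.mean(min_dists)) * px if min_dists else ranges.min_cell_distance[1]

    snr = estimate_snr(movie)
    frame_means = frames.mean(axis=(1, 2)).astype(np.float64)
    fluct = float(frame_means.std() / max(frame_means.mean(), 1e-9))
    sat_value = 2 ** movie.bit_depth - 1
    saturation = float((frames == sat_value).mean())

    raw = {
        "cell_count": cell_count, "snr": snr, "signal_fluctuation": fluct,
        "min_cell_distance": min_dist, "saturation": saturation,
    }
    score, components = combine_quality_components(raw, ranges)
    return score, {"normalized": components, "raw": raw}
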