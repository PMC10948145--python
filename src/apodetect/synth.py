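"""Ground-truthed synthetic timelapse movies of apoptotic cells.

Two phenomenologies are emulated:

* ``in_vitro`` — a near-confluent monolayer of fluorescently labeled
  nuclei.  An apoptotic nucleus shrinks while its total signal
  concentrates (chromatin condensation: area falls, pixel-intensity SD
  rises), then fragments into 2-4 small apoptotic bodies that fade.
  Mitotic figures — a nucleus that briefly condenses and then splits into
  two persistent daughters — can be planted as confounders, since they are
  the dominant false-positive mode for this assay.
* ``in_vivo`` — sparse motile leukocytes on a noisy background.  Cells
  perform a Brownian walk; an apoptotic cell arrests, blebs (transient
  peripheral bumps), and fragments into apoptotic bodies.

Cells are rendered as anisotropic 2D Gaussians with per-frame intensity
jitter.  All randomness flows from a single seeded generator, so equal
seeds give bit-identical movies.  Ground truth records each event's
centroid and start frame (beginning of shrinkage/blebbing) plus per-cell
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .data import ClipSequence, extract_clip
from .io import EventAnnotation, Timelapse

__all__ = ["SynthConfig", "SyntheticMovie", "generate", "generate_clip_library"]


@dataclass
class SynthConfig:
    """Parameters of the synthetic movie generator.

    Defaults describe the in-vitro regime: a 256 x 256 field imaged every
    5 minutes with ~100 nuclei, and morphological changes lasting 8 frames
    (the median event duration in this kind of data).
    """

    mode: str = "in_vitro"  # "in_vitro" | "in_vivo"
    H: int = 256
    W: int = 256
    T: int = 100
    n_cells: int = 100
    n_apoptoses: int = 10
    n_mitoses: int = 0
    cell_radius_px: Tuple[float, float] = (6.0, 1.0)  # mean, sd
    cell_amplitude: Tuple[float, float] = (150.0, 15.0)  # 8-bit mean, sd
    motility_px_per_frame: float = 0.0  # in_vivo default ~1.5
    noise_sd: float = 4.0
    background_level: float = 10.0
    event_duration_frames: int = 8
    fragment_fade_frames: int = 4
    frame_interval: float = 5.0  # minutes
    target_snr: Optional[float] = None  # overrides noise_sd when set
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("in_vitro", "in_vivo"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if min(self.H, self.W, self.T, self.n_cells) <= 0:
            raise ValueError("dimensions and cell count must be positive")
        if self.n_apoptoses + self.n_mitoses > self.n_cells:
            raise ValueError("n_apoptoses + n_mitoses cannot exceed n_cells")
        if self.event_duration_frames + self.fragment_fade_frames + 4 > self.T:
            raise ValueError("event window does not fit inside the movie")


@dataclass
class SyntheticMovie:
    movie: Timelapse
    truth: List[EventAnnotation]
    truth_tracks: Dict[int, List[Tuple[int, float, float]]]
    config: SynthConfig


class _Cell:
    __slots__ = ("x", "y", "r", "amp", "aniso", "theta", "fate", "t0")

    def __init__(self, x, y, r, amp, aniso, theta, fate="healthy", t0=-1):
        self.x, self.y = x, y
        self.r, self.amp = r, amp
        self.aniso, self.theta = aniso, theta
        self.fate = fate  # "healthy" | "apoptotic" | "mitotic"
        self.t0 = t0      # event start frame


def _place_cells(cfg: SynthConfig, rng: np.random.Generator) -> List[Tuple[float, float]]:
    """Near-confluent jittered grid (in vitro) or sparse rejection sampling (in vivo)."""
    if cfg.mode == "in_vitro":
        spacing = np.sqrt(cfg.H * cfg.W / cfg.n_cells)
        nx = int(np.ceil(cfg.W / spacing))
        ny = int(np.ceil(cfg.H / spacing))
        pts = []
        for iy in range(ny):
            for ix in range(nx):
                x = (ix + 0.5) * cfg.W / nx + rng.uniform(-0.22, 0.22) * spacing
                y = (iy + 0.5) * cfg.H / ny + rng.uniform(-0.22, 0.22) * spacing
                pts.append((float(np.clip(x, 2, cfg.W - 3)), float(np.clip(y, 2, cfg.H - 3))))
        order = rng.permutation(len(pts))[: cfg.n_cells]
        if len(order) < cfg.n_cells:
            raise RuntimeError("cannot place requested number of cells")
        return [pts[i] for i in order]
    # in vivo: sparse, min-distance rejection
    min_d = 2.5 * cfg.cell_radius_px[0]
    pts: List[Tuple[float, float]] = []
    attempts = 0
    while len(pts) < cfg.n_cells:
        attempts += 1
        if attempts > 200 * cfg.n_cells:
            raise RuntimeError("cannot place cells without overlap; lower n_cells")
        x = rng.uniform(4, cfg.W - 5)
        y = rng.uniform(4, cfg.H - 5)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_d ** 2 for px, py in pts):
            pts.append((x, y))
    return pts


def _add_gaussian(img, x, y, sx, sy, theta, amp):
    """Accumulate a rotated anisotropic Gaussian into img within a local window."""
    H, W = img.shape
    ext = int(np.ceil(3.2 * max(sx, sy))) + 1
    x0, x1 = max(0, int(x) - ext), min(W, int(x) + ext + 1)
    y0, y1 = max(0, int(y) - ext), min(H, int(y) + ext + 1)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx, dy = xs - x, ys - y
    c, s = np.cos(theta), np.sin(theta)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    img[y0:y1, x0:x1] += amp * np.exp(-0.5 * ((u / sx) ** 2 + (v / sy) ** 2))


def _make_cells(cfg: SynthConfig, rng: np.random.Generator) -> List[_Cell]:
    pts = _place_cells(cfg, rng)
    cells = []
    for (x, y) in pts:
        r = max(2.0, rng.normal(*cfg.cell_radius_px))
        amp = float(np.clip(rng.normal(*cfg.cell_amplitude), 80, 230))
        cells.append(
            _Cell(x, y, r, amp, aniso=rng.uniform(0.85, 1.18), theta=rng.uniform(0, np.pi))
        )
    margin = 2
    lo = margin
    hi = cfg.T - cfg.event_duration_frames - cfg.fragment_fade_frames - margin
    event_ids = rng.permutation(cfg.n_cells)[: cfg.n_apoptoses + cfg.n_mitoses]
    for j, ci in enumerate(event_ids):
        cells[ci].fate = "apoptotic" if j < cfg.n_apoptoses else "mitotic"
        cells[ci].t0 = int(rng.integers(lo, max(lo + 1, hi)))
    return cells


def _render(cfg: SynthConfig, rng: np.random.Generator):
    """Render clean frames and collect ground truth."""
    cells = _make_cells(cfg, rng)
    T, H, W = cfg.T, cfg.H, cfg.W
    dur, fade = cfg.event_duration_frames, cfg.fragment_fade_frames

    # pre-draw per-cell random programs so rendering per-frame is deterministic
    frag_plans = {}
    bleb_plans = {}
    mito_plans = {}
    walks = {}
    for i, c in enumerate(cells):
        if c.fate == "apoptotic":
            n_bodies = int(rng.integers(2, 5))
            ang = rng.uniform(0, 2 * np.pi, n_bodies)
            dist = rng.uniform(0.4, 1.5, n_bodies) * c.r
            bsig = rng.uniform(1.2, 2.0, n_bodies)
            frag_plans[i] = (ang, dist, bsig)
            if cfg.mode == "in_vivo":
                nb = int(rng.integers(2, 4))
                bleb_plans[i] = (
                    rng.uniform(0, 2 * np.pi, nb),
                    rng.uniform(0.8, 1.3, nb),
                    rng.integers(0, dur, nb),
                )
        elif c.fate == "mitotic":
            mito_plans[i] = rng.uniform(0, np.pi)
        if cfg.mode == "in_vivo":
            steps = rng.normal(0, cfg.motility_px_per_frame, size=(T, 2))
            walks[i] = steps
        else:
            walks[i] = rng.normal(0, 0.15, size=(T, 2))
    jitter = rng.normal(1.0, 0.03, size=(len(cells), T))

    clean = np.zeros((T, H, W), dtype=np.float64)
    tracks: Dict[int, List[Tuple[int, float, float]]] = {i: [] for i in range(len(cells))}
    positions = {i: (c.x, c.y) for i, c in enumerate(cells)}

    for t in range(T):
        img = clean[t]
        img += cfg.background_level
        for i, c in enumerate(cells):
            x, y = positions[i]
            # motion (arrested once an apoptotic program starts)
            moving = not (c.fate == "apoptotic" and 0 <= c.t0 <= t)
            if moving and t > 0:
                dx, dy = walks[i][t]
                x = float(np.clip(x + dx, 2, W - 3))
                y = float(np.clip(y + dy, 2, H - 3))
                positions[i] = (x, y)
            sx = c.r * c.aniso
            sy = c.r / c.aniso
            amp = c.amp * jitter[i, t]

            if c.fate == "apoptotic" and t >= c.t0:
                p = (t - c.t0 + 1) / dur
                if p <= 1.0:  # shrinkage + condensation
                    scale = 1.0 - 0.58 * p
                    # integrated fluorescence is conserved while the area
                    # shrinks, so peak brightness rises as 1/scale^2
                    # (clipped later by the 8-bit range)
                    amp_mult = 1.0 / scale ** 2
                    _add_gaussian(img, x, y, sx * scale, sy * scale, c.theta, amp * amp_mult)
                    if i in bleb_plans:
                        bang, bscale, bstart = bleb_plans[i]
                        for a, sc, st in zip(bang, bscale, bstart):
                            if st <= t - c.t0 <= st + 2:
                                bx = x + np.cos(a) * c.r * sc
                                by = y + np.sin(a) * c.r * sc
                                _add_gaussian(img, bx, by, 1.4, 1.4, 0.0, amp * 0.55)
                else:  # fragmentation into bodies that fade to persistent debris
                    k = t - c.t0 - dur
                    ang, dist, bsig = frag_plans[i]
                    if k < fade:
                        decay = 1.0 - (1.0 - 0.3) * (k + 1) / (fade + 1)
                        spread = 1.0 + 0.25 * k
                    else:  # static debris: apoptotic bodies from an earlier event
                        decay = 0.3 * 0.985 ** (k - fade)
                        spread = 1.0 + 0.25 * (fade - 1)
                    for a, d, bs in zip(ang, dist, bsig):
                        bx = x + np.cos(a) * d * spread
                        by = y + np.sin(a) * d * spread
                        _add_gaussian(img, bx, by, bs, bs, 0.0, amp * 1.3 * decay)
                    if k >= fade:
                        continue  # no longer tracked as a cell
                tracks[i].append((t, x, y))
                continue

            if c.fate == "mitotic" and t >= c.t0:
                k = t - c.t0
                if k < 3:  # condensation (apoptosis look-alike)
                    scale = 1.0 - 0.08 * (k + 1)
                    _add_gaussian(img, x, y, sx * scale, sy * scale, c.theta,
                                  amp * (1.0 + 0.12 * (k + 1)))
                else:
                    # daughters start small, condensed and bright (chromatin
                    # still compact), then grow and decondense -- the
                    # temporal mirror of apoptotic condensation
                    a = mito_plans[i]
                    q = min(1.0, (k - 2) / 6.0)
                    sep = c.r * (0.6 + 0.8 * q)
                    grow = 0.45 + 0.55 * q
                    bright = 1.45 - 0.45 * q
                    for sgn in (-1.0, 1.0):
                        _add_gaussian(img, x + sgn * np.cos(a) * sep,
                                      y + sgn * np.sin(a) * sep,
                                      sx * grow * 0.85, sy * grow * 0.85,
                                      c.theta, amp * bright)
                tracks[i].append((t, x, y))
                continue

            _add_gaussian(img, x, y, sx, sy, c.theta, amp)
            tracks[i].append((t, x, y))

    truth = [
        EventAnnotation(x=cells[i].x, y=cells[i].y, t=cells[i].t0, label=1, track_id=i)
        for i in range(len(cells))
        if cells[i].fate == "apoptotic"
    ]
    truth.sort(key=lambda a: (a.t, a.x, a.y))
    return clean, truth, tracks


def generate(config: SynthConfig) -> SyntheticMovie:
    """Generate a ground-truthed synthetic movie; equal seeds are bit-identical."""
    rng = np.random.default_rng(config.seed)
    clean, truth, tracks = _render(config, rng)

    def _finalize(noise_sd):
        if noise_sd > 0:
            rng_noise = np.random.default_rng(config.seed + 500_009)
            noisy = clean + rng_noise.normal(0, noise_sd, size=clean.shape)
        else:
            noisy = clean
        frames = np.clip(np.round(noisy), 0, 255).astype(np.uint8)
        return Timelapse(
            frames=frames,
            bit_depth=8,
            frame_interval=config.frame_interval,
            source_id=f"synth-{config.mode}-seed{config.seed}",
        )

    noise_sd = config.noise_sd
    if config.target_snr is not None:
        # calibrate the noise level against the package's own SNR
        # estimator, whose background sample also contains dim cell
        # fringes; a couple of fixed-point iterations land within a few
        # percent of the requested ratio
        from .evaluation import estimate_snr

        fg = clean[clean > config.background_level + 25]
        noise_sd = max((float(fg.mean()) if fg.size else 255.0)
                       / config.target_snr, 0.5)
        for _ in range(3):
            got = estimate_snr(_finalize(noise_sd))
            if abs(got - config.target_snr) / config.target_snr < 0.05:
                break
            noise_sd = max(noise_sd * got / config.target_snr, 0.05)
    movie = _finalize(noise_sd)
    return SyntheticMovie(movie=movie, truth=truth, truth_tracks=tracks, config=config)


def _clip_center_frame(cfg: SynthConfig, ann: EventAnnotation) -> int:
    # center positives mid-event so the clip spans shrinkage and fragmentation
    return ann.t + cfg.event_duration_frames // 2


def generate_clip_library(
    config: SynthConfig,
    n_per_class: int,
    ratio: float = 1.0,
    clip_len: int = 5,
    window: int = 9,
    include_mitoses: bool = True,
    include_temporal_negatives: bool = True,
    safety_radius: float = 40.0,
):
    """Cut a labeled clip library from freshly generated movies.

    Returns ``(positives, negatives)`` with ``n_per_class`` label-1 clips
    centered on planted events and ``ratio * n_per_class`` label-0 clips
    drawn from healthy cells, background locations at least
    ``safety_radius`` px from any event, residual debris, (optionally)
    mitotic confounders, and (optionally) time-reversed event clips.  The
    reversed clips are temporal-order negatives: apoptosis is a directed
    process (shrinkage then fragmentation), so its mirror image played
    backwards is not an event, and labeling it 0 forces the sequence
    classifier to read the direction of change rather than a single
    frame's morphology.  Deterministic under ``config.seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    n_neg_target = int(round(ratio * n_per_class))
    rng = np.random.default_rng(config.seed + 1_000_003)

    positives: List[ClipSequence] = []
    negatives: List[ClipSequence] = []
    neg_healthy: List[ClipSequence] = []
    neg_bg: List[ClipSequence] = []
    neg_mito: List[ClipSequence] = []
    neg_debris: List[ClipSequence] = []
    neg_reversed: List[ClipSequence] = []
    mito_frac = 0.2 if include_mitoses else 0.0
    bg_frac = 0.15
    debris_frac = 0.2
    reversed_frac = 0.15 if include_temporal_negatives else 0.0

    movie_seed = config.seed
    guard = 0
    while len(positives) < n_per_class or len(negatives) < n_neg_target:
        guard += 1
        if guard > 500:
            raise RuntimeError("clip library generation did not converge")
        cfg_m = replace(
            config,
            seed=movie_seed,
            n_mitoses=(max(config.n_mitoses, max(2, config.n_apoptoses // 2))
                       if include_mitoses else 0),
        )
        movie_seed += 1
        sm = generate(cfg_m)
        frames = sm.movie.frames
        T, H, W = frames.shape

        for ann in sm.truth:
            if len(positives) >= n_per_class:
                break
            tc = _clip_center_frame(cfg_m, ann)
            positives.append(
                ClipSequence(
                    frames=extract_clip(frames, ann.x, ann.y, tc, window, clip_len),
                    label=1, center_t=tc, movie_id=sm.movie.source_id,
                )
            )

        # healthy-cell negatives: any tracked cell that never dies
        apoptotic_ids = {a.track_id for a in sm.truth}
        healthy_ids = [
            i for i, tr in sm.truth_tracks.items()
            if i not in apoptotic_ids and len(tr) == T
        ]
        rng.shuffle(healthy_ids)
        for i in healthy_ids[: max(2, len(sm.truth))]:
            t_pick = int(rng.integers(window // 2, T - window // 2))
            _, x, y = sm.truth_tracks[i][t_pick]
            neg_healthy.append(
                ClipSequence(
                    frames=extract_clip(frames, x, y, t_pick, window, clip_len),
                    label=0, center_t=t_pick, movie_id=sm.movie.source_id,
                )
            )
        # background negatives: random locations far from every event
        events = [(a.x, a.y) for a in sm.truth]
        for _ in range(max(2, len(sm.truth) // 2)):
            for _try in range(50):
                x = rng.uniform(0, W - 1)
                y = rng.uniform(0, H - 1)
                if all((x - ex) ** 2 + (y - ey) ** 2 >= safety_radius ** 2
                       for ex, ey in events):
                    t_pick = int(rng.integers(window // 2, T - window // 2))
                    neg_bg.append(
                        ClipSequence(
                            frames=extract_clip(frames, x, y, t_pick, window, clip_len),
                            label=0, center_t=t_pick, movie_id=sm.movie.source_id,
                        )
                    )
                    break
        # debris negatives: the static apoptotic bodies left by earlier events
        dur = cfg_m.event_duration_frames + cfg_m.fragment_fade_frames
        for ann in sm.truth:
            td = ann.t + dur + window // 2 + 2
            if td + window // 2 < T:
                neg_debris.append(
                    ClipSequence(
                        frames=extract_clip(frames, ann.x, ann.y, td, window, clip_len),
                        label=0, center_t=td, movie_id=sm.movie.source_id,
                    )
                )
        # mitotic confounders
        if include_mitoses:
            neg_mito.extend(_mitosis_clips(sm, window, clip_len, rng))
        # temporal-order negatives: events played backwards
        if include_temporal_negatives:
            for ann in sm.truth:
                tc = _clip_center_frame(cfg_m, ann)
                clip = extract_clip(frames, ann.x, ann.y, tc, window, clip_len)
                neg_reversed.append(
                    ClipSequence(frames=clip[::-1].copy(), label=0, center_t=tc,
                                 movie_id=sm.movie.source_id)
                )

        n_m = int(round(mito_frac * n_neg_target))
        n_b = int(round(bg_frac * n_neg_target))
        n_d = int(round(debris_frac * n_neg_target))
        n_r = int(round(reversed_frac * n_neg_target))
        n_h = n_neg_target - n_m - n_b - n_d - n_r
        if (len(neg_healthy) >= n_h and len(neg_bg) >= n_b and len(neg_mito) >= n_m
                and len(neg_debris) >= n_d and len(neg_reversed) >= n_r
                and len(positives) >= n_per_class):
            negatives = (neg_healthy[:n_h] + neg_bg[:n_b] + neg_mito[:n_m]
                         + neg_debris[:n_d] + neg_reversed[:n_r])

    return positives, negatives


def _mitosis_clips(sm: SyntheticMovie, window: int, clip_len: int, rng) -> List[ClipSequence]:
    """Clips centered on planted mitotic figures (label 0 confounders)."""
    cfg = sm.config
    if cfg.n_mitoses == 0:
        return []
    # mitotic cells are the tracked cells that persist to the end but whose
    # track includes the condensation program; recover them by re-deriving
    # fate assignment from the seeded generator
    rng2 = np.random.default_rng(cfg.seed)
    cells = _make_cells(cfg, rng2)
    out = []
    frames = sm.movie.frames
    for i, c in enumerate(cells):
        if c.fate != "mitotic":
            continue
        tc = min(c.t0 + 2, cfg.T - 1)
        out.append(
            ClipSequence(
                frames=extract_clip(frames, c.x, c.y, tc, window, clip_len),
                label=0, center_t=tc, movie_id=sm.movie.source_id,
            )
        )
    return out
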