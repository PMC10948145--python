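"""Movie and annotation IO, intensity standardization, z-projection.

Conventions used throughout the package:

* coordinates are 0-based with ``x`` = column and ``y`` = row;
* bounding boxes are half-open ``[x_min, x_max) x [y_min, y_max)``;
* movies are ``T x H x W`` arrays of non-negative integers, volumetric
  movies ``T x Z x H x W``;
* annotation CSV columns are ``x,y,t[,label,track_id]`` (header required),
  detections ``t,x_min,y_min,x_max,y_max,prob`` and tracks
  ``track_id,t,x,y,prob``.

HDF5 layout: a single dataset ``frames`` plus scalar attributes
(``bit_depth``, ``frame_interval``, ``pixel_size``, ``source_id``,
``z_spacing``).  Multi-page TIFF pages are time for 2D movies; 4D data is
stored page-major in ``(t, z)`` order with the shape recorded in metadata.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "Timelapse", "VolumetricTimelapse", "EventAnnotation",
    "read_timelapse", "write_timelapse", "normalize_to_uint8", "max_project",
    "read_annotations", "write_annotations",
    "read_detections", "write_detections", "read_tracks", "write_tracks",
]


@dataclass
class Timelapse:
    """A single-channel 2D timelapse movie.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Non-negative integer intensities.
    bit_depth : {8, 16}
        Pixel depth; intensities must lie in ``[0, 2**bit_depth - 1]``.
    frame_interval : float
        Minutes per frame, > 0.
    pixel_size : float, optional
        Micrometers per pixel.
    source_id : str
        Free-text movie identifier.
    """

    frames: np.ndarray
    bit_depth: int = 8
    frame_interval: float = 1.0
    pixel_size: Optional[float] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"Timelapse frames must be 3D (T, H, W); got {self.frames.ndim}D"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("Timelapse must contain at least one frame")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        lo, hi = self.frames.min(), self.frames.max()
        if lo < 0 or hi > 2 ** self.bit_depth - 1:
            raise ValueError(
                f"intensities [{lo}, {hi}] out of range for {self.bit_depth}-bit data"
            )

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class VolumetricTimelapse:
    """A single-channel volumetric (3D + t) timelapse, frames ``(T, Z, H, W)``."""

    frames: np.ndarray
    bit_depth: int = 8
    frame_interval: float = 1.0
    pixel_size: Optional[float] = None
    z_spacing: Optional[float] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4:
            raise ValueError(
                f"VolumetricTimelapse frames must be 4D (T, Z, H, W); got {self.frames.ndim}D"
            )
        if self.frames.shape[0] < 1 or self.frames.shape[1] < 2:
            raise ValueError("need T >= 1 and Z >= 2")

    @property
    def shape(self) -> tuple:
        return self.frames.shape


@dataclass(frozen=True)
class EventAnnotation:
    """A point annotation of a cell-death event: centroid and start frame.

    ``t`` marks the beginning of the morphological change (nuclear
    shrinkage in adherent nuclei; membrane blebbing in leukocytes).
    """

    x: float
    y: float
    t: int
    label: int = 1
    track_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")

    def validate_against(self, movie: "Timelapse") -> None:
        T, H, W = movie.frames.shape
        if not (0 <= self.x < W and 0 <= self.y < H):
            raise ValueError(f"annotation ({self.x}, {self.y}) outside {W}x{H} frame")
        if not (0 <= self.t < T):
            raise ValueError(f"annotation frame {self.t} outside [0, {T})")


# ---------------------------------------------------------------------------
# movie readers / writers


def _infer_bit_depth(arr: np.ndarray) -> int:
    return 8 if arr.dtype == np.uint8 else 16


def read_timelapse(
    path,
    format: Optional[str] = None,
    frame_interval: float = 1.0,
    pixel_size: Optional[float] = None,
):
    """Read a 2D (T, H, W) or volumetric (T, Z, H, W) movie from TIFF or HDF5.

    ``format`` is inferred from the suffix when omitted.  Metadata stored by
    :func:`write_timelapse` takes precedence over the supplied defaults.
    Multi-channel stacks are rejected: the channel must be pre-selected.
    """
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "tiff"
    if format == "tiff":
        arr = tifffile.imread(path)
        arr = np.asarray(arr)
        if arr.ndim == 4 and arr.shape[-1] in (3, 4):
            raise ValueError("multi-channel TIFF: select a single channel first")
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim not in (3, 4):
            raise ValueError(f"cannot interpret TIFF of shape {arr.shape} as a movie")
        meta = {}
    elif format == "hdf5":
        with h5py.File(path, "r") as f:
            if "frames" not in f:
                raise ValueError(f"{path} has no 'frames' dataset")
            dset = f["frames"]
            arr = dset[()]
            meta = dict(dset.attrs)
    else:
        raise ValueError(f"unknown format {format!r}")

    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"movie must be integer-typed, got {arr.dtype}")

    kwargs = dict(
        bit_depth=int(meta.get("bit_depth", _infer_bit_depth(arr))),
        frame_interval=float(meta.get("frame_interval", frame_interval)),
        source_id=str(meta.get("source_id", path.stem)),
    )
    px = meta.get("pixel_size", pixel_size)
    kwargs["pixel_size"] = None if px is None or px <= 0 else float(px)
    if arr.ndim == 3:
        return Timelapse(frames=arr, **kwargs)
    zs = meta.get("z_spacing", None)
    return VolumetricTimelapse(
        frames=arr, z_spacing=None if zs is None or zs <= 0 else float(zs), **kwargs
    )


def write_timelapse(movie, path, format: Optional[str] = None) -> None:
    """Write a :class:`Timelapse` or :class:`VolumetricTimelapse` to disk."""
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "tiff"
    dtype = np.uint8 if movie.bit_depth == 8 else np.uint16
    arr = movie.frames.astype(dtype, copy=False)
    if format == "tiff":
        # 4D data is written page-major in (t, z) order
        tifffile.imwrite(path, arr.reshape((-1,) + arr.shape[-2:]) if arr.ndim == 4 else arr)
    elif format == "hdf5":
        with h5py.File(path, "w") as f:
            dset = f.create_dataset("frames", data=arr)
            dset.attrs["bit_depth"] = movie.bit_depth
            dset.attrs["frame_interval"] = movie.frame_interval
            dset.attrs["pixel_size"] = -1.0 if movie.pixel_size is None else movie.pixel_size
            dset.attrs["source_id"] = movie.source_id
            if isinstance(movie, VolumetricTimelapse):
                dset.attrs["z_spacing"] = -1.0 if movie.z_spacing is None else movie.z_spacing
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# intensity standardization and projection


def normalize_to_uint8(
    movie: Timelapse, q_low: float = 0.001, q_high: float = 0.999
) -> Timelapse:
    """Quantile min-max scale a movie to 8-bit.

    Intensities are linearly mapped so that the whole-movie ``q_low``
    quantile goes to 0 and the ``q_high`` quantile to 255, clipped to
    [0, 255] and floored.  Quantiles use linear interpolation over the
    sorted whole-movie sample.  A constant movie maps to all zeros (with a
    warning) so batch processing never aborts.
    """
    if not 0 <= q_low < q_high <= 1:
        raise ValueError(f"need 0 <= q_low < q_high <= 1, got {q_low}, {q_high}")
    data = movie.frames.astype(np.float64)
    lo, hi = np.quantile(data, [q_low, q_high])
    if hi <= lo:
        warnings.warn(
            f"movie {movie.source_id!r} is constant over the [{q_low}, {q_high}] "
            "quantile range; normalizing to all zeros"
        )
        out = np.zeros(movie.frames.shape, dtype=np.uint8)
    else:
        scaled = (data - lo) / (hi - lo) * 255.0
        out = np.floor(np.clip(scaled, 0, 255)).astype(np.uint8)
    return Timelapse(
        frames=out,
        bit_depth=8,
        frame_interval=movie.frame_interval,
        pixel_size=movie.pixel_size,
        source_id=movie.source_id,
    )


def max_project(volume: VolumetricTimelapse) -> Timelapse:
    """Per-frame maximum-intensity projection along z, (T,Z,H,W) -> (T,H,W)."""
    return Timelapse(
        frames=volume.frames.max(axis=1),
        bit_depth=volume.bit_depth,
        frame_interval=volume.frame_interval,
        pixel_size=volume.pixel_size,
        source_id=volume.source_id,
    )


# ---------------------------------------------------------------------------
# annotations / detections / tracks CSV


def read_annotations(path, movie: Optional[Timelapse] = None) -> list:
    """Read event annotations from CSV with columns ``x,y,t[,label,track_id]``.

    Coordinates are 0-based.  ``label`` defaults to 1 (apoptotic).  When a
    movie is supplied, each annotation is validated against its bounds.
    """
    df = pd.read_csv(path)
    missing = {"x", "y", "t"} - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        tid = getattr(row, "track_id", None)
        if tid is not None and pd.isna(tid):
            tid = None
        ann = EventAnnotation(
            x=float(row.x),
            y=float(row.y),
            t=int(row.t),
            label=int(getattr(row, "label", 1)),
            track_id=None if tid is None else int(tid),
        )
        if movie is not None:
            ann.validate_against(movie)
        out.append(ann)
    return out


def write_annotations(annotations: Sequence[EventAnnotation], path) -> None:
    pd.DataFrame(
        {
            "x": [a.x for a in annotations],
            "y": [a.y for a in annotations],
            "t": [a.t for a in annotations],
            "label": [a.label for a in annotations],
            "track_id": [a.track_id for a in annotations],
        }
    ).to_csv(path, index=False)


def write_detections(detections, path) -> None:
    """Write detections as ``t,x_min,y_min,x_max,y_max,prob``."""
    pd.DataFrame(
        {
            "t": [d.t for d in detections],
            "x_min": [d.box.x_min for d in detections],
            "y_min": [d.box.y_min for d in detections],
            "x_max": [d.box.x_max for d in detections],
            "y_max": [d.box.y_max for d in detections],
            "prob": [d.prob for d in detections],
        }
    ).to_csv(path, index=False)


def read_detections(path):
    from .pipeline import Detection
    from .proposal import RoiBox

    df = pd.read_csv(path)
    missing = {"t", "x_min", "y_min", "x_max", "y_max", "prob"} - set(df.columns)
    if missing:
        raise ValueError(f"detection CSV missing columns {sorted(missing)}")
    return [
        Detection(
            t=int(r.t),
            box=RoiBox(
                t=int(r.t),
                x_min=int(r.x_min),
                y_min=int(r.y_min),
                x_max=int(r.x_max),
                y_max=int(r.y_max),
            ),
            prob=float(r.prob),
        )
        for r in df.itertuples(index=False)
    ]


def write_tracks(tracks, path) -> None:
    """Write tracks as ``track_id,t,x,y,prob`` rows, one per detection."""
    rows = []
    for tr in tracks:
        for d in tr.detections:
            cx, cy = d.box.center
            rows.append((tr.track_id, d.t, cx, cy, d.prob))
    pd.DataFrame(rows, columns=["track_id", "t", "x", "y", "prob"]).to_csv(
        path, index=False
    )


def read_tracks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"track_id", "t", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns {sorted(missing)}")
    return df
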