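"""Volumetric augmentation: random 3D rotation + re-projection.

Scarce volumetric event sequences are expanded by rotating each frame's
volume about a random 3D axis by an angle up to 45 degrees, flattening by
maximum projection, symmetric-padding to the pre-rotation footprint, and
resizing/cropping to the classifier's 59 x 59 input.  The same (angle,
axis) draw is reused for every frame of one sequence, so temporal
coherence is preserved.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi

from .data import CLIP_SIZE

__all__ = ["rotate_project", "expand_dataset", "rotation_matrix"]


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis (z, y, x order)."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("rotation axis must be a nonzero vector")
    axis = axis / norm
    th = np.deg2rad(angle_deg)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def _resize_crop(img: np.ndarray, out_size: int) -> np.ndarray:
    """Center-crop larger images; symmetric-pad smaller ones."""
    H, W = img.shape
    if H > out_size:
        o = (H - out_size) // 2
        img = img[o:o + out_size, :]
    if W > out_size:
        o = (W - out_size) // 2
        img = img[:, o:o + out_size]
    H, W = img.shape
    if H < out_size or W < out_size:
        pt, pl = (out_size - H) // 2, (out_size - W) // 2
        img = np.pad(img, ((pt, out_size - H - pt), (pl, out_size - W - pl)),
                     mode="symmetric")
    return img


def rotate_project(
    seq: Sequence[np.ndarray],
    angle_deg: float,
    axis: Sequence[float],
    out_size: int = CLIP_SIZE,
    voxel_spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Rotate each (Z, H, W) volume of a sequence and max-project to 2D.

    The volume is first resampled to an isotropic grid (trilinear), then
    rotated about its center by ``angle_deg`` around ``axis`` (z, y, x
    direction), max-projected along z, padded symmetrically to the
    pre-rotation footprint and resized/cropped to ``out_size``.
    Out-of-volume samples fill with the volume's background median.
    Output intensities never leave the input range.
    """
    if not 0 <= angle_deg <= 45:
        raise ValueError("angle must be within [0, 45] degrees")
    R = rotation_matrix(np.asarray(axis, dtype=float), angle_deg)
    out = []
    for vol in seq:
        vol = np.asarray(vol)
        if vol.ndim != 3:
            raise ValueError("each sequence element must be a (Z, H, W) volume")
        lo, hi = float(vol.min()), float(vol.max())
        v = vol.astype(np.float32)
        spacing = np.asarray(voxel_spacing, dtype=float)
        if not np.allclose(spacing, spacing[0]):
            zoom = spacing / spacing.min()
            v = ndi.zoom(v, zoom, order=1)
        fill = float(np.median(v))
        if angle_deg > 0:
            center = (np.array(v.shape) - 1) / 2.0
            offset = center - R.T @ center
            v = ndi.affine_transform(v, R.T, offset=offset, order=1,
                                     mode="constant", cval=fill)
        proj = v.max(axis=0)
        proj = _resize_crop(proj, out_size)
        out.append(np.clip(proj, lo, hi))
    stack = np.stack(out)
    if np.issubdtype(np.asarray(seq[0]).dtype, np.integer):
        stack = np.round(stack).astype(np.asarray(seq[0]).dtype)
    return stack


def expand_dataset(
    sequences: Sequence[Sequence[np.ndarray]],
    k_per_sequence: int = 100,
    max_angle: float = 45.0,
    out_size: int = CLIP_SIZE,
    seed: int = 0,
) -> List[np.ndarray]:
    """k independently drawn (angle, axis) rotations per input sequence.

    Directions are uniform on the sphere, angles uniform in
    [0, max_angle]; one draw is shared by all frames of a sequence.
    Returns ``len(sequences) * k_per_sequence`` projected clip stacks,
    deterministic under ``seed``.
    """
    if k_per_sequence < 1:
        raise ValueError("k_per_sequence must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for seq in sequences:
        for _ in range(k_per_sequence):
            axis = rng.normal(size=3)
            while np.linalg.norm(axis) < 1e-9:
                axis = rng.normal(size=3)
            angle = float(rng.uniform(0, max_angle))
            out.append(rotate_project(seq, angle, axis, out_size=out_size))
    return out
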