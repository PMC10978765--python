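"""Intensity normalisation and geometric augmentation for the two networks.

The segmentation network consumes percentile-normalised intensities
(quantile window 0.05-0.95, clipped to [0, 1]); the classifier consumes
min-max normalised mask volumes.  Augmentation applies one shared random
rigid + isotropic-scale transform to an intensity volume and its label map
(linear interpolation for intensities, nearest neighbour for labels) so
that the pair stays aligned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from deshkit.io import LabelMap, Volume

__all__ = [
    "AugmentParams",
    "percentile_normalize",
    "minmax_normalize",
    "augment_pair",
]


def percentile_normalize(v: Volume, p_lo: float = 0.05, p_hi: float = 0.95) -> Volume:
    """Clip-normalise intensities by the (p_lo, p_hi) quantile window.

    With ``a = quantile(p_lo)`` and ``b = quantile(p_hi)`` the output is
    ``clip((v - a) / (b - a), 0, 1)``; a constant (a == b) volume maps to
    all zeros.  Quantiles use linear interpolation between order statistics.
    """
    data = np.asarray(v.data, dtype=np.float32)
    a, b = np.quantile(data, [p_lo, p_hi], method="linear")
    if b <= a:
        out = np.zeros_like(data)
    else:
        out = np.clip((data - a) / (b - a), 0.0, 1.0).astype(np.float32)
    return Volume(out, v.voxel_size_mm, v.origin_mm)


def minmax_normalize(v: Volume) -> Volume:
    """Map intensities affinely onto [0, 1]; constant input maps to zeros."""
    data = np.asarray(v.data, dtype=np.float32)
    lo = float(data.min())
    hi = float(data.max())
    if hi <= lo:
        out = np.zeros_like(data)
    else:
        out = ((data - lo) / (hi - lo)).astype(np.float32)
    return Volume(out, v.voxel_size_mm, v.origin_mm)


@dataclass
class AugmentParams:
    """Ranges of the random rigid+scale augmentation (sampled uniformly)."""

    rotation_deg_range: tuple[float, float] = (-10.0, 10.0)
    scale_range: tuple[float, float] = (0.9, 1.1)
    translation_mm_range: tuple[float, float] = (-5.0, 5.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.scale_range
        if not (0 < lo <= hi) or not np.isfinite([lo, hi]).all():
            raise ValueError(f"scale_range must be finite and positive, got {self.scale_range}")


def _sample_transform(params: AugmentParams, rng: np.random.Generator):
    angles = np.deg2rad(rng.uniform(*params.rotation_deg_range, size=3))
    scale = float(rng.uniform(*params.scale_range))
    shift_mm = rng.uniform(*params.translation_mm_range, size=3)
    return angles, scale, shift_mm


def _rotation_matrix(angles: np.ndarray) -> np.ndarray:
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def augment_pair(
    v: Volume,
    m: LabelMap,
    params: AugmentParams,
    rng: np.random.Generator | None = None,
    background_code: int = 0,
) -> tuple[Volume, LabelMap]:
    """Apply one shared random rotation/scale/translation to a volume+labels pair.

    The transform is about the grid centre, sampled once and applied to both
    inputs: intensities with linear interpolation (out-of-field -> 0), labels
    with nearest neighbour (out-of-field -> ``background_code``).  Identity
    ranges return the inputs unchanged.
    """
    if v.shape != m.shape:
        raise ValueError(f"volume and label grids differ: {v.shape} vs {m.shape}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    angles, scale, shift_mm = _sample_transform(params, rng)

    if not angles.any() and scale == 1.0 and not shift_mm.any():
        return (
            Volume(v.data.copy(), v.voxel_size_mm, v.origin_mm),
            LabelMap(m.data.copy(), m.voxel_size_mm, m.origin_mm, m.categories),
        )

    spacing = np.asarray(v.voxel_size_mm)
    centre = (np.asarray(v.shape) - 1) / 2.0
    rot = _rotation_matrix(angles)
    # Output voxel x maps to input voxel: inverse transform in voxel space,
    # with rotation/scaling performed in world mm about the grid centre.
    world = np.diag(spacing)
    world_inv = np.diag(1.0 / spacing)
    mat = world_inv @ np.linalg.inv(rot * scale) @ world
    offset = centre - mat @ centre + world_inv @ np.linalg.inv(rot * scale) @ (-shift_mm)

    out_v = ndimage.affine_transform(
        np.asarray(v.data, dtype=np.float32), mat, offset=offset, order=1, mode="constant", cval=0.0
    )
    out_m = ndimage.affine_transform(
        m.data, mat, offset=offset, order=0, mode="constant", cval=background_code
    )
    return (
        Volume(out_v, v.voxel_size_mm, v.origin_mm),
        LabelMap(out_m, m.voxel_size_mm, m.origin_mm, m.categories),
    )
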