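"""Resampling to the common analysis grid, intensity normalization and
patch extraction.

Multi-center PET scans arrive on heterogeneous voxel grids (e.g.
4.073x4.073x2.027 mm on one scanner, 4x4x4 mm on another).  CNN input must
live on a single grid, so every scan and its mask are linearly interpolated
to a common spacing (4x4x2 mm by default — the fine axial pitch keeps small
lesions resolvable).  Intensities are then Z-scored per scan using only the
non-zero (body) voxels, and training samples are fixed-size patches cut from
the normalized volume.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import DegenerateInputError
from .grids import BinaryMask3D, Volume3D, _as_triple

#: Common analysis grid spacing in mm.
COMMON_SPACING = (4.0, 4.0, 2.0)


def _output_shape(shape, native_spacing, target_spacing) -> tuple[int, int, int]:
    # round(native extent / target spacing), at least one voxel per axis
    return tuple(
        max(1, int(round(n * s / t)))
        for n, s, t in zip(shape, native_spacing, target_spacing)
    )


def _resample_values(
    values: np.ndarray,
    native_spacing,
    target_spacing,
    out_shape=None,
    *,
    order: int = 1,
) -> np.ndarray:
    if out_shape is None:
        out_shape = _output_shape(values.shape, native_spacing, target_spacing)
    axes = [
        np.arange(n, dtype=float) * t / s
        for n, t, s in zip(out_shape, target_spacing, native_spacing)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    return map_coordinates(
        np.asarray(values, dtype=float), coords, order=order, mode="nearest"
    )


def resample_volume(
    v: Volume3D,
    target_spacing=COMMON_SPACING,
    *,
    out_shape=None,
    nearest: bool = False,
) -> Volume3D:
    """Linearly interpolate a volume onto ``target_spacing``.

    The output shape is ``round(native_shape * native_spacing /
    target_spacing)`` per axis (minimum 1), so the field of view is preserved
    to within half a voxel.  Linear interpolation is the default; nearest
    neighbour sits behind a flag.
    """
    target_spacing = _as_triple(target_spacing)
    if any(t <= 0 for t in target_spacing):
        raise ValueError("target spacing must be strictly positive")
    out = _resample_values(
        v.values, v.spacing, target_spacing, out_shape, order=0 if nearest else 1
    )
    return Volume3D(out, target_spacing, v.origin)


def resample_mask(
    m: BinaryMask3D,
    target_spacing=COMMON_SPACING,
    *,
    out_shape=None,
    nearest: bool = False,
    threshold: float = 0.5,
) -> BinaryMask3D:
    """Resample a binary mask: linear interpolation of the ``{0,1}`` field
    followed by thresholding at 0.5 (nearest neighbour behind a flag)."""
    target_spacing = _as_triple(target_spacing)
    if any(t <= 0 for t in target_spacing):
        raise ValueError("target spacing must be strictly positive")
    field = _resample_values(
        m.values.astype(float),
        m.spacing,
        target_spacing,
        out_shape,
        order=0 if nearest else 1,
    )
    return BinaryMask3D((field >= threshold).astype(np.uint8), target_spacing, m.origin)


def znormalize(v: Volume3D) -> Volume3D:
    """Per-scan Z-score using statistics of the non-zero (body) voxels only.

    Every voxel — including the zero-valued background — is mapped through
    the same affine ``(x - mu) / sd``; only the statistics are restricted to
    the body.  Raises :class:`DegenerateInputError` when the scan is all zero
    or the body intensities are constant.
    """
    vals = np.asarray(v.values, dtype=float)
    body = vals != 0
    n = int(body.sum())
    if n == 0:
        raise DegenerateInputError("scan has no non-zero voxels")
    mu = float(vals[body].mean())
    sd = float(vals[body].std())
    if sd == 0.0:
        raise DegenerateInputError("non-zero voxels are constant; Z-score undefined")
    return Volume3D((vals - mu) / sd, v.spacing, v.origin)


@dataclass
class Patch:
    """A fixed-size training sample: an image crop and its mask crop."""

    volume: np.ndarray
    mask: np.ndarray
    case_id: str = ""
    corner: tuple[int, int, int] = (0, 0, 0)
    spacing: tuple[float, float, float] = COMMON_SPACING

    def copy(self) -> "Patch":
        return Patch(
            self.volume.copy(), self.mask.copy(), self.case_id, self.corner, self.spacing
        )


def _pad_to(arr: np.ndarray, size) -> np.ndarray:
    pad = [(0, max(0, p - s)) for s, p in zip(arr.shape, size)]
    if any(p[1] for p in pad):
        arr = np.pad(arr, pad)
    return arr


def extract_patch(
    volume_values: np.ndarray,
    mask_values: np.ndarray,
    patch_size,
    rng: np.random.Generator,
    *,
    case_id: str = "",
    spacing=COMMON_SPACING,
    fg_bias: float = 0.0,
) -> Patch:
    """Cut a random ``patch_size`` crop from a (normalized) volume and mask.

    The corner is uniform over all valid positions; volumes smaller than the
    patch are zero-padded first (zero is the pre-normalization background and
    stays out of the body statistics).  With probability ``fg_bias`` the
    corner is instead drawn so the patch contains at least one foreground
    voxel (oversampling of lesion-bearing patches; off by default).
    """
    patch_size = tuple(int(p) for p in patch_size)
    vol = _pad_to(np.asarray(volume_values), patch_size)
    msk = _pad_to(np.asarray(mask_values), patch_size)
    max_corner = [s - p for s, p in zip(vol.shape, patch_size)]
    if fg_bias > 0 and msk.any() and rng.random() < fg_bias:
        fg = np.argwhere(msk)
        t = fg[rng.integers(len(fg))]
        corner = tuple(
            int(rng.integers(max(0, ti - p + 1), min(mc, ti) + 1))
            for ti, p, mc in zip(t, patch_size, max_corner)
        )
    else:
        corner = tuple(int(rng.integers(0, mc + 1)) for mc in max_corner)
    sl = tuple(slice(c, c + p) for c, p in zip(corner, patch_size))
    return Patch(
        vol[sl].astype(np.float32, copy=True),
        msk[sl].astype(np.uint8, copy=True),
        case_id,
        corner,
        tuple(spacing),
    )


def mask_volume_cm3(m: BinaryMask3D) -> float:
    """Mask volume in cm^3: voxel count times voxel volume."""
    voxel_mm3 = float(np.prod(m.spacing))
    return m.voxel_count * voxel_mm3 / 1000.0
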