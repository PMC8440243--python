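"""In-memory containers for PET volumes and binary masks.

A :class:`Volume3D` is a scalar intensity grid together with its voxel
spacing in millimetres and a world-space origin; a :class:`BinaryMask3D` is a
``{0,1}`` grid on the same lattice.  Arrays are indexed ``(i, j, k)`` with the
world position of a voxel centre at ``origin + index * spacing`` (NIfTI-style
node-centred convention, diagonal affine).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError

Triple = tuple[float, float, float]


def _as_triple(x) -> Triple:
    t = tuple(float(v) for v in np.atleast_1d(np.asarray(x, dtype=float)).ravel())
    if len(t) == 1:
        t = t * 3
    if len(t) != 3:
        raise ValueError(f"expected a scalar or length-3 spacing/origin, got {x!r}")
    return t  # type: ignore[return-value]


@dataclass
class Volume3D:
    """A 3-D scalar intensity grid (the PET image)."""

    values: np.ndarray
    spacing: Triple
    origin: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("Volume3D expects a 3-D array")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def copy(self) -> "Volume3D":
        return Volume3D(self.values.copy(), self.spacing, self.origin)


@dataclass
class BinaryMask3D:
    """A 3-D ``{0,1}`` label grid aligned with a :class:`Volume3D`."""

    values: np.ndarray
    spacing: Triple
    origin: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError("BinaryMask3D expects a 3-D array")
        if arr.dtype != np.uint8:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be 0 or 1")
            arr = arr.astype(np.uint8)
        self.values = arr
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def astype_bool(self) -> np.ndarray:
        return self.values.astype(bool)

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    def copy(self) -> "BinaryMask3D":
        return BinaryMask3D(self.values.copy(), self.spacing, self.origin)


def check_aligned(volume: Volume3D, mask: BinaryMask3D, *, atol: float = 1e-4) -> None:
    """Raise :class:`AlignmentError` unless mask and volume share grid and spacing."""
    if volume.shape != mask.shape:
        raise AlignmentError(
            f"shape mismatch: volume {volume.shape} vs mask {mask.shape}"
        )
    if not np.allclose(volume.spacing, mask.spacing, atol=atol):
        raise AlignmentError(
            f"spacing mismatch: volume {volume.spacing} vs mask {mask.spacing}"
        )
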