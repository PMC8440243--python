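"""Whole-volume prediction with overlapping sliding windows.

Volumes of arbitrary size are covered by windows of the training patch size
at 50% overlap; window probabilities are averaged where they overlap (the
internal weight map is asserted to be positive everywhere and normalizes to
one).  Predicted masks can be resampled back to each case's native grid.
"""
from __future__ import annotations

import numpy as np

from .grids import BinaryMask3D, Volume3D
from .nn.modules import Module
from .nn.tensor import Tensor, no_grad
from .preprocessing import resample_mask


def sliding_window_starts(size: int, window: int, step: int | None = None) -> list[int]:
    """Start offsets covering ``[0, size)`` with ``window``-long windows at
    50% overlap (step = window // 2); the last window is clamped so the far
    edge is always covered."""
    step = step or max(1, window // 2)
    if size <= window:
        return [0]
    starts = list(range(0, size - window + 1, step))
    if starts[-1] != size - window:
        starts.append(size - window)
    return starts


def predict_volume(
    model: Module,
    v: Volume3D | np.ndarray,
    patch_size=None,
    *,
    return_weights: bool = False,
):
    """Probability map for a preprocessed (resampled + normalized) volume.

    Volumes smaller than one window are zero-padded and the output cropped
    back; a volume of exactly one window reduces to a single forward pass.
    """
    values = v.values if isinstance(v, Volume3D) else np.asarray(v)
    patch_size = tuple(patch_size) if patch_size is not None else (128, 128, 64)
    orig_shape = values.shape
    pad = [(0, max(0, p - s)) for s, p in zip(orig_shape, patch_size)]
    if any(p[1] for p in pad):
        values = np.pad(values, pad)
    shape = values.shape
    prob = np.zeros(shape, dtype=np.float64)
    weight = np.zeros(shape, dtype=np.float64)
    starts = [sliding_window_starts(s, p) for s, p in zip(shape, patch_size)]
    for i in starts[0]:
        for j in starts[1]:
            for k in starts[2]:
                sl = (
                    slice(i, i + patch_size[0]),
                    slice(j, j + patch_size[1]),
                    slice(k, k + patch_size[2]),
                )
                with no_grad():
                    pred = model(Tensor(values[sl][None, None].astype(np.float32)))
                prob[sl] += pred.data[0, 0]
                weight[sl] += 1.0
    assert (weight > 0).all(), "sliding windows left voxels uncovered"
    prob /= weight
    crop = tuple(slice(0, s) for s in orig_shape)
    if return_weights:
        return prob[crop], (weight / weight)[crop]
    return prob[crop]


def binarize(
    p: np.ndarray, threshold: float = 0.5, *, spacing=None, largest_component: bool = False
) -> BinaryMask3D | np.ndarray:
    """Threshold a probability map: mask = (p >= threshold).

    Largest-connected-component postprocessing is available but OFF by
    default — the pipeline uses no anatomical-prior postprocessing.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    mask = (np.asarray(p) >= threshold).astype(np.uint8)
    if largest_component and mask.any():
        from scipy.ndimage import label

        lab, n = label(mask)
        if n > 1:
            sizes = np.bincount(lab.ravel())[1:]
            mask = (lab == (1 + int(np.argmax(sizes)))).astype(np.uint8)
    if spacing is None:
        return mask
    return BinaryMask3D(mask, spacing)


def to_native_grid(mask: BinaryMask3D, native_spacing, native_shape=None) -> BinaryMask3D:
    """Resample a predicted mask from the common analysis grid back to the
    case's native grid (linear interpolation of the indicator, 0.5 cut)."""
    return resample_mask(mask, native_spacing, out_shape=native_shape)
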