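"""Training objective and evaluation metrics.

The training loss is the Soft Dice loss with Laplacian (+1) smoothing

    L(y, yhat) = 1 - (2 * sum_i y_i yhat_i + 1) / (sum_i y_i^2 + sum_i yhat_i^2 + 1)

computed over the whole patch and averaged over the batch; the +1 terms keep
the ratio defined when a patch contains a single class.  Evaluation uses the
Dice similarity coefficient together with precision (positive predictive
value) and recall (sensitivity); DSC is the harmonic mean of the two,
DSC = 2PR/(P+R).  The fixed-threshold baseline T40 segments at 40% of the
maximum uptake inside a search region.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation


from .grids import BinaryMask3D, Volume3D
from .nn.tensor import Tensor


def _soft_dice_np(pred: np.ndarray, target: np.ndarray, smooth: float = 1.0) -> float:
    p = pred.reshape(-1).astype(float)
    y = target.reshape(-1).astype(float)
    num = 2.0 * float(p @ y) + smooth
    den = float(y @ y) + float(p @ p) + smooth
    return 1.0 - num / den


def soft_dice_loss(pred, target, smooth: float = 1.0):
    """Soft Dice loss.

    NumPy inputs give a float; :class:`Tensor` predictions give a scalar
    Tensor for backpropagation.  5-D inputs ``(B, 1, X, Y, Z)`` are treated
    as a batch and the per-sample losses averaged; lower-dimensional inputs
    are a single example.
    """
    if isinstance(pred, Tensor):
        return soft_dice_loss_tensor(pred, target, smooth)
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if pred.ndim == 5:
        return float(
            np.mean([_soft_dice_np(p, t, smooth) for p, t in zip(pred, target)])
        )
    return _soft_dice_np(pred, target, smooth)


def soft_dice_loss_tensor(pred: Tensor, target: np.ndarray, smooth: float = 1.0) -> Tensor:
    """Differentiable Soft Dice on (B, 1, X, Y, Z) prediction tensors."""
    y = np.asarray(target, dtype=pred.data.dtype)
    if y.ndim == pred.ndim - 2:  # allow a single unbatched grid
        y = y[None, None]
    elif y.ndim == pred.ndim - 1:
        y = y[:, None]
    if y.shape != pred.data.shape:
        raise ValueError(f"shape mismatch: {pred.data.shape} vs {y.shape}")
    axes = tuple(range(1, pred.ndim))
    yt = Tensor(y)
    num = (pred * yt).sum(axis=axes) * 2.0 + smooth
    den = (pred * pred).sum(axis=axes) + Tensor((y * y).sum(axis=axes)) + smooth
    return (1.0 - num / den).mean()


@dataclass
class CaseMetrics:
    """Per-case confusion counts and overlap metrics."""

    dsc: float
    precision: float
    recall: float
    tp: int
    fp: int
    fn: int
    truth_voxels: int
    truth_volume_cm3: float = float("nan")
    contrast: float = float("nan")
    case_id: str = ""
    center: str = ""


def case_metrics(
    pred_mask,
    truth_mask,
    *,
    spacing=None,
    contrast: float = float("nan"),
    case_id: str = "",
    center: str = "",
) -> CaseMetrics:
    """Voxel-level DSC / precision / recall of a predicted binary mask.

    Edge conventions: both masks empty -> all metrics 1 (the prediction is
    vacuously perfect); prediction empty with non-empty truth (or vice
    versa) -> all metrics 0.
    """
    if isinstance(pred_mask, BinaryMask3D):
        spacing = spacing or pred_mask.spacing
        pred_mask = pred_mask.values
    if isinstance(truth_mask, BinaryMask3D):
        spacing = spacing or truth_mask.spacing
        truth_mask = truth_mask.values
    p = np.asarray(pred_mask).astype(bool)
    y = np.asarray(truth_mask).astype(bool)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    tp = int((p & y).sum())
    fp = int((p & ~y).sum())
    fn = int((~p & y).sum())
    if tp + fp + fn == 0:
        dsc = precision = recall = 1.0
    else:
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        recall = tp / (tp + fn) if (tp + fn) else 0.0
        dsc = 2 * tp / (2 * tp + fp + fn)
    vol = float("nan")
    if spacing is not None:
        vol = int(y.sum()) * float(np.prod(spacing)) / 1000.0
    return CaseMetrics(
        dsc, precision, recall, tp, fp, fn, int(y.sum()), vol, contrast, case_id, center
    )


def t40_segment(volume: Volume3D, region: BinaryMask3D) -> BinaryMask3D:
    """Fixed-threshold segmentation at 40% of the maximum uptake within the
    search region: the returned mask is the region voxels whose intensity is
    at or above that threshold."""
    reg = region.astype_bool()
    if not reg.any():
        raise ValueError("T40 requires a non-empty search region")
    vals = np.asarray(volume.values)
    thr = 0.4 * float(vals[reg].max())
    out = reg & (vals >= thr)
    return BinaryMask3D(out.astype(np.uint8), region.spacing, region.origin)


def t40_search_region(truth: BinaryMask3D, dilate_voxels: int = 2) -> BinaryMask3D:
    """Search region used when running T40 as a fully automatic baseline:
    the truth bounding box dilated by a fixed number of voxels.  A permissive
    region — near a hot bladder the 40% threshold latches onto the bladder
    maximum, which is exactly the failure mode the baseline exhibits."""
    y = truth.astype_bool()
    if not y.any():
        raise ValueError("empty truth mask")
    region = np.zeros_like(y)
    idx = np.argwhere(y)
    lo = np.maximum(idx.min(axis=0) - dilate_voxels, 0)
    hi = np.minimum(idx.max(axis=0) + dilate_voxels + 1, y.shape)
    region[tuple(slice(a, b) for a, b in zip(lo, hi))] = True
    return BinaryMask3D(region.astype(np.uint8), truth.spacing, truth.origin)


def operational_contrast(
    volume: Volume3D, truth: BinaryMask3D, bladder: BinaryMask3D | None = None,
    shell_voxels: int = 2,
) -> float:
    """Tumor-to-surround contrast statistic: maximum intensity inside the
    truth mask divided by the mean intensity in a 2-voxel peritumoral shell
    (bladder voxels excluded from the shell)."""
    y = truth.astype_bool()
    shell = binary_dilation(y, iterations=shell_voxels) & ~y
    if bladder is not None:
        shell &= ~bladder.astype_bool()
    vals = np.asarray(volume.values)
    if not y.any() or not shell.any():
        return float("nan")
    denom = float(vals[shell].mean())
    if denom <= 0:
        return float("inf")
    return float(vals[y].max()) / denom
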