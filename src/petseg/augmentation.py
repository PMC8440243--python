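"""Stochastic training-time transforms.

Each transform acts jointly on a patch's image and mask; intensity
transforms leave the mask untouched, spatial transforms move both and
re-binarize the mask.  During training every transform is applied
independently with probability ``p_apply`` (0.2 by default), in a fixed
order — spatial before intensity — so the intensity statistics seen by the
intensity transforms are those of the already-warped sample.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import affine_transform, gaussian_filter, map_coordinates, zoom

from .preprocessing import Patch

_EPS = 1e-12


@dataclass
class AugmentConfig:
    p_apply: float = 0.2
    rotation_deg_range: tuple[float, float] = (5.0, 15.0)
    scale_range: tuple[float, float] = (0.8, 1.2)
    gamma_range: tuple[float, float] = (0.8, 1.2)
    contrast_upper_range: tuple[float, float] = (0.8, 1.2)
    noise_sd_range: tuple[float, float] = (0.1, 0.2)
    elastic_grid_points: int = 4
    elastic_max_disp_mm: float = 5.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "rotation_deg_range",
            "scale_range",
            "gamma_range",
            "contrast_upper_range",
            "noise_sd_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered (lo <= hi)")
        if not 0.0 <= self.p_apply <= 1.0:
            raise ValueError("p_apply must be in [0, 1]")


# ---------------------------------------------------------------------------
# spatial transforms


def mirror_axial(patch: Patch) -> Patch:
    """Flip the patch left-right in the axial plane (first in-plane axis);
    image and mask flip together.  Applying it twice is the identity."""
    return Patch(
        np.flip(patch.volume, axis=0).copy(),
        np.flip(patch.mask, axis=0).copy(),
        patch.case_id,
        patch.corner,
        patch.spacing,
    )


def sample_affine_params(rng: np.random.Generator, config: AugmentConfig):
    """Draw (angles_deg per axis, scale). Each rotation axis is included with
    probability 1/2, at least one forced; angle magnitudes are uniform over
    the configured range with random sign; one isotropic scale factor."""
    axes = rng.random(3) < 0.5
    if not axes.any():
        axes[rng.integers(3)] = True
    lo, hi = config.rotation_deg_range
    angles = np.where(
        axes, rng.uniform(lo, hi, size=3) * rng.choice([-1.0, 1.0], size=3), 0.0
    )
    scale = float(rng.uniform(*config.scale_range))
    return angles, scale


def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    r = np.eye(3)
    for axis, ang in enumerate(angles_deg):
        if ang == 0:
            continue
        c, s = np.cos(np.radians(ang)), np.sin(np.radians(ang))
        i, j = [a for a in range(3) if a != axis]
        m = np.eye(3)
        m[i, i] = c
        m[j, j] = c
        m[i, j] = -s
        m[j, i] = s
        r = m @ r
    return r


def random_affine(patch: Patch, rng: np.random.Generator, config: AugmentConfig) -> Patch:
    """Random rotation about a random axis subset plus isotropic scaling,
    about the patch centre.  Scale > 1 enlarges the object; the image is
    linearly interpolated and the mask re-binarized at 0.5."""
    angles, scale = sample_affine_params(rng, config)
    rot = _rotation_matrix(angles)
    # affine_transform maps output coords -> input coords
    mat = rot.T / scale
    center = (np.asarray(patch.volume.shape, dtype=float) - 1) / 2.0
    offset = center - mat @ center
    vol = affine_transform(patch.volume.astype(float), mat, offset=offset, order=1)
    msk = affine_transform(patch.mask.astype(float), mat, offset=offset, order=1)
    return Patch(
        vol.astype(np.float32),
        (msk >= 0.5).astype(np.uint8),
        patch.case_id,
        patch.corner,
        patch.spacing,
    )


def elastic_deform(patch: Patch, rng: np.random.Generator, config: AugmentConfig) -> Patch:
    """Smooth random displacement field from a coarse control grid, applied
    jointly to image and mask (mask re-binarized).  Displacement magnitude is
    bounded by ``elastic_max_disp_mm`` per axis."""
    if config.elastic_max_disp_mm <= 0:
        return patch.copy()
    shape = patch.volume.shape
    disp = []
    for axis in range(3):
        coarse = rng.uniform(-1.0, 1.0, size=(config.elastic_grid_points,) * 3)
        fine = zoom(coarse, [s / config.elastic_grid_points for s in shape], order=3)
        fine = fine[tuple(slice(0, s) for s in shape)]
        peak = np.abs(fine).max()
        if peak > 0:
            fine = fine / peak
        max_vox = config.elastic_max_disp_mm / patch.spacing[axis]
        disp.append(fine * max_vox)
    coords = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    coords = [c + d for c, d in zip(coords, disp)]
    vol = map_coordinates(patch.volume.astype(float), coords, order=1, mode="nearest")
    msk = map_coordinates(patch.mask.astype(float), coords, order=1, mode="nearest")
    return Patch(
        vol.astype(np.float32),
        (msk >= 0.5).astype(np.uint8),
        patch.case_id,
        patch.corner,
        patch.spacing,
    )


# ---------------------------------------------------------------------------
# intensity transforms


def gamma_correct(patch: Patch, rng: np.random.Generator, config: AugmentConfig) -> Patch:
    """Power-law intensity transform: the patch range is mapped to [0, 1],
    raised to gamma ~ U(range), and mapped back.  Monotone; the detour
    through [0, 1] keeps the power law defined on Z-scored (negative)
    intensities."""
    gamma = float(rng.uniform(*config.gamma_range))
    v = patch.volume.astype(float)
    lo, hi = float(v.min()), float(v.max())
    if hi - lo < _EPS:
        return patch.copy()
    out = ((v - lo) / (hi - lo)) ** gamma * (hi - lo) + lo
    return Patch(out.astype(np.float32), patch.mask.copy(), patch.case_id, patch.corner, patch.spacing)


def contrast_stretch(patch: Patch, rng: np.random.Generator, config: AugmentConfig) -> Patch:
    """Linear re-map of the intensity range to ``c`` times the original range,
    anchored at the sample minimum, with c ~ U(contrast_upper_range)."""
    c = float(rng.uniform(*config.contrast_upper_range))
    v = patch.volume.astype(float)
    lo = float(v.min())
    out = lo + (v - lo) * c
    return Patch(out.astype(np.float32), patch.mask.copy(), patch.case_id, patch.corner, patch.spacing)


def add_gaussian_noise(patch: Patch, rng: np.random.Generator, config: AugmentConfig) -> Patch:
    """Additive zero-mean Gaussian noise with SD equal to u ~ U(range) times
    the sample's intensity SD."""
    u = float(rng.uniform(*config.noise_sd_range))
    sd = u * float(patch.volume.std())
    if sd == 0:
        return patch.copy()
    out = patch.volume.astype(float) + rng.normal(0.0, sd, size=patch.volume.shape)
    return Patch(out.astype(np.float32), patch.mask.copy(), patch.case_id, patch.corner, patch.spacing)


# ---------------------------------------------------------------------------
# pipeline

_PIPELINE = (
    ("mirror", lambda p, rng, cfg: mirror_axial(p)),
    ("affine", random_affine),
    ("elastic", elastic_deform),
    ("gamma", gamma_correct),
    ("contrast", contrast_stretch),
    ("noise", add_gaussian_noise),
)


def augment(
    patch: Patch,
    rng: np.random.Generator,
    config: AugmentConfig,
    record: list | None = None,
) -> Patch:
    """Apply each transform independently with probability ``p_apply``,
    spatial before intensity.  ``record`` (if given) collects the names of
    the transforms that fired."""
    out = patch
    for name, fn in _PIPELINE:
        if rng.random() < config.p_apply:
            out = fn(out, rng, config)
            if record is not None:
                record.append(name)
    if out is patch:
        out = patch.copy()
    return out
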