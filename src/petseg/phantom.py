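"""Synthetic multi-center pelvic PET phantoms with ground-truth masks.

The generator emulates the statistical structure a fully automatic tumor
delineation method has to cope with in cervical cancer FDG-PET: a body of
moderate background uptake, a very hot bladder (urinary tracer pooling), and
a tumor of variable size, contrast, heterogeneity and lobulated shape lying
close to — possibly touching — the bladder.  Scanner heterogeneity across
centers is emulated through per-center voxel spacings and axial extents, and
limited spatial resolution through Gaussian partial-volume smoothing of the
ideal activity map before additive noise.

Ground truth is defined as the ideal (pre-smoothing, pre-noise) tumor
support, so it is unambiguous and independent of the noise realization.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .errors import AlignmentError, PlacementInfeasibleError
from .grids import BinaryMask3D, Volume3D, check_aligned

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# specs


@dataclass
class PhantomSpec:
    """Full parameterization of a single phantom case.

    Lengths are millimetres, uptakes arbitrary intensity units.  The grid is
    node-centred: voxel ``i`` sits at ``i * spacing``.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_spacing: tuple[float, float, float] = (4.0, 4.0, 2.0)
    body_semiaxes: tuple[float, float, float] = (85.0, 80.0, 42.0)
    background_uptake: float = 1.0
    bladder_center: tuple[float, float, float] | None = None
    bladder_radius: float = 18.0
    bladder_uptake: float = 12.0
    tumor_center: tuple[float, float, float] | None = None
    tumor_semiaxes: tuple[float, float, float] = (14.0, 12.0, 11.0)
    tumor_uptake: float = 6.0
    tumor_heterogeneity: float = 0.2
    tumor_lobulation: float = 0.0
    gap_mm: float = 0.0
    noise_sd: float = 0.1
    pv_fwhm_mm: float | None = 4.5
    seed: int = 0

    def validate(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        if min(self.background_uptake, self.bladder_uptake, self.tumor_uptake) < 0:
            raise ValueError("uptakes must be non-negative")
        if self.tumor_uptake <= self.background_uptake:
            raise ValueError("tumor uptake must exceed background uptake")
        if self.gap_mm < 0:
            raise ValueError("gap_mm must be >= 0")
        if not 0.0 <= self.tumor_heterogeneity <= 1.0:
            raise ValueError("tumor_heterogeneity must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def grid_center_mm(self) -> np.ndarray:
        return (np.asarray(self.grid_shape, dtype=float) - 1) * np.asarray(
            self.voxel_spacing
        ) / 2.0


@dataclass
class CenterProfile:
    """Acquisition profile of one (synthetic) institution."""

    name: str
    voxel_spacing: tuple[float, float, float]
    n_cases: int
    axial_slices_range: tuple[int, int] = (77, 192)
    noise_sd_range: tuple[float, float] = (0.05, 0.15)
    in_plane_voxels: int = 64
    tumor_volume_cm3_median: float = 22.0
    tumor_volume_sigma: float = 1.0
    tumor_volume_range_cm3: tuple[float, float] = (1.0, 150.0)

    def validate(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("spacing must be strictly positive")
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        lo, hi = self.axial_slices_range
        if lo > hi or lo < 1:
            raise ValueError("invalid axial_slices_range")


@dataclass
class PatientCase:
    """One case: PET volume, ground-truth tumor mask, bladder mask, center tag."""

    volume: Volume3D
    truth: BinaryMask3D
    bladder: BinaryMask3D
    center: str = ""
    case_id: str = ""
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry helpers


def _world_grids(shape, spacing):
    axes = [np.arange(n, dtype=float) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_q(grids, center, semiaxes):
    q = np.zeros_like(grids[0])
    for g, c, a in zip(grids, center, semiaxes):
        q += ((g - c) / a) ** 2
    return q


def _smooth_field(shape, spacing, corr_mm, rng):
    """Zero-mean smooth random field with unit standard deviation."""
    sigma_vox = [max(corr_mm / s, 1e-6) for s in spacing]
    f = gaussian_filter(rng.standard_normal(shape), sigma_vox)
    sd = f.std()
    return f / sd if sd > 0 else f


def surface_gap_mm(a: BinaryMask3D, b: BinaryMask3D) -> float:
    """Minimum voxel-centre distance (mm) from mask ``a`` voxels to mask ``b``.

    Returns ``inf`` if either mask is empty, 0 if they overlap.
    """
    av, bv = a.astype_bool(), b.astype_bool()
    if not av.any() or not bv.any():
        return float("inf")
    if (av & bv).any():
        return 0.0
    dist = distance_transform_edt(~bv, sampling=a.spacing)
    return float(dist[av].min())


# ---------------------------------------------------------------------------
# single-phantom generation


def generate_phantom(spec: PhantomSpec) -> PatientCase:
    """Render one phantom case from its spec.

    Deterministic for a fixed seed.  Raises
    :class:`PlacementInfeasibleError` when the tumor does not fit inside the
    body, collides with the bladder, or violates the requested surface gap.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = tuple(float(s) for s in spec.voxel_spacing)
    grids = _world_grids(shape, spacing)
    center = spec.grid_center_mm

    body = _ellipsoid_q(grids, center, spec.body_semiaxes) <= 1.0

    bl_center = (
        np.asarray(spec.bladder_center, dtype=float)
        if spec.bladder_center is not None
        else center + np.array([-0.45 * spec.body_semiaxes[0], 0.0, 0.0])
    )
    bladder = _ellipsoid_q(grids, bl_center, (spec.bladder_radius,) * 3) <= 1.0
    bladder &= body

    tu_center = (
        np.asarray(spec.tumor_center, dtype=float)
        if spec.tumor_center is not None
        else center + np.array([0.25 * spec.body_semiaxes[0], 0.0, 0.0])
    )
    q = _ellipsoid_q(grids, tu_center, spec.tumor_semiaxes)
    if spec.tumor_lobulation > 0:
        corr = float(np.mean(spec.tumor_semiaxes)) / 2.0
        q = q + spec.tumor_lobulation * _smooth_field(shape, spacing, corr, rng)
    tumor = q <= 1.0

    # feasibility -----------------------------------------------------------
    if not tumor.any():
        raise PlacementInfeasibleError("tumor support is empty on this grid")
    if (tumor & ~body).any():
        raise PlacementInfeasibleError("tumor extends outside the body")
    if (tumor & bladder).any():
        raise PlacementInfeasibleError("tumor overlaps the bladder")
    truth = BinaryMask3D(tumor.astype(np.uint8), spacing)
    bl_mask = BinaryMask3D(bladder.astype(np.uint8), spacing)
    if spec.gap_mm > 0 and bladder.any():
        gap = surface_gap_mm(truth, bl_mask)
        if gap < spec.gap_mm:
            raise PlacementInfeasibleError(
                f"tumor-bladder gap {gap:.2f} mm < requested {spec.gap_mm:.2f} mm"
            )

    # activity map ----------------------------------------------------------
    activity = np.zeros(shape, dtype=float)
    activity[body] = spec.background_uptake
    activity[bladder] = spec.bladder_uptake
    tumor_vals = np.full(shape, spec.tumor_uptake)
    if spec.tumor_heterogeneity > 0:
        corr = float(np.mean(spec.tumor_semiaxes)) / 2.0
        het = np.clip(_smooth_field(shape, spacing, corr, rng) / 2.0, -1.0, 1.0)
        tumor_vals = spec.tumor_uptake * (1.0 + spec.tumor_heterogeneity * het)
    activity[tumor] = tumor_vals[tumor]

    if spec.pv_fwhm_mm:
        sigma_vox = [spec.pv_fwhm_mm * _FWHM_TO_SIGMA / s for s in spacing]
        activity = gaussian_filter(activity, sigma_vox)
        activity[~body] = 0.0  # air carries no signal

    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd * spec.background_uptake, size=shape)
        activity[body] += noise[body]
    np.clip(activity, 0.0, None, out=activity)

    volume = Volume3D(activity, spacing)
    prov = {
        "spec": dataclasses.asdict(spec),
        "tumor_voxels": int(truth.voxel_count),
        "contrast": spec.tumor_uptake / max(spec.background_uptake, 1e-12),
        "seed": int(spec.seed),
    }
    return PatientCase(volume, truth, bl_mask, case_id=f"phantom_{spec.seed}", provenance=prov)


# ---------------------------------------------------------------------------
# cohorts


def table1_profiles() -> list[CenterProfile]:
    """The five-institution cohort layout the package emulates by default:
    per-center case counts, majority-scanner voxel spacings and the 77-192
    axial slice range of the clinical description."""
    return [
        CenterProfile("Brest", (4.073, 4.073, 2.027), 69),
        CenterProfile("Nantes", (4.073, 4.073, 2.027), 23),
        CenterProfile("Montreal", (5.469, 5.469, 3.27), 26),
        CenterProfile("Barcelona", (4.0, 4.0, 4.0), 24),
        CenterProfile("Liege", (4.0, 4.0, 4.0), 90),
    ]


def demo_profiles(cases_per_center=(7, 7, 6)) -> list[CenterProfile]:
    """Small three-center cohort for desk-scale experiments: the same
    qualitative heterogeneity (mixed spacings, variable axial extent, hot
    adjacent bladder) on grids a CPU can train against in minutes."""
    spacings = [(4.0, 4.0, 2.0), (4.0, 4.0, 4.0), (5.469, 5.469, 3.27)]
    names = ["Alpha", "Bravo", "Charlie"]
    slices = [(28, 40), (16, 22), (18, 26)]
    return [
        CenterProfile(
            name=n,
            voxel_spacing=sp,
            n_cases=c,
            axial_slices_range=sl,
            in_plane_voxels=32,
            tumor_volume_cm3_median=7.0,
            tumor_volume_sigma=0.5,
            tumor_volume_range_cm3=(3.0, 16.0),
        )
        for n, sp, c, sl in zip(names, spacings, cases_per_center, slices)
    ]


def _draw_case_spec(profile: CenterProfile, rng: np.random.Generator, seed: int) -> PhantomSpec:
    lo, hi = profile.axial_slices_range
    n_z = int(rng.integers(lo, hi + 1))
    shape = (profile.in_plane_voxels, profile.in_plane_voxels, n_z)
    spacing = tuple(float(s) for s in profile.voxel_spacing)
    ext = np.asarray(shape) * np.asarray(spacing)
    # anatomy is sized in absolute millimetres (patient size does not depend
    # on the scanner), clipped to the field of view of the acquisition
    body = (
        min(float(rng.uniform(52.0, 60.0)), 0.48 * ext[0]),
        min(float(rng.uniform(48.0, 56.0)), 0.45 * ext[1]),
        0.46 * ext[2],
    )
    center = (np.asarray(shape, dtype=float) - 1) * np.asarray(spacing) / 2.0

    r_b = float(rng.uniform(14.0, 19.0))
    bl_center = center + np.array(
        [
            -rng.uniform(0.30, 0.45) * body[0],
            rng.uniform(-0.1, 0.1) * body[1],
            rng.uniform(-0.15, 0.15) * body[2],
        ]
    )

    # tumor volume (cm^3) from a clamped log-normal, converted to semiaxes
    vol_cm3 = float(
        np.clip(
            rng.lognormal(np.log(profile.tumor_volume_cm3_median), profile.tumor_volume_sigma),
            *profile.tumor_volume_range_cm3,
        )
    )
    r_eq = (3.0 * vol_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    f = rng.uniform(0.75, 1.3, size=3)
    f /= np.prod(f) ** (1.0 / 3.0)
    semiaxes = tuple(float(r_eq * fi) for fi in f)

    gap = 0.0 if rng.random() < 0.25 else float(rng.uniform(0.5, 6.0))
    theta = rng.uniform(0.0, 2.0 * np.pi)
    u = np.array([np.cos(theta), np.sin(theta), rng.uniform(-0.3, 0.3)])
    u /= np.linalg.norm(u)
    r_u = 1.0 / np.sqrt(np.sum((u / np.asarray(semiaxes)) ** 2))
    lob = float(rng.uniform(0.0, 0.3))
    margin = 1.5 + 0.15 * r_eq * lob + float(np.max(spacing))
    tu_center = bl_center + u * (r_b + r_u + gap + margin)

    tumor_uptake = float(rng.uniform(3.0, 8.0))
    return PhantomSpec(
        grid_shape=shape,
        voxel_spacing=spacing,
        body_semiaxes=body,
        background_uptake=1.0,
        bladder_center=tuple(bl_center),
        bladder_radius=r_b,
        bladder_uptake=tumor_uptake * float(rng.uniform(1.5, 5.0)),
        tumor_center=tuple(tu_center),
        tumor_semiaxes=semiaxes,
        tumor_uptake=tumor_uptake,
        tumor_heterogeneity=float(rng.uniform(0.0, 0.4)),
        tumor_lobulation=lob,
        gap_mm=gap,
        noise_sd=float(rng.uniform(*profile.noise_sd_range)),
        seed=seed,
    )


def generate_cohort(
    profiles: list[CenterProfile], seed: int, *, max_attempts: int = 30
) -> list[PatientCase]:
    """Generate a multi-center cohort, one list of cases tagged by center.

    Case geometry (tumor size, contrast, bladder gap, noise level) is drawn
    per case from the distributions recorded in each profile; infeasible
    placements are redrawn with fresh sub-seeds.
    """
    if not profiles:
        raise ValueError("need at least one center profile")
    for p in profiles:
        p.validate()
    master = np.random.default_rng(seed)
    cases: list[PatientCase] = []
    for profile in profiles:
        for i in range(profile.n_cases):
            case = None
            for _ in range(max_attempts):
                sub = int(master.integers(0, 2**31 - 1))
                spec = _draw_case_spec(profile, np.random.default_rng(sub), sub)
                try:
                    case = generate_phantom(spec)
                except PlacementInfeasibleError:
                    continue
                break
            if case is None:
                raise PlacementInfeasibleError(
                    f"could not place a tumor for center {profile.name} "
                    f"after {max_attempts} attempts"
                )
            case.center = profile.name
            case.case_id = f"{profile.name}_{i:03d}"
            cases.append(case)
    return cases


# ---------------------------------------------------------------------------
# NIfTI / manifest I/O


def _affine(spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def _save_nifti(path: Path, values: np.ndarray, spacing, origin) -> None:
    img = nib.Nifti1Image(np.asarray(values), _affine(spacing, origin))
    nib.save(img, str(path))


def _load_nifti(path: Path):
    img = nib.load(str(path))
    spacing = tuple(float(s) for s in nib.affines.voxel_sizes(img.affine))
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return np.asarray(img.dataobj), spacing, origin


def write_case(case: PatientCase, out_dir) -> Path:
    """Write one case as NIfTI files (+ provenance JSON) under ``out_dir/case_id``."""
    d = Path(out_dir) / (case.case_id or "case")
    d.mkdir(parents=True, exist_ok=True)
    _save_nifti(d / "pet.nii.gz", case.volume.values.astype(np.float32),
                case.volume.spacing, case.volume.origin)
    _save_nifti(d / "truth.nii.gz", case.truth.values, case.truth.spacing, case.truth.origin)
    _save_nifti(d / "bladder.nii.gz", case.bladder.values, case.bladder.spacing,
                case.bladder.origin)
    meta = {"center": case.center, "case_id": case.case_id, "provenance": case.provenance}
    (d / "meta.json").write_text(json.dumps(meta))
    return d


def read_case(case_dir) -> PatientCase:
    """Read a case written by :func:`write_case`; raises
    :class:`AlignmentError` if image and masks disagree in shape/spacing."""
    d = Path(case_dir)
    vol_vals, vol_sp, vol_or = _load_nifti(d / "pet.nii.gz")
    volume = Volume3D(np.asarray(vol_vals, dtype=np.float32), vol_sp, vol_or)
    masks = {}
    for name in ("truth", "bladder"):
        vals, sp, orig = _load_nifti(d / f"{name}.nii.gz")
        mask = BinaryMask3D(np.asarray(vals).astype(np.uint8), sp, orig)
        check_aligned(volume, mask)
        masks[name] = mask
    meta = {}
    meta_path = d / "meta.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    return PatientCase(
        volume,
        masks["truth"],
        masks["bladder"],
        center=meta.get("center", ""),
        case_id=meta.get("case_id", d.name),
        provenance=meta.get("provenance", {}),
    )


def write_cohort(cases: list[PatientCase], out_dir) -> Path:
    """Write all cases plus a manifest CSV; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        d = write_case(case, out)
        rows.append(
            {
                "case_id": case.case_id,
                "center": case.center,
                "path": str(d.relative_to(out)),
                "tumor_voxels": case.provenance.get("tumor_voxels", case.truth.voxel_count),
                "contrast": case.provenance.get("contrast", float("nan")),
                "seed": case.provenance.get("seed", -1),
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path) -> list[PatientCase]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    cases = []
    for _, row in df.iterrows():
        case = read_case(manifest_path.parent / row["path"])
        case.center = row["center"]
        case.case_id = row["case_id"]
        cases.append(case)
    return cases
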