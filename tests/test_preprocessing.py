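"""Resampling, normalization, patch extraction, volume bookkeeping."""
import numpy as np
import pytest
from scipy import stats

from petseg.errors import DegenerateInputError
from petseg.grids import BinaryMask3D, Volume3D
from petseg.preprocessing import (
    extract_patch,
    mask_volume_cm3,
    resample_mask,
    resample_volume,
    znormalize,
)


class TestResampleVolume:
    def test_identity_resample(self, small_volume):
        out = resample_volume(small_volume, small_volume.spacing)
        assert out.shape == small_volume.shape
        assert np.abs(out.values - small_volume.values).max() < 1e-6

    def test_1d_ramp_linear_interpolation(self):
        # ramp [0, 2, 4] at 2 mm -> [0, 1, 2, 3, 4] at 1 mm (hand oracle)
        vals = np.array([0.0, 2.0, 4.0]).reshape(3, 1, 1)
        v = Volume3D(vals, (2.0, 2.0, 2.0))
        out = resample_volume(v, (1.0, 2.0, 2.0))
        assert out.shape == (6, 1, 1)
        assert np.allclose(out.values[:5, 0, 0], [0, 1, 2, 3, 4])

    def test_output_shape_rule(self):
        v = Volume3D(np.zeros((128, 128, 100)), (4.073, 4.073, 2.027))
        out = resample_volume(v, (4.0, 4.0, 2.0))
        expected = tuple(
            max(1, round(n * s / t))
            for n, s, t in zip((128, 128, 100), (4.073, 4.073, 2.027), (4.0, 4.0, 2.0))
        )
        assert out.shape == expected == (130, 130, 101)

    def test_agrees_with_sitk_reference(self, rng):
        sitk = pytest.importorskip("SimpleITK")
        from scipy.ndimage import gaussian_filter

        vals = gaussian_filter(rng.random((24, 20, 16)), 2.0)
        native, target = (4.073, 4.073, 2.027), (4.0, 4.0, 2.0)
        ours = resample_volume(Volume3D(vals, native), target)

        img = sitk.GetImageFromArray(np.ascontiguousarray(vals.T))  # sitk is z,y,x
        img.SetSpacing(native)
        res = sitk.ResampleImageFilter()
        res.SetOutputSpacing(target)
        res.SetSize([int(s) for s in ours.shape])
        res.SetInterpolator(sitk.sitkLinear)
        ref = sitk.GetArrayFromImage(res.Execute(img)).T
        # compare on the interior, where no out-of-support convention applies
        core = tuple(slice(1, s - 1) for s in ours.shape)
        denom = np.abs(ref[core]).max()
        assert np.abs(ours.values[core] - ref[core]).max() / denom < 1e-4

    def test_rejects_nonpositive_spacing(self, small_volume):
        with pytest.raises(ValueError):
            resample_volume(small_volume, (0.0, 4.0, 2.0))


class TestResampleMask:
    def test_identity(self, cube_mask):
        out = resample_mask(cube_mask, cube_mask.spacing)
        assert np.array_equal(out.values, cube_mask.values)

    def test_solid_cube_downsample(self):
        arr = np.zeros((20, 20, 20), dtype=np.uint8)
        arr[4:14, 4:14, 4:14] = 1  # solid 10^3 cube
        m = BinaryMask3D(arr, (1.0, 1.0, 1.0))
        out = resample_mask(m, (2.0, 2.0, 2.0))
        assert out.shape == (10, 10, 10)
        assert out.voxel_count == pytest.approx(5**3, rel=0.3)
        # the interior of the cube must remain solid
        assert out.values[3:6, 3:6, 3:6].all()

    def test_empty_mask_stays_empty(self):
        m = BinaryMask3D(np.zeros((8, 8, 8), dtype=np.uint8), (4.0, 4.0, 2.0))
        for target in [(2.0, 2.0, 2.0), (5.0, 5.0, 5.0)]:
            assert resample_mask(m, target).voxel_count == 0

    def test_output_is_binary(self, cube_mask):
        out = resample_mask(cube_mask, (3.0, 3.0, 3.0))
        assert set(np.unique(out.values)) <= {0, 1}


class TestZnormalize:
    def test_two_point_body(self):
        vals = np.zeros((4, 4, 4))
        vals[0, 0, 0], vals[1, 1, 1] = 1.0, 3.0
        out = znormalize(Volume3D(vals, (1, 1, 1)))
        assert out.values[0, 0, 0] == pytest.approx(-1.0)
        assert out.values[1, 1, 1] == pytest.approx(1.0)

    def test_constant_body_raises(self):
        vals = np.zeros((4, 4, 4))
        vals[1:3, 1:3, 1:3] = 2.0
        with pytest.raises(DegenerateInputError):
            znormalize(Volume3D(vals, (1, 1, 1)))

    def test_all_zero_raises(self):
        with pytest.raises(DegenerateInputError):
            znormalize(Volume3D(np.zeros((4, 4, 4)), (1, 1, 1)))

    def test_phantom_body_statistics(self, noisy_case):
        out = znormalize(noisy_case.volume)
        body = noisy_case.volume.values != 0
        assert abs(out.values[body].mean()) < 1e-6
        assert abs(out.values[body].std() - 1.0) < 1e-6

    def test_invariant_to_positive_rescaling(self, noisy_case):
        a = znormalize(noisy_case.volume)
        scaled = Volume3D(noisy_case.volume.values * 3.7, noisy_case.volume.spacing)
        b = znormalize(scaled)
        assert np.allclose(a.values, b.values, atol=1e-9)

    def test_zero_voxels_transformed_not_pinned(self, noisy_case):
        out = znormalize(noisy_case.volume)
        air = noisy_case.volume.values == 0
        assert air.any()
        # air maps to -mu/sd, a strictly negative constant
        assert np.unique(out.values[air]).size == 1
        assert out.values[air].max() < 0


class TestExtractPatch:
    def test_exact_size_volume_returns_whole(self, rng):
        vol = rng.random((8, 8, 8))
        mask = (vol > 0.5).astype(np.uint8)
        p = extract_patch(vol, mask, (8, 8, 8), rng)
        assert p.corner == (0, 0, 0)
        assert np.array_equal(p.volume, vol.astype(np.float32))
        assert np.array_equal(p.mask, mask)

    def test_small_volume_zero_padded(self, rng):
        vol = rng.random((4, 4, 4)) + 1.0
        mask = np.ones((4, 4, 4), dtype=np.uint8)
        p = extract_patch(vol, mask, (8, 8, 8), rng)
        assert p.volume.shape == (8, 8, 8)
        assert p.volume[4:].sum() == 0 and p.mask[4:].sum() == 0

    def test_reproducible_corner_sequence(self, rng):
        vol = np.zeros((12, 12, 12))
        mask = np.zeros_like(vol, dtype=np.uint8)
        c1 = [
            extract_patch(vol, mask, (8, 8, 8), np.random.default_rng(7)).corner
            for _ in range(1)
        ]
        c2 = [
            extract_patch(vol, mask, (8, 8, 8), np.random.default_rng(7)).corner
            for _ in range(1)
        ]
        assert c1 == c2

    def test_corner_distribution_uniform(self):
        # volume one voxel larger than the patch on each axis -> 8 corners
        vol = np.zeros((5, 5, 5))
        mask = np.zeros_like(vol, dtype=np.uint8)
        rng = np.random.default_rng(42)
        counts = {}
        n = 10_000
        for _ in range(n):
            c = extract_patch(vol, mask, (4, 4, 4), rng).corner
            counts[c] = counts.get(c, 0) + 1
        observed = np.array([counts.get((i, j, k), 0) for i in range(2) for j in range(2) for k in range(2)])
        chi2 = ((observed - n / 8) ** 2 / (n / 8)).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=7)


class TestMaskVolume:
    @pytest.mark.parametrize(
        "voxels,expected",
        [(200, 6.4), (1160, 37.12), (0, 0.0)],
    )
    def test_worked_conversions_on_common_grid(self, voxels, expected):
        arr = np.zeros((16, 16, 16), dtype=np.uint8)
        arr.ravel()[:voxels] = 1
        m = BinaryMask3D(arr.reshape(16, 16, 16), (4.0, 4.0, 2.0))
        assert mask_volume_cm3(m) == pytest.approx(expected)

    def test_additive_over_disjoint_masks(self, rng):
        a = (rng.random((10, 10, 10)) > 0.7).astype(np.uint8)
        b = ((rng.random((10, 10, 10)) > 0.7) & ~a.astype(bool)).astype(np.uint8)
        sp = (3.0, 3.0, 3.0)
        total = mask_volume_cm3(BinaryMask3D((a | b), sp))
        assert total == pytest.approx(
            mask_volume_cm3(BinaryMask3D(a, sp)) + mask_volume_cm3(BinaryMask3D(b, sp))
        )
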