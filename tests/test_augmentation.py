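"""Training-time transforms: joint image/mask behavior, parameter
distributions, firing rates."""
import numpy as np
import pytest
from scipy import stats

from petseg.augmentation import (
    AugmentConfig,
    add_gaussian_noise,
    augment,
    contrast_stretch,
    elastic_deform,
    gamma_correct,
    mirror_axial,
    random_affine,
    sample_affine_params,
)
from petseg.preprocessing import Patch


@pytest.fixture
def patch(rng):
    vol = rng.standard_normal((16, 16, 12)).astype(np.float32)
    mask = np.zeros((16, 16, 12), dtype=np.uint8)
    mask[5:11, 6:12, 4:9] = 1
    return Patch(vol, mask, "case", (0, 0, 0), (4.0, 4.0, 2.0))


@pytest.fixture
def config():
    return AugmentConfig()


class TestMirror:
    def test_involution(self, patch):
        twice = mirror_axial(mirror_axial(patch))
        assert np.array_equal(twice.volume, patch.volume)
        assert np.array_equal(twice.mask, patch.mask)

    def test_symmetric_input_unchanged(self, patch):
        sym = Patch(
            patch.volume + np.flip(patch.volume, axis=0),
            (patch.mask | np.flip(patch.mask, axis=0)).astype(np.uint8),
        )
        out = mirror_axial(sym)
        assert np.array_equal(out.volume, sym.volume)

    def test_mask_count_preserved(self, patch):
        assert mirror_axial(patch).mask.sum() == patch.mask.sum()


class TestAffine:
    def test_identity_parameters(self, patch, rng):
        cfg = AugmentConfig(rotation_deg_range=(0.0, 0.0), scale_range=(1.0, 1.0))
        out = random_affine(patch, rng, cfg)
        assert np.abs(out.volume - patch.volume).max() < 1e-5
        assert np.array_equal(out.mask, patch.mask)

    def test_scale_grows_mask_volume(self, rng):
        vol = np.zeros((36, 36, 36), dtype=np.float32)
        mask = np.zeros_like(vol, dtype=np.uint8)
        mask[10:26, 10:26, 10:26] = 1  # centered 16^3 cube
        p = Patch(vol, mask)
        cfg = AugmentConfig(rotation_deg_range=(0.0, 0.0), scale_range=(1.2, 1.2))
        out = random_affine(p, rng, cfg)
        ratio = out.mask.sum() / mask.sum()
        assert ratio == pytest.approx(1.2**3, rel=0.10)

    def test_angle_distribution_uniform(self, config):
        rng = np.random.default_rng(99)
        angles = []
        for _ in range(1000):
            a, _ = sample_affine_params(rng, config)
            angles.extend(abs(x) for x in a if x != 0)
        u = (np.asarray(angles) - 5.0) / 10.0
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_mask_stays_binary(self, patch, rng, config):
        out = random_affine(patch, rng, config)
        assert set(np.unique(out.mask)) <= {0, 1}


class TestElastic:
    def test_zero_displacement_is_identity(self, patch, rng):
        cfg = AugmentConfig(elastic_max_disp_mm=0.0)
        out = elastic_deform(patch, rng, cfg)
        assert np.array_equal(out.volume, patch.volume)

    def test_reproducible_with_seed(self, patch, config):
        a = elastic_deform(patch, np.random.default_rng(5), config)
        b = elastic_deform(patch, np.random.default_rng(5), config)
        assert np.array_equal(a.volume, b.volume)
        assert np.array_equal(a.mask, b.mask)

    def test_small_displacement_keeps_mask_connected(self, rng):
        from scipy.ndimage import label

        vol = np.zeros((24, 24, 24), dtype=np.float32)
        mask = np.zeros_like(vol, dtype=np.uint8)
        mask[8:16, 8:16, 8:16] = 1
        cfg = AugmentConfig(elastic_max_disp_mm=3.0)
        out = elastic_deform(Patch(vol, mask, spacing=(4, 4, 4)), rng, cfg)
        _, n = label(out.mask)
        assert n == 1


class TestIntensity:
    def test_gamma_one_is_identity(self, patch):
        cfg = AugmentConfig(gamma_range=(1.0, 1.0))
        out = gamma_correct(patch, np.random.default_rng(0), cfg)
        assert np.allclose(out.volume, patch.volume, atol=1e-6)

    def test_gamma_power_law_on_unit_range(self):
        # gamma=2 maps normalized 0.5 -> 0.25 before re-mapping
        vol = np.array([0.0, 0.5, 1.0], dtype=np.float32).reshape(3, 1, 1)
        p = Patch(vol, np.zeros((3, 1, 1), dtype=np.uint8))
        cfg = AugmentConfig(gamma_range=(2.0, 2.0))
        out = gamma_correct(p, np.random.default_rng(0), cfg)
        assert out.volume[1, 0, 0] == pytest.approx(0.25)

    def test_gamma_preserves_ordering(self, patch, rng, config):
        out = gamma_correct(patch, rng, config)
        flat_in = patch.volume.ravel()
        flat_out = out.volume.ravel()
        order = np.argsort(flat_in)
        assert np.all(np.diff(flat_out[order]) >= -1e-6)

    def test_contrast_stretch_range(self, patch):
        cfg = AugmentConfig(contrast_upper_range=(0.8, 0.8))
        out = contrast_stretch(patch, np.random.default_rng(0), cfg)
        old = patch.volume.max() - patch.volume.min()
        new = out.volume.max() - out.volume.min()
        assert new == pytest.approx(0.8 * old, abs=1e-5)
        assert out.volume.min() == pytest.approx(patch.volume.min(), abs=1e-6)

    def test_noise_sd_matches_target(self):
        rng = np.random.default_rng(3)
        vol = rng.standard_normal((32, 32, 32)).astype(np.float32)
        p = Patch(vol, np.zeros_like(vol, dtype=np.uint8))
        cfg = AugmentConfig(noise_sd_range=(0.15, 0.15))
        out = add_gaussian_noise(p, np.random.default_rng(4), cfg)
        achieved = (out.volume - vol).std()
        assert achieved == pytest.approx(0.15 * vol.std(), rel=0.05)

    def test_intensity_transforms_leave_mask_alone(self, patch, rng, config):
        for fn in (gamma_correct, contrast_stretch, add_gaussian_noise):
            out = fn(patch, rng, config)
            assert np.array_equal(out.mask, patch.mask)


class TestAugmentPipeline:
    def test_all_probabilities_zero_is_bitwise_identity(self, patch, rng):
        cfg = AugmentConfig(p_apply=0.0)
        out = augment(patch, rng, cfg)
        assert np.array_equal(out.volume, patch.volume)
        assert np.array_equal(out.mask, patch.mask)

    def test_all_on_with_identity_parameters(self, patch, rng):
        cfg = AugmentConfig(
            p_apply=1.0,
            rotation_deg_range=(0.0, 0.0),
            scale_range=(1.0, 1.0),
            gamma_range=(1.0, 1.0),
            contrast_upper_range=(1.0, 1.0),
            noise_sd_range=(0.0, 0.0),
            elastic_max_disp_mm=0.0,
        )
        out = augment(patch, rng, cfg)
        # mirroring still fires; undo it before comparing
        out = mirror_axial(out)
        assert np.abs(out.volume - patch.volume).max() < 1e-4
        assert np.array_equal(out.mask, patch.mask)

    def test_firing_rate_matches_probability(self, patch):
        rng = np.random.default_rng(17)
        cfg = AugmentConfig(p_apply=0.2)
        fired = []
        n = 2000
        for _ in range(n):
            rec = []
            augment(patch, rng, cfg, record=rec)
            fired.append(len(rec))
        # 6 transforms, each Bernoulli(0.2): mean fires per call = 1.2
        rate = np.sum(fired) / (6 * n)
        assert rate == pytest.approx(0.2, abs=0.02)

    def test_output_mask_binary_and_volume_finite(self, patch):
        rng = np.random.default_rng(23)
        cfg = AugmentConfig(p_apply=1.0)
        for _ in range(5):
            out = augment(patch, rng, cfg)
            assert np.isfinite(out.volume).all()
            assert set(np.unique(out.mask)) <= {0, 1}

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            AugmentConfig(scale_range=(1.2, 0.8))
        with pytest.raises(ValueError):
            AugmentConfig(p_apply=1.5)
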