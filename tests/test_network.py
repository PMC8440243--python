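"""Architecture contracts of the residual scSE U-Net and the StdU-Net
baseline: shapes, gate algebra, identity behavior, parameter counting,
end-to-end differentiability, checkpointing."""
import dataclasses

import numpy as np
import pytest

from petseg.errors import CheckpointError, ConfigError, ShapeError
from petseg.nn.modules import SCSE, DownBlock, ResidualBlock
from petseg.nn.network import (
    ModelConfig,
    ResScSEUNet,
    StdUNet,
    build_model,
    load_checkpoint,
    save_checkpoint,
    summary,
)
from petseg.nn.tensor import Tensor
from petseg.objectives import soft_dice_loss_tensor

SMALL = ModelConfig(channels=(4, 8), seed=0)


def randx(rng, shape):
    return Tensor(rng.standard_normal(shape).astype(np.float32))


class TestSCSE:
    def test_shape_preserved(self, rng):
        s = SCSE(4, 2)
        x = randx(rng, (2, 4, 6, 6, 4))
        assert s(x).shape == x.shape

    def test_gates_forced_to_one_doubles_input_in_add_mode(self, rng):
        s = SCSE(4, 2, "add")
        for p in (s.fc1.weight, s.fc2.weight, s.spatial.weight):
            p.data[:] = 0.0
        s.fc2.bias.data[:] = 500.0  # sigmoid saturates to exactly 1 in float32
        s.spatial.bias.data[:] = 500.0
        x = randx(rng, (1, 4, 4, 4, 4))
        assert np.allclose(s(x).data, 2.0 * x.data)

    def test_half_gates_give_identity_in_add_mode(self, rng):
        s = SCSE(4, 2, "add")
        for p in (s.fc1.weight, s.fc2.weight, s.spatial.weight):
            p.data[:] = 0.0
        s.fc2.bias.data[:] = 0.0
        s.spatial.bias.data[:] = 0.0
        x = randx(rng, (1, 4, 4, 4, 4))
        assert np.allclose(s(x).data, x.data, atol=1e-6)

    def test_max_mode_selects_larger_branch(self, rng):
        s = SCSE(4, 2, "max")
        x = Tensor(np.abs(rng.standard_normal((1, 4, 4, 4, 4))).astype(np.float32))
        out = s(x)
        assert out.shape == x.shape

    def test_indivisible_reduction_rejected(self):
        with pytest.raises(ConfigError):
            SCSE(6, 4)


class TestResidualBlock:
    def test_zero_convs_give_pure_identity(self, rng):
        rb = ResidualBlock(6, 6, zero_init=True)
        x = randx(rng, (1, 6, 8, 8, 8))
        assert np.allclose(rb(x).data, x.data)

    def test_channel_change_uses_projection(self, rng):
        rb = ResidualBlock(4, 8)
        x = randx(rng, (1, 4, 6, 6, 6))
        assert rb(x).shape == (1, 8, 6, 6, 6)

    def test_parameter_count_matches_layerwise_arithmetic(self):
        c = 24
        rb = ResidualBlock(c, c, kernel=3, reduction=2)
        conv = c * c * 27 + c  # weight + bias
        norm = 2 * c  # gamma + beta
        scse = (c * (c // 2) + c // 2) + ((c // 2) * c + c) + (c * 1 + 1)
        expected = 2 * conv + 2 * norm + scse
        assert rb.n_parameters() == expected


class TestDownUpSampling:
    def test_downsample_halves_dims(self, rng):
        d = DownBlock(4, 8)
        x = randx(rng, (1, 4, 32, 32, 16))
        assert d(x).shape == (1, 8, 16, 16, 8)

    def test_stem_kernel7_halves_128_input(self, rng):
        d = DownBlock(1, 4, kernel=7)
        x = randx(rng, (1, 1, 128, 128, 64))
        assert d(x).shape == (1, 4, 64, 64, 32)


class TestForward:
    @pytest.mark.parametrize("shape", [(16, 16, 16), (32, 16, 16), (64, 32, 16)])
    def test_output_matches_input_shape_and_range(self, rng, shape):
        model = ResScSEUNet(SMALL)
        x = randx(rng, (1, 1, *shape))
        out = model(x)
        assert out.shape == (1, 1, *shape)
        assert out.data.min() > 0.0 and out.data.max() < 1.0

    def test_indivisible_dims_raise_with_padding_hint(self, rng):
        model = ResScSEUNet(SMALL)
        with pytest.raises(ShapeError, match="pad"):
            model(randx(rng, (1, 1, 18, 16, 16)))

    def test_std_unet_same_contract(self, rng):
        model = StdUNet(SMALL)
        x = randx(rng, (1, 1, 16, 16, 8))
        out = model(x)
        assert out.shape == x.shape
        assert 0.0 < out.data.min() and out.data.max() < 1.0

    def test_total_parameter_count_matches_independent_sum(self):
        cfg = ModelConfig(channels=(4, 8), seed=1)
        model = ResScSEUNet(cfg)

        def conv_p(ci, co, k, bias=True):
            return ci * co * k**3 + (co if bias else 0)

        def scse_p(c, r=2):
            return (c * (c // r) + c // r) + ((c // r) * c + c) + (c + 1)

        def norm_p(c):
            return 2 * c

        def down_p(ci, co, k):
            return conv_p(ci, co, k) + norm_p(co) + scse_p(co)

        def res_p(ci, co):
            p = conv_p(ci, co, 3) + conv_p(co, co, 3) + norm_p(ci) + norm_p(co) + scse_p(co)
            if ci != co:
                p += conv_p(ci, co, 1, bias=False)
            return p

        def up_p(ci, co):
            return conv_p(ci, co, 3) + norm_p(co) + scse_p(co)

        expected = (
            down_p(1, 4, 7) + res_p(4, 4)      # level 0 encoder
            + down_p(4, 8, 3) + res_p(8, 8)    # level 1 encoder
            + up_p(8, 4) + res_p(8, 4)         # decoder level 1 (concat 4+4)
            + up_p(4, 4)                       # final upsample to full res
            + conv_p(4, 1, 1)                  # head
        )
        assert model.n_parameters() == expected

    def test_end_to_end_gradients_match_finite_differences(self, rng):
        model = build_model(ModelConfig(channels=(4, 8), seed=3)).to_dtype(np.float64)
        x = Tensor(rng.standard_normal((1, 1, 8, 8, 8)))
        target = (rng.random((1, 1, 8, 8, 8)) > 0.7).astype(float)

        def loss():
            return soft_dice_loss_tensor(model(x), target)

        L = loss()
        model.zero_grad()
        L.backward()
        params = model.parameters()
        for pi in rng.choice(len(params), size=6, replace=False):
            p = params[pi]
            flat, g = p.data.ravel(), p.grad.ravel()
            idx = rng.integers(flat.size)
            eps, orig = 1e-6, flat[idx]
            flat[idx] = orig + eps
            f1 = loss().item()
            flat[idx] = orig - eps
            f2 = loss().item()
            flat[idx] = orig
            num = (f1 - f2) / (2 * eps)
            assert abs(num - g[idx]) <= 1e-2 * max(1e-6, abs(num)) + 1e-7

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(channels=(8,))
        with pytest.raises(ConfigError):
            ModelConfig(channels=(8, 4))  # decreasing
        with pytest.raises(ConfigError):
            ModelConfig(channels=(6, 9), scse_reduction=2)  # indivisible


class TestCheckpoint:
    def test_round_trip(self, rng, tmp_path):
        model = build_model(SMALL)
        x = randx(rng, (1, 1, 16, 16, 16))
        before = model(x).data
        save_checkpoint(model, tmp_path / "m.npz")
        back = load_checkpoint(tmp_path / "m.npz")
        assert np.allclose(back(x).data, before)

    def test_missing_sidecar_raises(self, tmp_path):
        model = build_model(SMALL)
        save_checkpoint(model, tmp_path / "m.npz")
        (tmp_path / "m.json").unlink()
        with pytest.raises(CheckpointError):
            load_checkpoint(tmp_path / "m.npz")

    def test_summary_lists_total(self):
        model = build_model(SMALL)
        text = summary(model)
        assert str(model.n_parameters()) in text
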