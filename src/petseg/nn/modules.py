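"""Layer library: parameter containers and the building blocks of the
segmentation networks (convolutions, instance norm, scSE gating, residual
blocks, learnable down/upsampling blocks)."""
from __future__ import annotations

import numpy as np

from ..errors import ConfigError
from . import conv as F
from .tensor import Tensor, concat, maximum

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Minimal container with recursive parameter discovery (torch-style)."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield f"{prefix}{name}", p
        for name, m in self._modules.items():
            yield from m.named_parameters(f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ConfigError(f"state dict does not match model parameters: {missing}")
        for name, p in own.items():
            arr = np.asarray(state[name])
            if arr.shape != p.data.shape:
                raise ConfigError(
                    f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}"
                )
            p.data = arr.astype(p.data.dtype, copy=True)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def to_dtype(self, dtype) -> "Module":
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Conv3d(Module):
    def __init__(self, cin, cout, kernel=3, stride=1, padding=None, bias=True,
                 rng=None, zero_init=False):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = cin * kernel**3
        w = np.zeros((cout, cin, kernel, kernel, kernel), dtype=DTYPE) if zero_init \
            else _kaiming(rng, (cout, cin, kernel, kernel, kernel), fan_in)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(cout, dtype=DTYPE)) if bias else None

    def forward(self, x):
        return F.conv3d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose3d(Module):
    def __init__(self, cin, cout, kernel=3, stride=2, padding=1, output_padding=1,
                 bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding, self.output_padding = stride, padding, output_padding
        fan_in = cin * kernel**3
        self.weight = Parameter(
            _kaiming(rng, (cin, cout, kernel, kernel, kernel), fan_in)
        )
        self.bias = Parameter(np.zeros(cout, dtype=DTYPE)) if bias else None

    def forward(self, x):
        return F.conv_transpose3d(
            x, self.weight, self.bias, self.stride, self.padding, self.output_padding
        )


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalization over the spatial axes, with
    learnable affine parameters (the batch-size-2 regime of patch training
    makes batch statistics unreliable)."""

    def __init__(self, channels, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones((1, channels, 1, 1, 1), dtype=DTYPE))
        self.beta = Parameter(np.zeros((1, channels, 1, 1, 1), dtype=DTYPE))

    def forward(self, x):
        axes = (2, 3, 4)
        mu = x.mean(axis=axes, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=axes, keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        return xn * self.gamma + self.beta


class Linear(Module):
    def __init__(self, cin, cout, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_kaiming(rng, (cin, cout), cin))
        self.bias = Parameter(np.zeros(cout, dtype=DTYPE))

    def forward(self, x):
        return x @ self.weight + self.bias


class SCSE(Module):
    """Concurrent spatial and channel squeeze-and-excitation.

    Channel branch: global average pool -> bottleneck (C/r) -> sigmoid gate
    per channel.  Spatial branch: 1x1x1 convolution -> sigmoid gate per
    voxel.  The two recalibrated maps are combined by addition (default) or
    elementwise maximum.
    """

    def __init__(self, channels, reduction=2, mode="add", rng=None):
        super().__init__()
        if channels % reduction:
            raise ConfigError(
                f"scSE reduction {reduction} must divide channel count {channels}"
            )
        if mode not in ("add", "max"):
            raise ConfigError(f"unknown scSE combine mode {mode!r}")
        rng = rng or np.random.default_rng(0)
        self.mode = mode
        self.fc1 = Linear(channels, channels // reduction, rng)
        self.fc2 = Linear(channels // reduction, channels, rng)
        self.spatial = Conv3d(channels, 1, kernel=1, bias=True, rng=rng)

    def forward(self, x):
        b, c = x.shape[:2]
        z = x.mean(axis=(2, 3, 4))  # (B, C)
        gate_c = self.fc2(self.fc1(z).relu()).sigmoid().reshape((b, c, 1, 1, 1))
        cse = x * gate_c
        gate_s = self.spatial(x).sigmoid()  # (B, 1, X, Y, Z)
        sse = x * gate_s
        return cse + sse if self.mode == "add" else maximum(cse, sse)


class ResidualBlock(Module):
    """Full pre-activation residual unit with scSE on the residual path:
    two (norm -> ReLU -> 3^3 conv) stages, then scSE, plus the identity skip
    (1x1x1 projection when the channel count changes)."""

    def __init__(self, cin, cout=None, kernel=3, reduction=2, scse_mode="add",
                 eps=1e-5, rng=None, zero_init=False):
        super().__init__()
        cout = cin if cout is None else cout
        rng = rng or np.random.default_rng(0)
        self.norm1 = InstanceNorm3d(cin, eps)
        self.conv1 = Conv3d(cin, cout, kernel, rng=rng, zero_init=zero_init)
        self.norm2 = InstanceNorm3d(cout, eps)
        self.conv2 = Conv3d(cout, cout, kernel, rng=rng, zero_init=zero_init)
        self.scse = SCSE(cout, reduction, scse_mode, rng)
        self.proj = (
            Conv3d(cin, cout, kernel=1, bias=False, rng=rng) if cin != cout else None
        )

    def forward(self, x):
        h = self.conv1(self.norm1(x).relu())
        h = self.conv2(self.norm2(h).relu())
        h = self.scse(h)
        skip = self.proj(x) if self.proj is not None else x
        return h + skip


class DownBlock(Module):
    """Learnable downsampling: strided conv -> instance norm -> ReLU -> scSE.
    Halves each spatial dimension."""

    def __init__(self, cin, cout, kernel=3, reduction=2, scse_mode="add",
                 eps=1e-5, rng=None):
        super().__init__()
        self.conv = Conv3d(cin, cout, kernel, stride=2, padding=kernel // 2, rng=rng)
        self.norm = InstanceNorm3d(cout, eps)
        self.scse = SCSE(cout, reduction, scse_mode, rng)

    def forward(self, x):
        return self.scse(self.norm(self.conv(x)).relu())


class UpBlock(Module):
    """Learnable upsampling: 3^3 transposed conv (stride 2) -> instance norm
    -> ReLU -> scSE.  Doubles each spatial dimension."""

    def __init__(self, cin, cout, reduction=2, scse_mode="add", eps=1e-5, rng=None):
        super().__init__()
        self.conv = ConvTranspose3d(cin, cout, rng=rng)
        self.norm = InstanceNorm3d(cout, eps)
        self.scse = SCSE(cout, reduction, scse_mode, rng)

    def forward(self, x):
        return self.scse(self.norm(self.conv(x)).relu())


class PlainBlock(Module):
    """Conventional U-Net block: two (3^3 conv -> instance norm -> ReLU)."""

    def __init__(self, cin, cout, kernel=3, eps=1e-5, rng=None):
        super().__init__()
        self.conv1 = Conv3d(cin, cout, kernel, rng=rng)
        self.norm1 = InstanceNorm3d(cout, eps)
        self.conv2 = Conv3d(cout, cout, kernel, rng=rng)
        self.norm2 = InstanceNorm3d(cout, eps)

    def forward(self, x):
        h = self.norm1(self.conv1(x)).relu()
        return self.norm2(self.conv2(h)).relu()


__all__ = [
    "Module",
    "Parameter",
    "Conv3d",
    "ConvTranspose3d",
    "InstanceNorm3d",
    "Linear",
    "SCSE",
    "ResidualBlock",
    "DownBlock",
    "UpBlock",
    "PlainBlock",
    "concat",
]
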