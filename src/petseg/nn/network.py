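"""The segmentation networks.

``ResScSEUNet`` is the proposed model: a 3-D encoder-decoder where every
downsampling is a learnable strided-convolution block (7^3 kernel right
after the input, 3^3 elsewhere), every level carries a full pre-activation
residual block with concurrent spatial/channel squeeze-and-excitation, the
decoder upsamples with 3^3 transposed convolutions and concatenates encoder
skips, and the head is a 1x1x1 convolution with a sigmoid.

``StdUNet`` is the conventional baseline built from the same configuration:
plain conv blocks, max pooling, trilinear upsampling.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..errors import CheckpointError, ConfigError, ShapeError
from .conv import maxpool2, upsample2_trilinear
from .modules import (
    Conv3d,
    DownBlock,
    Module,
    PlainBlock,
    ResidualBlock,
    UpBlock,
    concat,
)
from .tensor import Tensor


@dataclass
class ModelConfig:
    """Architecture knobs with their full-scale defaults."""

    in_channels: int = 1
    channels: tuple[int, ...] = (24, 48, 96, 192)
    scse_reduction: int = 2
    stem_kernel: int = 7
    block_kernel: int = 3
    norm_eps: float = 1e-5
    scse_mode: str = "add"  # or "max"
    arch: str = "res-scse"  # or "std"
    seed: int = 0

    def __post_init__(self):
        self.channels = tuple(int(c) for c in self.channels)
        if len(self.channels) < 2:
            raise ConfigError("need at least 2 resolution levels")
        if any(c <= 0 for c in self.channels):
            raise ConfigError("channel counts must be positive")
        if any(b < a for a, b in zip(self.channels, self.channels[1:])):
            raise ConfigError("channel counts must be non-decreasing")
        if any(c % self.scse_reduction for c in self.channels):
            raise ConfigError("scse_reduction must divide every channel count")

    @property
    def levels(self) -> int:
        return len(self.channels)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        d["channels"] = tuple(d["channels"])
        return cls(**d)


def _check_divisible(shape, factor: int) -> None:
    if any(s % factor for s in shape):
        need = tuple((-s) % factor for s in shape)
        raise ShapeError(
            f"spatial dims {tuple(shape)} must be divisible by {factor}; "
            f"pad by {need} voxels"
        )


class ResScSEUNet(Module):
    """Residual scSE U-Net with learnable down/upsampling."""

    def __init__(self, config: ModelConfig | None = None):
        super().__init__()
        cfg = config or ModelConfig()
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        ch = cfg.channels
        kw = dict(reduction=cfg.scse_reduction, scse_mode=cfg.scse_mode, eps=cfg.norm_eps)

        prev = cfg.in_channels
        for i, c in enumerate(ch):
            kernel = cfg.stem_kernel if i == 0 else cfg.block_kernel
            setattr(self, f"down{i}", DownBlock(prev, c, kernel, rng=rng, **kw))
            setattr(
                self,
                f"enc{i}",
                ResidualBlock(c, c, cfg.block_kernel, rng=rng, **kw),
            )
            prev = c
        for i in range(cfg.levels - 1, 0, -1):
            setattr(self, f"up{i}", UpBlock(ch[i], ch[i - 1], rng=rng, **kw))
            setattr(
                self,
                f"dec{i}",
                ResidualBlock(2 * ch[i - 1], ch[i - 1], cfg.block_kernel, rng=rng, **kw),
            )
        self.up0 = UpBlock(ch[0], ch[0], rng=rng, **kw)
        self.head = Conv3d(ch[0], 1, kernel=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.config
        _check_divisible(x.shape[2:], 2**cfg.levels)
        skips = []
        h = x
        for i in range(cfg.levels):
            h = getattr(self, f"down{i}")(h)
            h = getattr(self, f"enc{i}")(h)
            skips.append(h)
        for i in range(cfg.levels - 1, 0, -1):
            h = getattr(self, f"up{i}")(h)
            h = concat([h, skips[i - 1]], axis=1)
            h = getattr(self, f"dec{i}")(h)
        h = self.up0(h)
        return self.head(h).sigmoid()


class StdUNet(Module):
    """Standard U-Net baseline: plain conv blocks, max pooling, trilinear
    upsampling, same channel schedule and head as the proposed model."""

    def __init__(self, config: ModelConfig | None = None):
        super().__init__()
        cfg = config or ModelConfig()
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        ch = cfg.channels
        prev = cfg.in_channels
        for i, c in enumerate(ch):
            setattr(self, f"enc{i}", PlainBlock(prev, c, cfg.block_kernel, cfg.norm_eps, rng))
            prev = c
        for i in range(cfg.levels - 1, 0, -1):
            setattr(
                self,
                f"dec{i}",
                PlainBlock(ch[i] + ch[i - 1], ch[i - 1], cfg.block_kernel, cfg.norm_eps, rng),
            )
        self.head = Conv3d(ch[0], 1, kernel=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.config
        _check_divisible(x.shape[2:], 2 ** (cfg.levels - 1))
        skips = []
        h = x
        for i in range(cfg.levels):
            if i > 0:
                h = maxpool2(h)
            h = getattr(self, f"enc{i}")(h)
            skips.append(h)
        for i in range(cfg.levels - 1, 0, -1):
            h = upsample2_trilinear(h)
            h = concat([h, skips[i - 1]], axis=1)
            h = getattr(self, f"dec{i}")(h)
        return self.head(h).sigmoid()


def build_model(config: ModelConfig) -> Module:
    if config.arch == "res-scse":
        return ResScSEUNet(config)
    if config.arch == "std":
        return StdUNet(config)
    raise ConfigError(f"unknown architecture {config.arch!r}")


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: Module, path) -> None:
    """Parameters as ``.npz`` plus a JSON sidecar carrying the config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **{k.replace(".", "/"): v for k, v in model.state_dict().items()})
    path.with_suffix(".json").write_text(model.config.to_json())


def load_checkpoint(path) -> Module:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise CheckpointError(f"missing config sidecar {sidecar}")
    model = build_model(ModelConfig.from_json(sidecar.read_text()))
    with np.load(path) as data:
        state = {k.replace("/", "."): data[k] for k in data.files}
    try:
        model.load_state_dict(state)
    except ConfigError as exc:
        raise CheckpointError(str(exc)) from exc
    return model


def summary(model: Module) -> str:
    """Layer table with per-parameter counts and the total."""
    lines = [f"{'parameter':60s} {'shape':>20s} {'count':>10s}"]
    total = 0
    for name, p in model.named_parameters():
        total += p.data.size
        lines.append(f"{name:60s} {str(p.data.shape):>20s} {p.data.size:>10d}")
    lines.append(f"{'total':60s} {'':>20s} {total:>10d}")
    return "\n".join(lines)
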