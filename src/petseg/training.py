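"""Patch-based training engine.

One epoch draws a random patch per training case (foreground-biased if
configured), augments it, and performs Adam updates on the Soft Dice loss at
the cosine-annealed learning rate of that epoch.  The schedule restarts
every ``cycle_epochs`` (warm restarts; Adam moment estimates are kept across
restarts).  A 20% validation split, stratified by center, is monitored each
epoch and the best-validation-DSC parameters are retained.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augmentation import AugmentConfig, augment
from .nn.modules import Module
from .nn.optim import Adam
from .nn.tensor import Tensor
from .objectives import soft_dice_loss, soft_dice_loss_tensor
from .phantom import PatientCase
from .preprocessing import extract_patch


@dataclass
class TrainConfig:
    """Optimization knobs, defaulting to the full-scale training recipe."""

    epochs: int = 400
    batch_size: int = 2
    patch_size: tuple[int, int, int] = (128, 128, 64)
    beta1: float = 0.9
    beta2: float = 0.99
    lr_max: float = 1e-4
    lr_min: float = 1e-6
    cycle_epochs: int = 25
    warm_restarts: bool = True
    steps_per_epoch: int | None = None  # None -> one patch per training case
    validation_fraction: float = 0.2
    fg_bias: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.lr_min < self.lr_max:
            raise ValueError("lr_min must be < lr_max")
        if self.cycle_epochs < 1:
            raise ValueError("cycle_epochs must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainConfig":
        """Scaled-down profile for CPU desk experiments: small patches, a
        single cosine decay over few epochs, a larger learning rate suited to
        the narrow networks, and foreground-biased patch sampling so the
        sparse tumor class is seen every epoch."""
        kw = dict(
            epochs=40,
            batch_size=2,
            patch_size=(32, 32, 16),
            lr_max=5e-3,
            lr_min=1e-4,
            cycle_epochs=40,
            fg_bias=0.6,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class TrainingHistory:
    """Per-epoch curves recorded during training."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_dsc: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.train_loss)),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "val_dsc": self.val_dsc,
                "lr": self.lr,
            }
        )


def cosine_lr(epoch: float, cfg: TrainConfig) -> float:
    """Cosine-annealed learning rate at a (possibly fractional) epoch.

    ``lr_min + (lr_max - lr_min)/2 * (1 + cos(pi * t / cycle))`` with
    ``t = epoch mod cycle_epochs`` (warm restarts every cycle) or, with
    restarts disabled, a single decay clamped at ``lr_min``.
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    cycle = cfg.cycle_epochs
    if cfg.warm_restarts:
        t = epoch % cycle
    else:
        t = min(epoch, cycle)
    return cfg.lr_min + 0.5 * (cfg.lr_max - cfg.lr_min) * (1.0 + np.cos(np.pi * t / cycle))


def split_train_val(
    cases: list[PatientCase], fraction: float = 0.2, seed: int = 0
) -> tuple[list[PatientCase], list[PatientCase]]:
    """Reproducible train/validation split, stratified by center.

    Within each center the cases are shuffled and ``round(fraction * n)``
    (at least 1 when the center has >= 2 cases) go to validation.  The split
    is disjoint and exhaustive.
    """
    if len(cases) < 2:
        raise ValueError("need at least 2 cases to split")
    rng = np.random.default_rng(seed)
    by_center: dict[str, list[PatientCase]] = {}
    for c in cases:
        by_center.setdefault(c.center, []).append(c)
    train: list[PatientCase] = []
    val: list[PatientCase] = []
    for center in sorted(by_center):
        group = sorted(by_center[center], key=lambda c: c.case_id)
        order = rng.permutation(len(group))
        n_val = int(round(fraction * len(group)))
        if len(group) >= 2:
            n_val = min(max(n_val, 1), len(group) - 1)
        else:
            n_val = 0
        val.extend(group[i] for i in order[:n_val])
        train.extend(group[i] for i in order[n_val:])
    if not val and len(train) >= 2:
        val.append(train.pop())
    return train, val


def _batch_forward(model: Module, vols: np.ndarray, masks: np.ndarray):
    x = Tensor(vols[:, None].astype(np.float32))
    pred = model(x)
    loss = soft_dice_loss_tensor(pred, masks)
    return pred, loss


def train(
    model: Module,
    train_cases: list[PatientCase],
    val_cases: list[PatientCase],
    cfg: TrainConfig,
    aug_cfg: AugmentConfig | None = None,
) -> tuple[Module, TrainingHistory]:
    """Run the optimization loop; returns the model (loaded with the best
    validation-DSC parameters when validation cases exist) and the history.

    Cases must already be on the common grid and Z-score normalized.  Fully
    reproducible for a fixed config seed.  Aborts on a non-finite loss.
    """
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), cfg.beta1, cfg.beta2)
    history = TrainingHistory()
    best_dsc, best_state = -1.0, None
    train_ids = {c.case_id for c in train_cases}
    val_ids = {c.case_id for c in val_cases}
    if train_ids & val_ids:
        raise ValueError(f"validation cases leak into training: {train_ids & val_ids}")

    n_steps = cfg.steps_per_epoch or max(1, int(np.ceil(len(train_cases) / cfg.batch_size)))
    for epoch in range(cfg.epochs):
        lr = cosine_lr(epoch, cfg)
        order = rng.permutation(len(train_cases))
        losses = []
        pos = 0
        for _ in range(n_steps):
            batch_vols, batch_masks = [], []
            for _ in range(cfg.batch_size):
                case = train_cases[order[pos % len(order)]]
                pos += 1
                patch = extract_patch(
                    case.volume.values,
                    case.truth.values,
                    cfg.patch_size,
                    rng,
                    case_id=case.case_id,
                    spacing=case.volume.spacing,
                    fg_bias=cfg.fg_bias,
                )
                if aug_cfg is not None:
                    patch = augment(patch, rng, aug_cfg)
                batch_vols.append(patch.volume)
                batch_masks.append(patch.mask)
            _, loss = _batch_forward(model, np.stack(batch_vols), np.stack(batch_masks))
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (lr={lr:.2e}); aborting"
                )
            model.zero_grad()
            loss.backward()
            opt.step(lr)
            losses.append(loss.item())

        val_loss, val_dsc = _validate(model, val_cases, cfg, epoch)
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(val_loss)
        history.val_dsc.append(val_dsc)
        history.lr.append(lr)
        if val_cases and val_dsc >= best_dsc:
            best_dsc = val_dsc
            best_state = model.state_dict()

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def _validate(model: Module, val_cases, cfg: TrainConfig, epoch: int):
    """One foreground-centred patch per validation case: Soft Dice loss and
    hard DSC at threshold 0.5."""
    from zlib import crc32

    from .nn.tensor import no_grad

    if not val_cases:
        return float("nan"), float("nan")
    losses, dscs = [], []
    for case in val_cases:
        vrng = np.random.default_rng(crc32(f"{case.case_id}:{epoch}".encode()) % 2**31)
        patch = extract_patch(
            case.volume.values,
            case.truth.values,
            cfg.patch_size,
            vrng,
            spacing=case.volume.spacing,
            fg_bias=1.0,
        )
        with no_grad():
            pred = model(Tensor(patch.volume[None, None].astype(np.float32)))
        p = pred.data[0, 0]
        losses.append(soft_dice_loss(p, patch.mask.astype(float)))
        hard = (p >= 0.5).astype(np.uint8)
        inter = int((hard & patch.mask).sum())
        denom = int(hard.sum()) + int(patch.mask.sum())
        dscs.append(1.0 if denom == 0 else 2.0 * inter / denom)
    return float(np.mean(losses)), float(np.mean(dscs))
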