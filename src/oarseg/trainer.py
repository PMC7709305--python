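"""Training harness: deterministic model building, validation splitting,
epoch loop with Adam and early stopping, and inference.

Early stopping follows the rule: training stops once the improvement of the
monitored validation quantity over the best value seen so far has been below
``min_improvement`` (default 0.001) for ``patience`` (default 4) consecutive
epochs; the parameters from the best epoch are restored.  The monitored
quantity is the negated validation loss of the configured cost function, so
"higher is better" regardless of the loss chosen.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import List, Sequence, Tuple

import numpy as np

from .core import ROISpec, SegCase, ValidationError
from .losses import LossSpec, loss_value, soft_dice_grad
from .nn import Adam, NetSpec, UNet3D
from .preprocess import preprocess_case

__all__ = ["ModelConfig", "TrainConfig", "build_model", "split_validation",
           "EarlyStopper", "early_stop_epoch", "train", "predict",
           "save_model", "load_model"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture configuration; ``input_shape`` is the ROI crop shape and
    must be divisible by 2**depth along every axis."""

    input_shape: Tuple[int, int, int]
    depth: int = 2
    base_filters: int = 8
    dropout: float = 0.2
    # expected foreground fraction of the ROI; the output layer's bias is
    # initialised to its logit so initial predictions match the class balance
    foreground_prior: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.foreground_prior < 1.0:
            raise ValidationError("foreground_prior must be in (0, 1)")
        if any(s % (2 ** self.depth) for s in self.input_shape):
            raise ValidationError(
                f"input shape {self.input_shape} must be divisible by 2^depth "
                f"= {2 ** self.depth} per axis")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings.  ``val_fraction=0`` disables the validation
    split and therefore early stopping (training runs to ``max_epochs``)."""

    loss: LossSpec = field(default_factory=LossSpec)
    learning_rate: float = 1e-3
    max_epochs: int = 50
    batch_size: int = 1
    val_fraction: float = 0.10
    min_improvement: float = 0.001
    patience: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValidationError("val_fraction must be in [0, 1)")
        if self.patience < 1:
            raise ValidationError("patience must be >= 1")


def build_model(config: ModelConfig, seed: int) -> UNet3D:
    """Deterministically initialised network; different seeds give different
    parameters (the prerequisite for seed-diverse ensembles)."""
    bias = float(np.log(config.foreground_prior / (1.0 - config.foreground_prior)))
    return UNet3D(NetSpec(depth=config.depth, base_filters=config.base_filters,
                          dropout=config.dropout, output_bias=bias), seed=seed)


def split_validation(cases: Sequence, fraction: float, seed: int):
    """Random disjoint, exhaustive split; validation size = round(fraction*n),
    at least 1."""
    n = len(cases)
    if n < 2:
        raise ValidationError("need at least 2 cases to split off a validation set")
    k = max(1, int(round(fraction * n)))
    idx = np.random.default_rng(seed).permutation(n)
    val_idx = set(idx[:k].tolist())
    train_set = [cases[i] for i in range(n) if i not in val_idx]
    val_set = [cases[i] for i in sorted(val_idx)]
    return train_set, val_set


class EarlyStopper:
    """Streak-based early stopping on a 'higher is better' metric."""

    def __init__(self, min_improvement: float = 0.001, patience: int = 4):
        self.min_improvement = min_improvement
        self.patience = patience
        self.best = -np.inf
        self.best_epoch: int | None = None
        self._streak = 0
        self._epoch = -1

    def update(self, metric: float) -> bool:
        """Record one epoch's metric; returns True when training should stop."""
        self._epoch += 1
        improvement = metric - self.best
        if metric > self.best:
            self.best = metric
            self.best_epoch = self._epoch
        if improvement < self.min_improvement:
            self._streak += 1
        else:
            self._streak = 0
        return self._streak >= self.patience


def early_stop_epoch(trace: Sequence[float], min_improvement: float = 0.001,
                     patience: int = 4) -> int | None:
    """Index of the epoch after which the stop rule fires on a metric trace,
    or None if it never does (training would run to the end)."""
    stopper = EarlyStopper(min_improvement, patience)
    for i, m in enumerate(trace):
        if stopper.update(m):
            return i
    return None


def _case_arrays(case: SegCase) -> Tuple[np.ndarray, np.ndarray]:
    return case.image.voxels.astype(np.float32), case.organ_mask.astype(np.float32)


def train(model: UNet3D, cases: Sequence[SegCase], cfg: TrainConfig,
          spec: ROISpec | None = None) -> List[dict]:
    """Train in place; returns the per-epoch log.

    ``cases`` may be raw (pass ``spec`` to preprocess them here) or already
    preprocessed to the model's input shape.  Batches of ``batch_size`` cases
    average their Dice-term gradients before each Adam step; the HD part of a
    combined loss enters the monitored loss value but not the gradient.
    """
    if len(cases) < 1:
        raise ValidationError("no training cases")
    if spec is not None:
        cases = [preprocess_case(c, spec) for c in cases]
    data = [_case_arrays(c) for c in cases]

    use_val = cfg.val_fraction > 0.0 and len(data) >= 2
    if use_val:
        train_data, val_data = split_validation(data, cfg.val_fraction, cfg.seed)
    else:
        train_data, val_data = list(data), []

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    stopper = EarlyStopper(cfg.min_improvement, cfg.patience)
    best_state = None
    log: List[dict] = []

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_data))
        ep_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            grads = None
            for i in batch:
                x, r = train_data[i]
                prob = model.forward(x, train=True)
                lv = loss_value(prob, r, cfg.loss)
                if not np.isfinite(lv):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}: {lv}")
                ep_losses.append(lv)
                model.backward(soft_dice_grad(prob, r, w=cfg.loss.w))
                g = model.gradients()
                grads = g if grads is None else [a + b for a, b in zip(grads, g)]
            opt.step([g / len(batch) for g in grads])
        entry = {"epoch": epoch, "train_loss": float(np.mean(ep_losses))}
        if use_val:
            val_losses = [loss_value(model.forward(x, train=False), r, cfg.loss)
                          for x, r in val_data]
            val_metric = -float(np.mean(val_losses))
            entry["val_loss"] = -val_metric
            stop = stopper.update(val_metric)
            if stopper.best_epoch == epoch:
                best_state = model.get_state()
            log.append(entry)
            if stop:
                break
        else:
            log.append(entry)

    if use_val and best_state is not None:
        model.set_state(best_state)
    return log


def predict(model: UNet3D, case: SegCase, spec: ROISpec | None = None
            ) -> Tuple[np.ndarray, np.ndarray]:
    """Deterministic inference (dropout off): returns (soft map, 0.5-threshold
    binary mask); preprocesses first when ``spec`` is given."""
    if spec is not None:
        case = preprocess_case(case, spec)
    prob = model.forward(case.image.voxels.astype(np.float32), train=False)
    return prob, (prob >= 0.5).astype(np.uint8)


def save_model(model: UNet3D, path: str) -> None:
    """Persist parameters and architecture to an .npz file."""
    arrays = {f"p{i}": p for i, p in enumerate(model.parameters())}
    meta = json.dumps({"depth": model.spec.depth, "base_filters": model.spec.base_filters,
                       "dropout": model.spec.dropout, "in_channels": model.spec.in_channels,
                       "seed": model.seed})
    np.savez(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_model(path: str) -> UNet3D:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        model = UNet3D(NetSpec(depth=meta["depth"], base_filters=meta["base_filters"],
                               dropout=meta["dropout"], in_channels=meta["in_channels"]),
                       seed=meta["seed"])
        model.set_state([data[f"p{i}"] for i in range(len(model.parameters()))])
    return model
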