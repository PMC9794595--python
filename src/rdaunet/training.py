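"""Training loop: weighted binary cross-entropy + Adam, fully seeded.

The loss down-weights the foreground term by beta < 1,

    WBCE(p, phat) = -mean[ beta * p * log(phat) + (1 - p) * log(1 - phat) ],

which penalises false positives relatively more and therefore trades a
little recall for precision -- the right direction when background clutter
(ghost organoids, bubbles) would otherwise be segmented as foreground.
Predictions are clamped to [eps, 1 - eps] before the logs.

``train`` runs Adam at a constant learning rate (default 1e-3) for up to
``max_epochs`` epochs (default 80) or ``max_steps`` optimiser steps,
annealing the dynamic-convolution attention temperature towards 1 over the
first epochs, recording per-epoch train/validation loss and validation
metrics, and restoring the best-on-validation checkpoint at the end.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _tensor as T
from ._tensor import Tensor
from . import nn
from .nn import set_global_seed  # re-exported: one seed drives everything
from . import evaluation

__all__ = ["LossParams", "TrainConfig", "weighted_bce", "train",
           "predict", "set_global_seed", "TrainingDivergedError"]

log = logging.getLogger(__name__)


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class LossParams:
    """beta weights the foreground (positive-class) term; beta = 1 recovers
    plain BCE, beta < 1 suppresses false positives."""

    beta: float = 0.7
    eps: float = 1e-7

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be > 0")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    max_epochs: int = 80
    max_steps: int | None = None
    batch_size: int = 4
    beta: float = 0.7
    seed: int = 0
    temperature_start: float = 30.0
    temperature_anneal_epochs: int = 10
    threshold: float = 0.5

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


def weighted_bce(pred, target, params: LossParams | float = LossParams()) -> Tensor:
    """Mean weighted binary cross-entropy over all pixels."""
    if not isinstance(params, LossParams):
        params = LossParams(beta=float(params))
    p_hat = pred if isinstance(pred, Tensor) else Tensor(np.asarray(pred, dtype=np.float64))
    dt = p_hat.data.dtype if p_hat.data.dtype.kind == "f" else np.float64
    p = Tensor(np.asarray(target.data if isinstance(target, Tensor) else target,
                          dtype=dt))
    if p_hat.shape != p.shape:
        raise ValueError(f"shape mismatch: pred {p_hat.shape} vs target {p.shape}")
    p_hat = T.clamp(p_hat, params.eps, 1.0 - params.eps)
    pos = p * T.log(p_hat) * params.beta
    neg = (1.0 - p) * T.log(1.0 - p_hat)
    return -T.tmean(pos + neg)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def _stack(dataset, idx) -> tuple[np.ndarray, np.ndarray]:
    xs = np.stack([np.asarray(dataset[i][0], dtype=np.float32) for i in idx])
    ys = np.stack([np.asarray(dataset[i][1], dtype=np.float32) for i in idx])
    return xs[:, None], ys[:, None]


def _set_temperature(model: nn.Module, temp: float) -> None:
    for m in model.modules():
        if isinstance(m, nn.DynamicConv2d):
            m.temperature = temp


def predict(model: nn.Module, image: np.ndarray) -> np.ndarray:
    """Probability map for one H x W image (inference mode, no gradients)."""
    model.eval()
    with T.no_grad():
        out = model(Tensor(np.asarray(image, dtype=np.float32)[None, None]))
    return out.data[0, 0]


def _validate(model, val_set, loss_params, threshold):
    model.eval()
    losses, counts = [], evaluation.ConfusionCounts(0, 0, 0, 0)
    with T.no_grad():
        for img, msk in val_set:
            out = model(Tensor(np.asarray(img, dtype=np.float32)[None, None]))
            losses.append(float(weighted_bce(
                out, np.asarray(msk, dtype=np.float32)[None, None],
                loss_params).data))
            pred = evaluation.binarize(out.data[0, 0], threshold)
            counts = counts + evaluation.confusion(pred, np.asarray(msk))
    m = evaluation.metrics(counts)
    return float(np.mean(losses)), m


def train(model: nn.Module, train_set, val_set, config: TrainConfig):
    """Train ``model``; returns ``(model, history)`` with the model restored
    to its best-on-validation checkpoint (last epoch if no validation set)."""
    if not train_set:
        raise ValueError("training set is empty")
    if not val_set:
        warnings.warn("empty validation set: checkpointing falls back to the "
                      "last epoch", stacklevel=2)
    set_global_seed(config.seed)
    rng = np.random.default_rng(config.seed + 1)
    loss_params = LossParams(beta=config.beta)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    history, best = [], (np.inf, None)
    steps = 0
    for epoch in range(config.max_epochs):
        frac = min(epoch / max(config.temperature_anneal_epochs, 1), 1.0)
        _set_temperature(model, 1.0 + (config.temperature_start - 1.0) * (1 - frac))
        model.train()
        epoch_losses = []
        for idx in _batches(len(train_set), config.batch_size, rng):
            xs, ys = _stack(train_set, idx)
            out = model(Tensor(xs))
            loss = weighted_bce(out, ys, loss_params)
            value = float(loss.data)
            if not np.isfinite(value):
                raise TrainingDivergedError(
                    f"loss became {value} at step {steps}; lower the learning "
                    "rate or check the probability clamping")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(value)
            steps += 1
            if config.max_steps is not None and steps >= config.max_steps:
                break
        row = {"epoch": epoch, "steps": steps,
               "train_loss": float(np.mean(epoch_losses))}
        if val_set:
            val_loss, vm = _validate(model, val_set, loss_params, config.threshold)
            row.update(val_loss=val_loss, val_iou=vm.iou, val_dsc=vm.dsc,
                       val_precision=vm.precision, val_recall=vm.recall)
            if val_loss < best[0]:
                best = (val_loss, copy.deepcopy(model.state_dict()))
        history.append(row)
        if config.max_steps is not None and steps >= config.max_steps:
            break
    if best[1] is not None:
        model.load_state_dict(best[1])
    model.eval()
    return model, pd.DataFrame(history)
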