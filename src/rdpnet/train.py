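"""Model optimization with label-smoothed cross-entropy.

The regimen: Adam (lr 5e-4, weight decay 1e-4), batch size 64, up to 100
epochs, per-step gradient clipping at global norm 1.0, label smoothing
coefficient 0.2.  Early stopping monitors the training loss (patience 10
epochs, minimum improvement 1e-4); model selection follows the
training-set-optimum rule — the epoch with the highest training
accuracy, ties broken by lowest training loss, then by earliest epoch.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .model import RDPNet, softmax
from .preprocess import LabeledSegment, segments_to_arrays

logger = logging.getLogger(__name__)

PROB_FLOOR = 1e-12  # keeps log() finite inside the loss


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 5e-4
    weight_decay: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 100
    clip_norm: float = 1.0
    smoothing_alpha: float = 0.2
    seed: int = 0
    early_stop_patience: int = 10
    early_stop_min_delta: float = 1e-4

    def __post_init__(self) -> None:
        if min(self.lr, self.weight_decay, self.batch_size, self.max_epochs,
               self.clip_norm, self.early_stop_patience) <= 0:
            raise ValueError("all training settings must be positive")
        if not 0.0 <= self.smoothing_alpha < 1.0:
            raise ValueError("smoothing_alpha must be in [0, 1)")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "lr", "weight_decay", "batch_size", "max_epochs", "clip_norm",
            "smoothing_alpha", "seed", "early_stop_patience",
            "early_stop_min_delta")}

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


@dataclass
class TrainHistory:
    """Per-epoch training loss and accuracy, plus the selected epoch."""

    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    selected_epoch: int = 0

    def __len__(self) -> int:
        return len(self.loss)


def smooth_labels(y: np.ndarray, alpha: float, n_classes: int) -> np.ndarray:
    """Soft-label matrix: true class (1-alpha) + alpha/C, others alpha/C."""
    y = np.asarray(y, dtype=np.int64)
    if y.min() < 0 or y.max() >= n_classes:
        raise IndexError("class label out of range")
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must be in [0, 1)")
    out = np.full((y.size, n_classes), alpha / n_classes, dtype=np.float64)
    out[np.arange(y.size), y] += 1.0 - alpha
    return out


def smoothed_ce_loss(probs: np.ndarray, soft_labels: np.ndarray) -> float:
    """Mean cross term -1/N sum_ij y~_ij log p_ij over the batch."""
    p = np.maximum(probs, PROB_FLOOR)
    return float(-(soft_labels * np.log(p)).sum(axis=1).mean())


def select_checkpoint(history: TrainHistory) -> int:
    """Training-set-optimum epoch: max accuracy, then min loss, then
    earliest."""
    if len(history) == 0:
        raise ValueError("empty history")
    order = sorted(
        range(len(history)),
        key=lambda i: (-history.accuracy[i], history.loss[i], i))
    return order[0]


def _is_better(acc: float, loss: float, best: tuple[float, float]) -> bool:
    return (-acc, loss) < (-best[0], best[1])


def train_model(model: RDPNet, train_segments: list[LabeledSegment],
                cfg: TrainConfig) -> tuple[RDPNet, TrainHistory]:
    """Optimize the model in place; returns it restored to the selected
    epoch's weights together with the full history.

    Fully reproducible: the seed drives the per-epoch shuffles and every
    dropout mask.
    """
    if not train_segments:
        raise ValueError("no training data")
    x_all, y_all = segments_to_arrays(train_segments)
    n = x_all.shape[0]
    C = model.cfg.n_classes
    rng = np.random.default_rng(cfg.seed)
    model.set_rng(np.random.default_rng(rng.integers(2 ** 31)))
    opt = nn.Adam(model.parameters(), lr=cfg.lr,
                  weight_decay=cfg.weight_decay)
    history = TrainHistory()
    best = (-np.inf, np.inf)
    best_state: dict[str, np.ndarray] | None = None
    best_loss_for_stop = np.inf
    stall = 0
    model.train()
    for epoch in range(cfg.max_epochs):
        perm = np.random.default_rng(rng.integers(2 ** 31)).permutation(n)
        total_loss = 0.0
        total_correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            xb, yb = x_all[idx], y_all[idx]
            logits = model.forward(xb)
            probs = softmax(logits)
            soft = smooth_labels(yb, cfg.smoothing_alpha, C)
            loss = smoothed_ce_loss(probs, soft)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}")
            total_loss += loss * len(idx)
            total_correct += int((logits.argmax(axis=1) == yb).sum())
            model.zero_grad()
            model.backward(((probs - soft) / len(idx)).astype(nn.DTYPE))
            nn.clip_grad_norm(model.parameters(), cfg.clip_norm)
            opt.step()
        epoch_loss = total_loss / n
        epoch_acc = total_correct / n
        history.loss.append(epoch_loss)
        history.accuracy.append(epoch_acc)
        logger.info("epoch %d: loss %.4f acc %.4f", epoch, epoch_loss,
                    epoch_acc)
        if _is_better(epoch_acc, epoch_loss, best):
            best = (epoch_acc, epoch_loss)
            best_state = copy.deepcopy(model.state_arrays())
        if epoch_loss < best_loss_for_stop - cfg.early_stop_min_delta:
            best_loss_for_stop = epoch_loss
            stall = 0
        else:
            stall += 1
            if stall >= cfg.early_stop_patience:
                logger.info("early stop at epoch %d", epoch)
                break
    history.selected_epoch = select_checkpoint(history)
    if best_state is not None:
        model.load_state_arrays(best_state)
    model.eval()
    return model, history


def predict(model: RDPNet, segments: list[LabeledSegment],
            batch_size: int = 256) -> np.ndarray:
    """Class predictions in evaluation mode (running BN statistics,
    no dropout)."""
    x, _ = segments_to_arrays(segments)
    model.eval()
    preds = []
    for start in range(0, x.shape[0], batch_size):
        logits = model.forward(x[start:start + batch_size])
        preds.append(logits.argmax(axis=1))
    return np.concatenate(preds)
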