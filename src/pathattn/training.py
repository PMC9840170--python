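"""Supervised training: stratified 70/30 split, cross-entropy, SGD + cosine decay.

The optimizer is plain momentum SGD with optional weight decay; the learning
rate follows a per-epoch cosine schedule lr0 * (1 + cos(pi * epoch/epochs)) / 2.
The mask is re-applied to the embedding tensor after every step, so off-mask
weights stay exactly zero.  The returned model is the epoch checkpoint with
the best validation accuracy (ties go to the earlier epoch).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .gene_sets import MaskMatrix
from .model import ModelConfig, ModelState, init_state, _forward_batch, _backward_batch

logger = logging.getLogger(__name__)


@dataclass
class TrainingConfig:
    epochs: int = 20
    batch_size: int = 128
    lr0: float = 0.2
    momentum: float = 0.9
    weight_decay: float = 1e-3
    val_fraction: float = 0.30
    max_grad_norm: float = 1.0    # global gradient-norm clip; 0 disables
    class_weights: bool = False   # inverse-frequency reweighting of the loss
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainingHistory:
    """Per-epoch curves; ``lr`` follows the cosine schedule exactly."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.train_loss)),
                "lr": self.lr,
                "train_loss": self.train_loss,
                "train_acc": self.train_acc,
                "val_loss": self.val_loss,
                "val_acc": self.val_acc,
            }
        )


def cosine_lr(epoch: int, epochs: int, lr0: float) -> float:
    """Cosine learning-rate decay: lr0 at epoch 0, ~0 at the final epoch."""
    if not (0 <= epoch < epochs):
        raise ValueError(f"epoch {epoch} outside [0, {epochs})")
    return lr0 * (1.0 + np.cos(np.pi * epoch / epochs)) / 2.0


def split_train_val(
    x: ExpressionMatrix, fraction: float = 0.30, seed: int = 0
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Stratified split: each class contributes round(fraction * n_class) cells
    to validation (at least 1 when the class has >= 2 cells).  Singleton
    classes stay in training with a warning."""
    if x.labels is None:
        raise ValueError("split requires labels")
    rng = np.random.default_rng(seed)
    val_idx: list[int] = []
    for label in pd.unique(x.labels):
        idx = np.where(x.labels == label)[0]
        if len(idx) < 2:
            logger.warning("class %r has a single cell; kept in training", label)
            continue
        n_val = int(np.round(fraction * len(idx)))
        n_val = min(max(n_val, 1), len(idx) - 1)
        val_idx.extend(rng.choice(idx, size=n_val, replace=False))
    val_mask = np.zeros(x.n_cells, dtype=bool)
    val_mask[val_idx] = True
    return x.subset(np.where(~val_mask)[0]), x.subset(np.where(val_mask)[0])


def _cross_entropy(probs: np.ndarray, y: np.ndarray, weights: np.ndarray | None) -> float:
    p = np.clip(probs[np.arange(len(y)), y], 1e-12, None)
    if weights is None:
        return float(-np.log(p).mean())
    w = weights[y]
    return float(-(w * np.log(p)).sum() / w.sum())


def _evaluate(E: np.ndarray, y: np.ndarray, state: ModelState,
              weights: np.ndarray | None, chunk: int = 512) -> tuple[float, float]:
    losses, hits, total = 0.0, 0, len(y)
    wsum = 0.0
    for start in range(0, total, chunk):
        sl = slice(start, start + chunk)
        probs, _, _ = _forward_batch(E[sl], state)
        p = np.clip(probs[np.arange(len(y[sl])), y[sl]], 1e-12, None)
        w = np.ones(len(p)) if weights is None else weights[y[sl]]
        losses += float(-(w * np.log(p)).sum())
        wsum += float(w.sum())
        hits += int((probs.argmax(axis=1) == y[sl]).sum())
    return losses / wsum, hits / total


def train(
    ref: ExpressionMatrix,
    mask: MaskMatrix,
    mconfig: ModelConfig | None = None,
    tconfig: TrainingConfig | None = None,
) -> tuple[ModelState, TrainingHistory]:
    """Train the classifier on a labeled, aligned, normalized reference.

    Returns the best-validation-accuracy checkpoint and the full history.
    Fully reproducible given ``mconfig.seed`` and ``tconfig.seed``.
    """
    mconfig = mconfig or ModelConfig()
    tconfig = tconfig or TrainingConfig()
    if ref.labels is None:
        raise ValueError("reference must carry labels")
    if tuple(ref.gene_names.names) != tuple(mask.gene_names.names):
        raise ValueError("reference genes are not aligned to the mask vocabulary")
    classes = tuple(sorted(pd.unique(ref.labels).astype(str)))
    if len(classes) < 2:
        raise ValueError("training requires at least 2 cell-type labels")
    if "Unknown" in classes:
        raise ValueError('"Unknown" is reserved and cannot be a training class')
    class_index = {c: i for i, c in enumerate(classes)}

    tr, va = split_train_val(ref, tconfig.val_fraction, seed=tconfig.seed)
    y_tr = np.array([class_index[str(l)] for l in tr.labels])
    y_va = np.array([class_index[str(l)] for l in va.labels])
    E_tr, E_va = tr.values, va.values

    weights = None
    if tconfig.class_weights:
        counts = np.bincount(y_tr, minlength=len(classes)).astype(float)
        weights = counts.sum() / np.maximum(counts, 1.0) / len(classes)

    state = init_state(mask, classes, mconfig)
    velocity = {k: np.zeros_like(v) for k, v in state.params.items()}
    rng = np.random.default_rng(np.random.SeedSequence([tconfig.seed, 7919]))
    history = TrainingHistory()
    best = (-1.0, -1, None)  # (val_acc, epoch, params snapshot)

    for epoch in range(tconfig.epochs):
        lr = cosine_lr(epoch, tconfig.epochs, tconfig.lr0)
        order = rng.permutation(len(y_tr))
        epoch_loss, epoch_n = 0.0, 0
        for start in range(0, len(order), tconfig.batch_size):
            batch = order[start : start + tconfig.batch_size]
            probs, _, cache = _forward_batch(
                E_tr[batch], state, training=True, rng=rng, need_cache=True
            )
            bsz = len(batch)
            yb = y_tr[batch]
            epoch_loss += _cross_entropy(probs, yb, weights) * bsz
            epoch_n += bsz
            if weights is None:
                dlogits = probs.copy()
                dlogits[np.arange(bsz), yb] -= 1.0
                dlogits /= bsz
            else:
                w = weights[yb]
                dlogits = probs * w[:, None]
                dlogits[np.arange(bsz), yb] -= w
                dlogits /= w.sum()
            if not np.isfinite(dlogits).all():
                raise FloatingPointError(
                    f"non-finite loss gradient at epoch {epoch}, batch {start // tconfig.batch_size}"
                )
            grads = _backward_batch(dlogits, state, cache)
            if tconfig.max_grad_norm > 0:
                gnorm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
                if gnorm > tconfig.max_grad_norm:
                    scale = tconfig.max_grad_norm / gnorm
                    grads = {k: g * scale for k, g in grads.items()}
            for key, gval in grads.items():
                # decay only weight matrices, not biases / layer norms / CLS
                if tconfig.weight_decay and "W" in key:
                    gval = gval + tconfig.weight_decay * state.params[key]
                velocity[key] = tconfig.momentum * velocity[key] - lr * gval
                state.params[key] += velocity[key]
            state.apply_mask()
        # train loss = running mean of batch losses (the curve a trainer logs);
        # accuracies and validation loss are full post-epoch evaluations
        tl = epoch_loss / epoch_n
        _, ta = _evaluate(E_tr, y_tr, state, weights)
        vl, vacc = _evaluate(E_va, y_va, state, weights)
        history.train_loss.append(tl)
        history.train_acc.append(ta)
        history.val_loss.append(vl)
        history.val_acc.append(vacc)
        history.lr.append(lr)
        logger.info(
            "epoch %d lr %.4g train loss %.4f acc %.4f | val loss %.4f acc %.4f",
            epoch, lr, tl, ta, vl, vacc,
        )
        if vacc > best[0]:
            best = (vacc, epoch, copy.deepcopy(state.params))

    history.best_epoch = best[1]
    state.params = best[2]
    state.apply_mask()
    return state, history
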