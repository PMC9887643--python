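"""Training loop: binary cross-entropy, Adam, and the batch-size schedule.

The learning rate is effectively scheduled by doubling the batch size at fixed
epoch milestones while dividing the weight decay by the same factor, keeping
the product batch_size * weight_decay constant across epochs (the implemented
reading of holding the two in fixed proportion — a growing batch at constant
learning rate behaves like a decayed learning rate, and shrinking the decay in
step keeps the effective regularization pressure per step unchanged).

All randomness flows from the integer seed in :class:`TrainConfig`; identical
seeds and configs reproduce identical histories on fixed hardware.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import Adam, bce_with_logits
from .model import InteractionModel

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "PairStore",
    "bce_loss",
    "bce_from_logits",
    "schedule_step",
    "fit",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    The learning rate and weight decay defaults are the published values for
    the full-scale model; reduced-dimension desk-scale runs typically pass a
    larger learning rate.
    """

    epochs: int = 40
    learning_rate: float = 3.1e-5
    weight_decay: float = 7.2e-7
    base_batch_size: int = 32
    milestones: tuple = (10, 20, 30)
    factor: float = 2.0
    seed: int = 0
    grad_clip: float | None = None

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.factor <= 1.0:
            raise ValueError("schedule factor must be > 1")


@dataclass
class TrainHistory:
    epochs: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_auc: list = field(default_factory=list)
    batch_size: list = field(default_factory=list)
    weight_decay: list = field(default_factory=list)
    best_epoch: int | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({k: v for k, v in asdict(self).items()
                             if isinstance(v, list) and v})


def bce_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy of probabilities against 0/1 labels."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    eps = np.finfo(float).tiny
    p = np.clip(p, eps, 1.0 - np.finfo(float).epsneg)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def bce_from_logits(logits: np.ndarray, labels: np.ndarray) -> float:
    """Numerically stable binary cross-entropy straight from logits."""
    l = np.asarray(logits, dtype=float)
    y = np.asarray(labels, dtype=float)
    if l.shape != y.shape:
        raise ValueError(f"length mismatch: {l.shape} vs {y.shape}")
    return float(np.mean(np.maximum(l, 0) - l * y + np.log1p(np.exp(-np.abs(l)))))


def schedule_step(epoch: int, config: TrainConfig):
    """(batch_size, weight_decay) at a given epoch; the product is constant."""
    m = sum(1 for ms in config.milestones if epoch >= ms)
    f = config.factor ** m
    return int(round(config.base_batch_size * f)), config.weight_decay / f


class PairStore:
    """Shared feature stores for (metabolite index, protein index, label) pairs.

    ``met_matrix`` holds processed metabolite feature rows, ``prot_embedded``
    position-encoded residue matrices; pairs reference rows by index so the
    per-protein matrices are materialized once.
    """

    def __init__(self, met_matrix: np.ndarray, prot_embedded: np.ndarray,
                 met_index: dict, prot_index: dict):
        self.met_matrix = np.asarray(met_matrix)
        self.prot_embedded = np.asarray(prot_embedded)
        self.met_index = met_index
        self.prot_index = prot_index

    def pairs_from_table(self, table) -> tuple:
        frame = table.frame if hasattr(table, "frame") else table
        mi = frame["metabolite_id"].map(self.met_index)
        pi = frame["protein_id"].map(self.prot_index)
        if mi.isna().any() or pi.isna().any():
            raise KeyError("interaction references an entity missing from the store")
        return (mi.to_numpy(dtype=int), pi.to_numpy(dtype=int),
                frame["label"].to_numpy(dtype=float))

    def batch(self, met_idx, prot_idx):
        return self.met_matrix[met_idx], self.prot_embedded[prot_idx]


def _epoch_pass(model, store, met_idx, prot_idx, labels, batch_size, opt, rng,
                grad_clip):
    order = rng.permutation(len(labels))
    losses, counts = [], []
    for start in range(0, len(order), batch_size):
        sel = order[start:start + batch_size]
        met, prot = store.batch(met_idx[sel], prot_idx[sel])
        logits = model.forward_logits(met, prot, train=True)
        loss = bce_with_logits(logits, labels[sel])
        opt.zero_grad()
        loss.backward()
        if grad_clip is not None:
            total = np.sqrt(sum(float((p.grad ** 2).sum())
                                for p in opt.params if p.grad is not None))
            if total > grad_clip:
                scale = grad_clip / (total + 1e-12)
                for p in opt.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        opt.step()
        losses.append(float(loss.data))
        counts.append(len(sel))
    return float(np.average(losses, weights=counts))


def predict_logits(model: InteractionModel, store: PairStore, met_idx, prot_idx,
                   batch_size: int = 256) -> np.ndarray:
    out = []
    for start in range(0, len(met_idx), batch_size):
        met, prot = store.batch(met_idx[start:start + batch_size],
                                prot_idx[start:start + batch_size])
        out.append(model.forward_logits(met, prot, train=False).detach())
    return np.concatenate(out) if out else np.empty(0)


def fit(model: InteractionModel, store: PairStore, train_table,
        config: TrainConfig, val_table=None, checkpoint_path=None,
        callback=None):
    """Train ``model`` on the pairs of ``train_table`` with Adam and the
    batch-size/weight-decay schedule; returns (model, TrainHistory).

    When ``val_table`` is given, validation BCE and AUC are tracked each epoch
    and the best checkpoint (by validation AUC) is written to
    ``checkpoint_path`` if provided. Non-finite training loss aborts.
    """
    from .evaluate import roc_auc

    mi, pi, y = store.pairs_from_table(train_table)
    if len(y) == 0:
        raise ValueError("training fold is empty")
    val = store.pairs_from_table(val_table) if val_table is not None else None
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate,
               weight_decay=config.weight_decay)
    hist = TrainHistory()
    best_auc = -np.inf
    for epoch in range(config.epochs):
        bs, wd = schedule_step(epoch, config)
        opt.weight_decay = wd
        loss = _epoch_pass(model, store, mi, pi, y, bs, opt, rng, config.grad_clip)
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged at epoch {epoch}: loss={loss}")
        hist.epochs.append(epoch)
        hist.train_loss.append(loss)
        hist.batch_size.append(bs)
        hist.weight_decay.append(wd)
        if val is not None:
            vl = predict_logits(model, store, val[0], val[1])
            hist.val_loss.append(bce_from_logits(vl, val[2]))
            try:
                auc = roc_auc(1.0 / (1.0 + np.exp(-vl)), val[2])
            except ValueError:
                auc = np.nan
            hist.val_auc.append(auc)
            if np.isfinite(auc) and auc > best_auc:
                best_auc = auc
                hist.best_epoch = epoch
                if checkpoint_path is not None:
                    model.save(checkpoint_path)
        if callback is not None:
            callback(epoch, hist)
    if val is None and checkpoint_path is not None:
        model.save(checkpoint_path)
    return model, hist
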