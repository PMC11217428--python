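"""Toy-scale training loop: NAdam, plateau LR decay, F1 model selection.

Full-scale training (thousands of maps, distributed batches) is out of
scope; this loop exists so the classifier is trainable and overfittable on
small synthetic datasets on a single CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score

from .loss import class_weights, weighted_ce_loss_var
from .network import VoxelClassifier


class NAdam:
    """Nesterov-momentum Adam (Dozat 2016)."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            m_hat = m / bc1
            v_hat = v / bc2
            update = (b1 * m_hat + (1.0 - b1) * g / bc1) / (
                np.sqrt(v_hat) + self.eps)
            p.data = (p.data - self.lr * update).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


@dataclass
class TrainConfig:
    lr: float = 1e-4
    epochs: int = 20
    steps_per_epoch: int = 10
    batch_size: int = 2
    patience: int = 5  # epochs without val-loss improvement before LR decay
    lr_factor: float = 0.1
    seed: int = 0


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_f1: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_state: dict[str, np.ndarray] | None = None


def _dataset_arrays(dataset) -> tuple[np.ndarray, np.ndarray]:
    grids = np.stack([np.asarray(g, dtype=np.float32) for g, _ in dataset])
    labels = np.stack([np.asarray(l) for _, l in dataset])
    if grids.ndim == 4:
        grids = grids[:, None]  # add channel axis
    return grids, labels


def train_toy(network: VoxelClassifier, dataset,
              config: TrainConfig | None = None,
              val_dataset=None) -> TrainHistory:
    """Train on (sub-grid, label-grid) pairs; returns the loss history.

    ``dataset``: iterable of (values (S,S,S), labels (S,S,S) int) pairs.
    Class weights are computed from the training labels.  Validation loss
    drives plateau LR decay (patience then x ``lr_factor``); the epoch with
    the highest validation macro-F1 is kept as ``best_state``.
    """
    if config is None:
        config = TrainConfig()
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty training dataset")
    x_train, y_train = _dataset_arrays(dataset)
    if val_dataset is None:
        x_val, y_val = x_train, y_train
    else:
        x_val, y_val = _dataset_arrays(list(val_dataset))
    c = network.spec.out_channels
    counts = np.bincount(y_train.reshape(-1), minlength=c)
    weights = class_weights(counts)

    rng = np.random.default_rng(config.seed)
    opt = NAdam(network.parameters(), lr=config.lr)
    history = TrainHistory()
    best_f1 = -np.inf
    stale = 0
    best_val = np.inf
    for epoch in range(config.epochs):
        epoch_losses = []
        for _ in range(config.steps_per_epoch):
            idx = rng.integers(0, len(x_train), size=config.batch_size)
            logits = network.forward(x_train[idx], train=True, rng=rng)
            loss = weighted_ce_loss_var(logits, y_train[idx], weights)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        # validation pass, dropout off
        logits = network.forward(x_val, train=False)
        vloss = float(weighted_ce_loss_var(logits, y_val, weights).data)
        pred = logits.data.argmax(axis=1).reshape(-1)
        f1 = f1_score(y_val.reshape(-1), pred, average="macro",
                      zero_division=0)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(vloss)
        history.val_f1.append(float(f1))
        history.lr.append(opt.lr)
        if f1 > best_f1:
            best_f1 = f1
            history.best_epoch = epoch
            history.best_state = {name: p.data.copy()
                                  for name, p in network.named_parameters()}
        if vloss < best_val - 1e-12:
            best_val = vloss
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                opt.lr *= config.lr_factor
                stale = 0
    if history.best_state is not None:
        for name, p in network.named_parameters():
            p.data = history.best_state[name].copy()
    return history
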