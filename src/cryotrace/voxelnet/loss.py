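"""Weighted cross-entropy loss and inverse-frequency class weights.

The loss is the mean over samples of the class-weighted negative
log-softmax at the true class — note the division by the sample count N,
not by the sum of the selected weights (which is what common library
implementations of weighted cross-entropy divide by):

    L(x, y) = -(1/N) sum_n w_{y_n} * log softmax(x_n)_{y_n}

Class weights down-weight abundant classes:  w_c = 1 - n_c / sum_k n_k,
so the weight vector always sums to C - 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_softmax as _log_softmax

from . import autograd as ag
from .autograd import Var


@dataclass
class ClassWeightVector:
    """Per-class weights derived from per-class voxel counts."""

    weights: np.ndarray
    class_counts: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.class_counts = np.asarray(self.class_counts, dtype=float)


def class_weights(class_counts) -> ClassWeightVector:
    """Inverse-frequency weights: w_c = 1 - n_c / total."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("class counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("at least one class count must be positive")
    return ClassWeightVector(weights=1.0 - counts / total,
                             class_counts=counts)


def _check_labels(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        raise ValueError(
            f"label outside [0, {n_classes}): range "
            f"[{labels.min()}, {labels.max()}]")
    return labels


def weighted_ce_loss(logits: np.ndarray, labels: np.ndarray,
                     weights) -> float:
    """Evaluate the weighted cross-entropy on plain arrays.

    ``logits``: (N, C); ``labels``: (N,) integer class indices;
    ``weights``: length-C vector or a :class:`ClassWeightVector`.
    """
    logits = np.asarray(logits, dtype=float)
    if isinstance(weights, ClassWeightVector):
        weights = weights.weights
    w = np.asarray(weights, dtype=float)
    n, c = logits.shape
    labels = _check_labels(labels, c)
    logp = _log_softmax(logits, axis=1)
    picked = logp[np.arange(n), labels]
    return float(-(w[labels] * picked).sum() / n)


def weighted_ce_loss_var(logits: Var, labels: np.ndarray,
                         weights) -> Var:
    """Autograd version of the same loss, for training.

    ``logits`` may be (N, C) or (B, C, D, H, W) with labels of matching
    spatial shape.
    """
    if isinstance(weights, ClassWeightVector):
        weights = weights.weights
    w = np.asarray(weights, dtype=float)
    if logits.data.ndim == 5:
        b, c = logits.shape[:2]
        flat = ag.reshape(ag.transpose(logits, (0, 2, 3, 4, 1)), (-1, c))
        labels = np.asarray(labels).reshape(-1)
    else:
        flat = logits
        c = logits.shape[1]
        labels = np.asarray(labels)
    labels = _check_labels(labels, c)
    n = flat.shape[0]
    logp = ag.log_softmax(flat, axis=1)
    onehot = np.zeros((n, c))
    onehot[np.arange(n), labels] = 1.0
    sel = ag.mul(logp, Var(onehot * w[labels][:, None]))
    return ag.mul_scalar(ag.vsum(sel), -1.0 / n)
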