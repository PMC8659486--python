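"""Shared optimisation loop for the two segmentation networks.

Defaults mirror the study setup: Adam at an initial learning rate of 1e-4
halved every 50 epochs, weight decay 1e-8, dropout 0.2, mini-batches of 4,
up to 400 epochs.  Desk-scale runs shrink epochs/batches through
:class:`OptimizerConfig` without touching the loss or architectures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Adam, Tensor
from .nn import functional as F

__all__ = ["OptimizerConfig", "compute_class_weights", "weighted_cross_entropy", "fit"]


@dataclass
class OptimizerConfig:
    lr: float = 1e-4
    lr_drop_every: int = 50
    lr_drop_factor: float = 0.5
    weight_decay: float = 1e-8
    batch_size: int = 4
    epochs: int = 400
    seed: int = 0


def compute_class_weights(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Per-class loss weights, inversely proportional to each foreground
    class's voxel prior and normalised so the background weight is 1."""
    counts = np.bincount(np.asarray(labels).ravel(), minlength=n_classes).astype(float)
    priors = counts / max(counts.sum(), 1.0)
    w = np.ones(n_classes)
    for c in range(1, n_classes):
        if priors[c] > 0:
            w[c] = priors[0] / priors[c]
    return w


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """``(N, D, H, W)`` integer labels -> ``(N, C, D, H, W)`` one-hot."""
    lab = np.asarray(labels)
    out = np.zeros((lab.shape[0], n_classes) + lab.shape[1:], np.float32)
    for c in range(n_classes):
        out[:, c] = lab == c
    return out


def weighted_cross_entropy(
    pred_probs: Tensor | np.ndarray,
    truth_labels: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> Tensor:
    """Class-weighted cross-entropy between per-voxel softmax outputs and
    integer (or one-hot) ground truth.

    Each voxel contributes a binary cross-entropy term per channel, weighted
    by the class weight of the voxel's true class, averaged over the number
    of voxels.  Differentiable when ``pred_probs`` is a graph tensor.
    """
    probs = pred_probs if isinstance(pred_probs, Tensor) else Tensor(pred_probs)
    n_classes = probs.data.shape[1]
    truth = np.asarray(truth_labels)
    if truth.ndim == probs.data.ndim:  # one-hot supplied
        onehot = truth.astype(np.float32)
        dense = onehot.argmax(axis=1)
    else:
        dense = truth
        onehot = one_hot(truth, n_classes)
    if class_weights is None:
        class_weights = np.ones(n_classes)
    wmap = np.asarray(class_weights, np.float32)[dense][:, None]
    return F.weighted_bce_from_probs(probs, onehot, wmap)


def fit(
    model,
    dataset: list[tuple[np.ndarray, np.ndarray]],
    n_classes: int,
    config: OptimizerConfig,
) -> list[float]:
    """Train ``model`` on ``(channels, labels)`` pairs; returns per-epoch
    mean loss.  Fully deterministic for a fixed seed."""
    if not dataset:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(config.seed)
    model.set_rng(rng)
    model.train()
    opt = Adam(
        model.parameters(),
        lr=config.lr,
        weight_decay=config.weight_decay,
    )
    all_labels = np.stack([lab for _, lab in dataset])
    class_w = compute_class_weights(all_labels, n_classes)
    history: list[float] = []
    n = len(dataset)
    # batch order is drawn once per run: with frozen weights (lr=0) the
    # history is then exactly constant even though batch normalisation
    # couples the samples sharing a mini-batch
    order = rng.permutation(n)
    for epoch in range(config.epochs):
        opt.lr = config.lr * config.lr_drop_factor ** (epoch // max(config.lr_drop_every, 1))
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            x = Tensor(np.stack([dataset[i][0] for i in idx]))
            y = np.stack([dataset[i][1] for i in idx])
            probs = F.softmax_channel(model(x))
            loss = weighted_cross_entropy(probs, y, class_w)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            del x, probs, loss  # release the step's graph before the next forward
        history.append(float(np.mean(losses)))
    return history
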