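"""Supervised contrastive loss and the twin-channel training loop.

For an anchor embedding z_i with label y_i in a batch of M = 2N unit
vectors, the positives are the other same-label members
P(i) = {j != i : y_j = y_i} and the per-anchor loss is

    L_i = -(1/|P(i)|) * sum_{j in P(i)}
              log[ exp(z_i.z_j / tau) / sum_{k != i} exp(z_i.z_k / tau) ]

with temperature tau > 0. The total loss sums L_i over all 2N anchors; the
mean over anchors is reported alongside and used for gradient updates so
the step size is batch-size stable. Each training step duplicates the
sampled batch of N images into the two channels of the twin architecture
(2N samples through one shared parameter set), so every anchor is
guaranteed at least one positive — its own duplicate.

Everything is computed with a numerically stable log-sum-exp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .encoder import Encoder, _stack_pixels
from .phantom import LabeledImage
from . import nn


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class ContrastiveBatch:
    """2N unit-norm embeddings with labels and a temperature.

    Element i and element i + N originate from the same image (the batch
    is duplicated into the two channels before embedding).
    """

    embeddings: np.ndarray
    labels: np.ndarray
    temperature_tau: float = 0.07

    def __post_init__(self):
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        m = self.embeddings.shape[0]
        if m != self.labels.shape[0]:
            raise ValueError("embeddings and labels must have equal length")
        if m % 2 != 0:
            raise ValueError("a contrastive batch holds 2N elements (even count)")
        if self.temperature_tau <= 0:
            raise ValueError("temperature_tau must be positive")
        norms = np.linalg.norm(self.embeddings, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-4):
            raise ValueError("embeddings must be unit norm")


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    Defaults: batch of 32 images (64 after channel duplication),
    temperature 0.07, Adam with learning rate 3e-4 (larger rates can
    overshoot into the embedding-collapse saddle where every anchor's
    loss is log(2N-1) and the sphere-projected gradient vanishes).
    ``augmentation``
    "none" duplicates each batch as exact copies; "light" flips/shifts
    the duplicate so it is a non-trivial positive.
    """

    batch_size: int = 32
    temperature_tau: float = 0.07
    epochs: int = 10
    learning_rate: float = 3e-4
    optimizer_name: str = "adam"
    augmentation: str = "none"
    seed: int = 0
    max_batch_retries: int = 20

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.temperature_tau <= 0:
            raise ValueError("temperature_tau must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.augmentation not in ("none", "light"):
            raise ValueError("augmentation must be 'none' or 'light'")
        if self.optimizer_name != "adam":
            raise ValueError("only the 'adam' optimizer is available")


def _loss_core(z: np.ndarray, labels: np.ndarray, tau: float):
    """Per-anchor losses, positives mask and softmax matrix.

    Anchors without positives get NaN per-anchor loss; callers decide
    whether that is an error (standalone op) or an exclusion (training).
    """
    m = z.shape[0]
    sim = (z @ z.T) / tau
    off_diag = ~np.eye(m, dtype=bool)
    logits = np.where(off_diag, sim, -np.inf)
    row_max = logits.max(axis=1, keepdims=True)
    exps = np.exp(logits - row_max)
    lse = row_max[:, 0] + np.log(exps.sum(axis=1))
    log_prob = sim - lse[:, None]
    pos = (labels[:, None] == labels[None, :]) & off_diag
    n_pos = pos.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_anchor = -np.where(pos, log_prob, 0.0).sum(axis=1) / n_pos
    softmax = exps / exps.sum(axis=1, keepdims=True)
    return per_anchor, pos, n_pos, softmax


@dataclass
class SupConLossResult:
    """Total (summed over anchors) and mean per-anchor loss."""

    total: float
    mean: float
    per_anchor: np.ndarray = field(repr=False)


def supcon_loss(batch: ContrastiveBatch) -> SupConLossResult:
    """Evaluate the supervised contrastive loss on a batch.

    Raises if any anchor has no positive (the strict standalone contract;
    the training loop instead excludes such anchors with a warning).
    """
    per_anchor, _, n_pos, _ = _loss_core(
        batch.embeddings, batch.labels, batch.temperature_tau
    )
    if np.any(n_pos == 0):
        bad = int((n_pos == 0).sum())
        raise ValueError(f"{bad} anchor(s) have no positive in the batch")
    return SupConLossResult(
        total=float(per_anchor.sum()),
        mean=float(per_anchor.mean()),
        per_anchor=per_anchor,
    )


def supcon_loss_and_grad(z: np.ndarray, labels: np.ndarray, tau: float):
    """Mean per-anchor loss and its gradient wrt the embeddings.

    Anchors without positives contribute zero loss and zero gradient and
    trigger a warning. Returns ``(mean_loss, total_loss, dz)``.
    """
    per_anchor, pos, n_pos, softmax = _loss_core(z, labels, tau)
    valid = n_pos > 0
    if not np.all(valid):
        warnings.warn(
            f"{int((~valid).sum())} anchor(s) without positives excluded from the loss",
            stacklevel=2,
        )
    n_valid = int(valid.sum())
    if n_valid == 0:
        return 0.0, 0.0, np.zeros_like(z)
    total = float(per_anchor[valid].sum())
    mean = total / n_valid
    # d(mean loss)/d(sim): softmax term minus uniform mass on positives
    g = np.where(valid[:, None], softmax - pos / np.maximum(n_pos, 1)[:, None], 0.0)
    g /= n_valid
    dz = (g + g.T) @ z / tau
    return mean, total, dz


def _augment(pixels: np.ndarray, rng: np.random.Generator, mode: str) -> np.ndarray:
    """Light augmentation for the duplicated channel: flip + small shift."""
    if mode == "none":
        return pixels
    out = pixels.copy()
    for i in range(out.shape[0]):
        if rng.random() < 0.5:
            out[i, 0] = out[i, 0, :, ::-1]
        dy, dx = rng.integers(-2, 3, size=2)
        out[i, 0] = np.roll(out[i, 0], (int(dy), int(dx)), axis=(0, 1))
    return out


@dataclass
class TrainResult:
    encoder: Encoder
    history: pd.DataFrame


def train(
    encoder: Encoder, images: Sequence[LabeledImage], config: TrainConfig
) -> TrainResult:
    """Train the encoder in place with the supervised contrastive objective.

    Each step samples a batch of N images, duplicates it into both
    channels (2N samples, one shared parameter set), embeds, evaluates the
    loss and applies an Adam update. The per-epoch history records the
    mean and the summed loss. Fully reproducible for a fixed seed.
    """
    images = list(images)
    stages = {im.stage for im in images}
    if len(stages) < 2:
        raise ValueError("training data must contain at least 2 stages")
    if config.epochs == 0:
        return TrainResult(encoder, pd.DataFrame(
            columns=["epoch", "mean_loss", "sum_loss"]))

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7EA1]))
    labels_all = np.array([im.stage for im in images])
    pixels_all = _stack_pixels(images)
    n = len(images)
    bs = min(config.batch_size, n)
    optimizer = nn.Adam(encoder.parameters(), lr=config.learning_rate)

    rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_means, epoch_sums = [], []
        for start in range(0, n - bs + 1, bs):
            idx = order[start : start + bs]
            for _ in range(config.max_batch_retries):
                # after duplication every anchor has its copy as a positive,
                # so a sampled batch is always usable; the resample guard
                # protects future batch schemes that do not duplicate
                dup_labels = np.concatenate([labels_all[idx], labels_all[idx]])
                counts = pd.Series(dup_labels).value_counts()
                if (counts >= 2).all():
                    break
                idx = rng.choice(n, size=bs, replace=False)
            else:
                raise RuntimeError("could not sample a batch where every anchor "
                                   "has a positive")
            x = pixels_all[idx]
            x2 = _augment(x, rng, config.augmentation)
            batch_x = np.concatenate([x, x2], axis=0)
            z = encoder.forward(batch_x, train=True)
            mean_loss, sum_loss, dz = supcon_loss_and_grad(
                z, dup_labels, config.temperature_tau
            )
            if not np.isfinite(mean_loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, step {start // bs}"
                )
            optimizer.zero_grad()
            encoder.backward(dz)
            optimizer.step()
            epoch_means.append(mean_loss)
            epoch_sums.append(sum_loss)
        rows.append(
            {"epoch": epoch, "mean_loss": float(np.mean(epoch_means)),
             "sum_loss": float(np.mean(epoch_sums))}
        )
    return TrainResult(encoder, pd.DataFrame(rows))
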