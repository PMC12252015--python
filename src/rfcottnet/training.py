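"""Joint multi-exit training loop and manifest-backed data loading."""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.modules import Module
from .nn.optim import AdamW
from .data.types import DatasetManifest
from .models.multi_exit import joint_loss


def load_arrays(manifest: DatasetManifest, split: str | None = None,
                image_size: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Read images into a (N, 3, H, W) float32 array in [0, 1] plus labels."""
    subset = manifest.samples if split is None else \
        [s for s in manifest.samples if s.split == split]
    class_index = {c: i for i, c in enumerate(manifest.classes)}
    images, labels = [], []
    for s in subset:
        im = Image.open(s.path).convert("RGB")
        if image_size is not None and im.size != (image_size, image_size):
            im = im.resize((image_size, image_size), Image.BILINEAR)
        images.append(np.asarray(im, dtype=np.float32).transpose(2, 0, 1) / 255.0)
        labels.append(class_index[s.label])
    if not images:
        return (np.zeros((0, 3, 1, 1), dtype=np.float32),
                np.zeros(0, dtype=np.int64))
    return np.stack(images), np.asarray(labels, dtype=np.int64)


@dataclass
class EpochLog:
    epoch: int
    stage_losses: list[float]   # mean per-stage cross-entropy over the epoch
    total_loss: float


def train_model(model: Module, images: np.ndarray, labels: np.ndarray,
                epochs: int = 10, batch_size: int = 32, lr: float = 5e-4,
                weight_decay: float = 0.01, seed: int = 0,
                stage_weights: tuple[float, ...] | None = None,
                cosine_decay: bool = True, min_lr_fraction: float = 0.05,
                log_fn=None) -> list[EpochLog]:
    """Train all exit stages jointly with summed cross-entropy losses.

    The learning rate follows a cosine schedule from ``lr`` down to
    ``min_lr_fraction * lr`` unless ``cosine_decay`` is off.  Deterministic
    for fixed (model init, data, seed): batching order is the only randomness
    and is driven by one seeded generator.
    """
    opt = AdamW(model.parameters(), lr=lr, weight_decay=weight_decay)
    rng = np.random.default_rng(seed)
    n = len(images)
    history: list[EpochLog] = []
    model.train()
    for epoch in range(epochs):
        if cosine_decay and epochs > 1:
            frac = 0.5 * (1 + np.cos(np.pi * epoch / (epochs - 1)))
            opt.lr = lr * (min_lr_fraction + (1 - min_lr_fraction) * frac)
        order = rng.permutation(n)
        sums = None
        total = 0.0
        n_batches = 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            x = Tensor(images[idx])
            outs = model(x)
            report = joint_loss(outs, labels[idx], stage_weights)
            opt.zero_grad()
            report.total.backward()
            opt.step()
            vals = report.values()
            sums = vals if sums is None else [a + b for a, b in zip(sums, vals)]
            total += float(report.total.data)
            n_batches += 1
        log = EpochLog(epoch, [s / n_batches for s in sums], total / n_batches)
        history.append(log)
        if log_fn is not None:
            log_fn(log)
    model.eval()
    return history


def predict_final(model: Module, images: np.ndarray,
                  batch_size: int = 64) -> np.ndarray:
    """Final-head class predictions for a batch of images."""
    model.eval()
    preds = []
    with ag.no_grad():
        for start in range(0, len(images), batch_size):
            outs = model(Tensor(images[start:start + batch_size]))
            logits = outs[-1] if isinstance(outs, list) else outs
            preds.append(np.argmax(logits.data, axis=1))
    return np.concatenate(preds) if preds else np.zeros(0, dtype=np.int64)


def accuracy(model: Module, images: np.ndarray, labels: np.ndarray,
             batch_size: int = 64) -> float:
    preds = predict_final(model, images, batch_size)
    return float((preds == labels).mean()) if len(labels) else float("nan")
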