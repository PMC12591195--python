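"""Seeded training loop, evaluation metrics and augmentation pipeline.

Training minimizes the composite loss with a decoupled-weight-decay adaptive
optimizer (AdamW) under a cosine learning-rate schedule.  All randomness —
shuffling, augmentation draws, parameter init — flows from the single seed
in :class:`TrainConfig`, and the numpy/float64 engine makes runs
bit-reproducible.  Augmentations (random resized crop, horizontal flip,
intensity jitter) apply only on the training path; by default the contour
prior is recomputed from the augmented image so the memory always describes
what the network actually sees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage.transform import resize

from .ltm import build_ltm0
from .model import Prediction, VcogmConfig, VcogmModel, composite_loss

__all__ = ["TrainConfig", "EvalReport", "Adamw", "train", "evaluate", "augment_image"]

_AUGS = ("random_resized_crop", "horizontal_flip", "color_jitter")


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 3e-3
    weight_decay: float = 0.01
    seed: int = 0
    augmentations: Sequence[str] = ()
    prior_policy: str = "recompute_after_augment"  # or "reuse_original"
    n1: int = 2
    n2: int = 2
    d: int = 4

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        for a in self.augmentations:
            if a not in _AUGS:
                raise ValueError(f"unknown augmentation {a!r}")
        if self.prior_policy not in ("recompute_after_augment", "reuse_original"):
            raise ValueError(f"unknown prior_policy {self.prior_policy!r}")


@dataclass
class EvalReport:
    top1: float
    confusion: np.ndarray  # (C, C) counts, rows = true class, cols = predicted


class Adamw:
    """Decoupled-weight-decay Adam over the model's parameter list."""

    def __init__(self, params, lr: float, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: Optional[float] = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)


def augment_image(img: np.ndarray, augs: Sequence[str], rng: np.random.Generator) -> np.ndarray:
    """Apply the configured augmentations to one [-1, 1] grayscale image."""
    out = img
    H, W = img.shape
    if "random_resized_crop" in augs:
        scale = rng.uniform(0.6, 1.0)
        ch, cw = max(8, int(H * scale)), max(8, int(W * scale))
        y0 = rng.integers(0, H - ch + 1)
        x0 = rng.integers(0, W - cw + 1)
        crop = out[y0 : y0 + ch, x0 : x0 + cw]
        out = resize(crop, (H, W), order=1, mode="reflect", anti_aliasing=False)
    if "horizontal_flip" in augs and rng.random() < 0.5:
        out = out[:, ::-1]
    if "color_jitter" in augs:
        contrast = rng.uniform(0.8, 1.2)
        brightness = rng.uniform(-0.1, 0.1)
        out = out * contrast + brightness
    return np.clip(out, -1.0, 1.0)


def _cosine_lr(base: float, step: int, total: int) -> float:
    return base * 0.5 * (1.0 + np.cos(np.pi * step / max(1, total)))


def _batch_priors(images: np.ndarray, cfg: TrainConfig) -> np.ndarray:
    return np.stack(
        [build_ltm0(im, cfg.n1, cfg.n2, cfg.d).maps for im in images]
    )


def train(
    model: VcogmModel,
    dataset: Sequence[tuple[np.ndarray, int]],
    cfg: TrainConfig,
    priors: Optional[Sequence[np.ndarray]] = None,
    log: Optional[list] = None,
):
    """Seeded mini-batch optimization of the composite loss.

    ``dataset`` yields ``(image, label)`` pairs of [-1, 1] grayscale arrays.
    Pre-computed priors may be supplied; with the default
    ``recompute_after_augment`` policy they are rebuilt from each augmented
    image instead.  Returns ``(model, loss_curve)`` with one mean loss per
    epoch; per-epoch records are appended to ``log`` when given.
    """
    images = np.stack([im for im, _ in dataset])
    labels = np.array([lab for _, lab in dataset], dtype=np.int64)
    N = len(labels)
    if priors is None:
        base_priors = _batch_priors(images, cfg)
    else:
        base_priors = np.stack(list(priors))
    rng = np.random.default_rng(cfg.seed)
    opt = Adamw(model.parameters(), cfg.learning_rate, cfg.weight_decay)
    steps_per_epoch = (N + cfg.batch_size - 1) // cfg.batch_size
    total_steps = cfg.epochs * steps_per_epoch
    curve: list[float] = []
    model.train()
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(N)
        losses = []
        correct = 0
        for b in range(steps_per_epoch):
            idx = order[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            batch_imgs = images[idx]
            if cfg.augmentations:
                batch_imgs = np.stack(
                    [augment_image(im, cfg.augmentations, rng) for im in batch_imgs]
                )
            if cfg.augmentations and cfg.prior_policy == "recompute_after_augment":
                batch_priors = _batch_priors(batch_imgs, cfg)
            else:
                batch_priors = base_priors[idx]
            pred = model.forward(batch_imgs, batch_priors)
            loss = composite_loss(pred, labels[idx], model.cfg)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {b}: {loss.data}"
                )
            model.zero_grad()
            loss.backward()
            opt.step(lr=_cosine_lr(cfg.learning_rate, step, total_steps))
            step += 1
            losses.append(float(loss.data))
            correct += int(
                (pred.class_probs.data.argmax(axis=1) == labels[idx]).sum()
            )
        epoch_loss = float(np.mean(losses))
        curve.append(epoch_loss)
        if log is not None:
            log.append(
                {"epoch": epoch, "loss": epoch_loss, "train_top1": correct / N}
            )
    return model, curve


def evaluate(
    model: VcogmModel,
    dataset: Sequence[tuple[np.ndarray, int]],
    priors: Optional[Sequence[np.ndarray]] = None,
    prior_cfg: Optional[TrainConfig] = None,
    batch_size: int = 16,
) -> EvalReport:
    """Single augmentation-free pass: top-1 accuracy and confusion matrix."""
    if len(dataset) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    images = np.stack([im for im, _ in dataset])
    labels = np.array([lab for _, lab in dataset], dtype=np.int64)
    if priors is None:
        prior_cfg = prior_cfg or TrainConfig()
        priors = _batch_priors(images, prior_cfg)
    else:
        priors = np.stack(list(priors))
    C = model.cfg.num_classes
    confusion = np.zeros((C, C), dtype=np.int64)
    was_training = model.training
    model.eval()
    try:
        for start in range(0, len(labels), batch_size):
            sl = slice(start, start + batch_size)
            pred = model.forward(images[sl], priors[sl])
            hats = pred.class_probs.data.argmax(axis=1)
            for t, p in zip(labels[sl], hats):
                confusion[t, p] += 1
    finally:
        if was_training:
            model.train()
    top1 = float(np.trace(confusion) / confusion.sum())
    return EvalReport(top1=top1, confusion=confusion)
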