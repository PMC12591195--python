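"""The VCogM classifier: VCNU stages over a patch-embedding stem, seeded by a
per-image UMA contour prior, trained with a memory-supervised composite loss.

The stem embeds non-overlapping ``p x p`` patches (``p`` equal to the prior
downsampling factor ``d``, so the prior grid aligns with stage-1 features).
Each stage threads ``(FeatureMap, LtmState)`` through its blocks; between
stages both are spatially halved by average pooling and channel-adapted by
1x1 linear maps.  A global-average-pooled linear head over the final feature
map yields class probabilities; in ``memory_head`` mode an auxiliary pooled
head over the final memory state yields a second distribution used for
auxiliary supervision.

The composite loss adds to the standard cross-entropy a 0.5-weighted memory
term.  Two readings are provided: ``literal`` re-uses the class
probabilities with the memory label equal to the true label (the loss is
then exactly 1.5x cross-entropy), while ``memory_head`` supervises the
auxiliary memory head with the true label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .autograd import Module, Parameter, Tensor, gather_rows, trunc_normal
from .vcnu import VcnuBlock, VcnuConfig

__all__ = ["VcogmConfig", "Prediction", "VcogmModel", "composite_loss", "softmax"]


@dataclass
class VcogmConfig:
    stage_depths: Sequence[int] = (1, 1)
    stage_channels: Sequence[int] = (8, 16)
    memory_channels: Sequence[int] = (4, 4)
    stem_downsample: int = 4
    num_classes: int = 2
    j: int = 2
    ffn_ratio: float = 4.0
    loss_mode: str = "memory_head"  # or "literal"
    memory_loss_weight: float = 0.5
    enable_p: bool = True
    enable_m: bool = True
    enable_a: bool = True
    enable_u: bool = True
    enable_n: bool = True

    def __post_init__(self):
        if not (len(self.stage_depths) == len(self.stage_channels) == len(self.memory_channels)):
            raise ValueError("stage lists must have equal length")
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.memory_loss_weight < 0:
            raise ValueError("memory_loss_weight must be non-negative")
        if self.loss_mode not in ("literal", "memory_head"):
            raise ValueError(f"unknown loss_mode {self.loss_mode!r}")


@dataclass
class Prediction:
    """Class probabilities (B, C), plus the memory head's (B, C) if enabled."""

    class_probs: Tensor
    memory_probs: Optional[Tensor] = None


def softmax(logits: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(logits.data.max(axis=axis, keepdims=True))
    e = (logits - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


class _Linear(Module):
    def __init__(self, out_dim: int, in_dim: int, rng: np.random.Generator):
        super().__init__()
        self.W = Parameter(trunc_normal((out_dim, in_dim), rng))
        self.b = Parameter(np.zeros(out_dim))

    def forward(self, x: Tensor) -> Tensor:
        # x: (B, in) -> (B, out)
        return x @ self.W.transpose(1, 0) + self.b


class _ChannelLinear(Module):
    """1x1 linear over the channel axis of (B, C, L) tensors."""

    def __init__(self, out_ch: int, in_ch: int, rng: np.random.Generator):
        super().__init__()
        self.W = Parameter(trunc_normal((out_ch, in_ch), rng))
        self.b = Parameter(np.zeros((out_ch, 1)))

    def forward(self, x: Tensor) -> Tensor:
        return self.W @ x + self.b


class _PatchEmbed(Module):
    """Non-overlapping patch embedding: (B, 1, H, W) -> (B, D, H/p, W/p)."""

    def __init__(self, D: int, p: int, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.proj = _ChannelLinear(D, p * p, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        p = self.p
        if H % p or W % p:
            raise ValueError(f"input {H}x{W} not divisible by stem factor {p}")
        h, w = H // p, W // p
        # (B,1,H,W) -> (B, p*p, h*w) with patch pixels along the channel axis
        t = x.reshape(B, h, p, w, p).transpose(0, 2, 4, 1, 3).reshape(B, p * p, h * w)
        return self.proj.forward(t).reshape(B, -1, h, w)


def _avg_pool2(t: Tensor) -> Tensor:
    """2x spatial average pooling of a (B, C, H, W) tensor."""
    B, C, H, W = t.shape
    return (
        t.reshape(B, C, H // 2, 2, W // 2, 2)
        .mean(axis=(3, 5))
        .reshape(B, C, H // 2, W // 2)
    )


class VcogmModel(Module):
    """Hierarchical memory-augmented classifier over VCNU blocks."""

    def __init__(self, cfg: VcogmConfig, prior_channels: int, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        D0, n0 = cfg.stage_channels[0], cfg.memory_channels[0]
        self.stem = _PatchEmbed(D0, cfg.stem_downsample, rng)
        self.prior_channels = prior_channels
        self.prior_adapter = (
            _ChannelLinear(n0, prior_channels, rng) if prior_channels != n0 else None
        )
        self.stages: list[list[VcnuBlock]] = []
        self.x_downs: list[_ChannelLinear] = []
        self.m_downs: list[_ChannelLinear] = []
        for s, (depth, D, n) in enumerate(
            zip(cfg.stage_depths, cfg.stage_channels, cfg.memory_channels)
        ):
            block_cfg = VcnuConfig(
                D=D,
                j=cfg.j,
                n=n,
                ffn_ratio=cfg.ffn_ratio,
                enable_p=cfg.enable_p,
                enable_m=cfg.enable_m,
                enable_a=cfg.enable_a,
                enable_u=cfg.enable_u,
                enable_n=cfg.enable_n,
            )
            self.stages.append([VcnuBlock(block_cfg, rng) for _ in range(depth)])
            if s + 1 < len(cfg.stage_depths):
                self.x_downs.append(
                    _ChannelLinear(cfg.stage_channels[s + 1], D, rng)
                )
                self.m_downs.append(
                    _ChannelLinear(cfg.memory_channels[s + 1], n, rng)
                )
        self.head = _Linear(cfg.num_classes, cfg.stage_channels[-1], rng)
        self.memory_head = (
            _Linear(cfg.num_classes, cfg.memory_channels[-1], rng)
            if cfg.loss_mode == "memory_head"
            else None
        )

    def forward(self, images: np.ndarray, priors: np.ndarray) -> Prediction:
        """Run a batch.

        ``images``: (B, H, W) grayscale in [-1, 1]; ``priors``: the per-image
        LTM_0 stacks, (B, n_prior, H/d, W/d), matching the stem output grid.
        """
        images = np.asarray(images, dtype=np.float64)
        priors = np.asarray(priors, dtype=np.float64)
        B, H, W = images.shape
        x = self.stem.forward(Tensor(images[:, None]))
        _, _, h, w = x.shape
        if priors.shape[-2:] != (h, w):
            raise ValueError(
                f"prior grid {priors.shape[-2:]} does not match stem output {(h, w)}"
            )
        ltm = Tensor(priors.reshape(B, priors.shape[1], h * w))
        if self.prior_adapter is not None:
            ltm = self.prior_adapter.forward(ltm)
        for s, blocks in enumerate(self.stages):
            for block in blocks:
                x, ltm = block.forward(x, ltm)
            if s + 1 < len(self.stages):
                Bc, C, hs, ws = x.shape
                x = _avg_pool2(x)
                x = self.x_downs[s].forward(x.reshape(Bc, C, -1)).reshape(
                    Bc, -1, hs // 2, ws // 2
                )
                n = ltm.shape[1]
                ltm = _avg_pool2(ltm.reshape(Bc, n, hs, ws))
                ltm = self.m_downs[s].forward(ltm.reshape(Bc, n, -1))
        B_, D, h_, w_ = x.shape
        pooled = x.reshape(B_, D, h_ * w_).mean(axis=2)
        probs = softmax(self.head.forward(pooled), axis=1)
        mem_probs = None
        if self.memory_head is not None:
            mem_pooled = ltm.mean(axis=2)
            mem_probs = softmax(self.memory_head.forward(mem_pooled), axis=1)
        return Prediction(class_probs=probs, memory_probs=mem_probs)


def _cross_entropy(probs: Tensor, labels: np.ndarray) -> Tensor:
    return -gather_rows(probs.log(), labels).mean()


def composite_loss(pred: Prediction, labels: np.ndarray, cfg: VcogmConfig) -> Tensor:
    """Cross-entropy plus the 0.5-weighted memory supervision term.

    ``literal`` mode: the memory label equals the true label and both terms
    use the class probabilities, so the loss is exactly
    ``1.5 x cross_entropy``.  ``memory_head`` mode: the auxiliary memory
    head is supervised with the true label at weight
    ``cfg.memory_loss_weight``.
    """
    labels = np.asarray(labels, dtype=np.int64)
    C = pred.class_probs.shape[1]
    if labels.min() < 0 or labels.max() >= C:
        raise ValueError(f"labels must lie in [0, {C})")
    ce = _cross_entropy(pred.class_probs, labels)
    if cfg.loss_mode == "literal":
        return ce * 1.5
    if pred.memory_probs is None:
        raise RuntimeError("memory_head loss mode requires memory_probs in the prediction")
    return ce + cfg.memory_loss_weight * _cross_entropy(pred.memory_probs, labels)
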