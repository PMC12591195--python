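"""The visual cognitive neural unit (VCNU) and its five operators.

The block follows a dual-input / dual-output computation graph modeling a
closed-loop attention-memory system:

* **P** (perceive) — multi-scale bottom-up perception: the channels are
  split into ``j`` groups, group ``i`` convolved with its own
  ``(2i+1) x (2i+1)`` kernel, results concatenated.
* **M** (recall) — top-down retrieval: a linear map ``W_m in R^{D x n}``
  reconstructs a working memory WM from the long-term memory state
  ``LTM_t in R^{n x HW}``.
* **A** (attend) — biased competition between the two attention sources:
  ``Attn = W_a @ GeLU(Norm([WM; MP])) + b`` with per-channel batch
  normalization over the concatenated ``2D`` channels.
* **U** (update) — memory encoding with slow, forgetful updates:
  ``LTM_{t+1} = GeLU(W_u @ Attn + LTM_t)``, a compression since ``n < D``.
* **N** (analyze) — position-wise feed-forward refinement of ``Attn``.

``vcnu_forward`` threads ``(x, LTM_t) -> (y, LTM_{t+1})``; the M/A/U loop on
its own (wrapped around an arbitrary base operator) is the prior-based
memory (PBM) plug-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Module, Parameter, Tensor, concat, conv2d, trunc_normal

__all__ = [
    "VcnuConfig",
    "Perceive",
    "Recall",
    "BatchNorm1d",
    "Attend",
    "UpdateMemory",
    "Analyze",
    "VcnuBlock",
    "PbmWrapper",
    "pbm_wrap",
]


@dataclass
class VcnuConfig:
    """Structural configuration of one block.

    ``D`` feature channels are split into ``j`` perception branches (kernel
    sizes 3, 5, ..., 2j+1); the memory carries ``n < D`` channels; the
    feed-forward analyzer expands by ``ffn_ratio``.  The ``enable_*`` flags
    implement single-operator ablations: a disabled operator contributes no
    parameters and its stage reduces to a pass-through (see
    :meth:`VcnuBlock.forward`).
    """

    D: int
    j: int = 2
    n: int = 4
    ffn_ratio: float = 4.0
    bias: bool = True
    enable_p: bool = True
    enable_m: bool = True
    enable_a: bool = True
    enable_u: bool = True
    enable_n: bool = True

    def __post_init__(self):
        if self.D % self.j != 0:
            raise ValueError(f"channel count D={self.D} not divisible by j={self.j}")
        if not self.n < self.D:
            raise ValueError(f"memory channels n={self.n} must be < D={self.D}")


class Perceive(Module):
    """P: j parallel grouped convolutions with kernel sizes 2i+1."""

    def __init__(self, cfg: VcnuConfig, rng: np.random.Generator):
        super().__init__()
        self.j = cfg.j
        self.Dg = cfg.D // cfg.j
        self.kernels = [
            Parameter(trunc_normal((self.Dg, self.Dg, 2 * i + 1, 2 * i + 1), rng))
            for i in range(1, cfg.j + 1)
        ]
        self.bias = Parameter(np.zeros((cfg.D, 1, 1))) if cfg.bias else None

    def forward(self, x: Tensor) -> Tensor:
        outs = []
        for i, w in enumerate(self.kernels):
            xi = x[:, i * self.Dg : (i + 1) * self.Dg]
            outs.append(conv2d(xi, w))
        out = concat(outs, axis=1)
        if self.bias is not None:
            out = out + self.bias
        return out


class Recall(Module):
    """M: WM = W_m @ LTM_t + b, a linear reconstruction of working memory."""

    def __init__(self, D: int, n: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.W_m = Parameter(trunc_normal((D, n), rng))
        self.bias = Parameter(np.zeros((D, 1))) if bias else None

    def forward(self, ltm: Tensor) -> Tensor:
        out = self.W_m @ ltm
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm1d(Module):
    """Per-channel normalization over batch and positions for (B, C, L) input.

    Training mode uses batch statistics and maintains exponential running
    estimates; inference mode requires the running statistics and raises if
    none were ever accumulated.
    """

    def __init__(self, C: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones((C, 1)))
        self.beta = Parameter(np.zeros((C, 1)))
        self.running_mean = np.zeros((C, 1))
        self.running_var = np.ones((C, 1))
        self.initialized = False

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=(0, 2), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data[0]
            self.running_var = (1 - m) * self.running_var + m * var.data[0]
            self.initialized = True
            xhat = (x - mu) * (var + self.eps).pow(-0.5)
        else:
            if not self.initialized:
                raise RuntimeError(
                    "batch norm has no running statistics; run at least one "
                    "training batch before inference"
                )
            mu = Tensor(self.running_mean[None])
            var = Tensor(self.running_var[None])
            xhat = (x - mu) * (var + self.eps).pow(-0.5)
        return xhat * self.gamma + self.beta


class Attend(Module):
    """A: Attn = W_a @ GeLU(Norm([WM; MP])) + b."""

    def __init__(self, D: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.norm = BatchNorm1d(2 * D)
        self.W_a = Parameter(trunc_normal((D, 2 * D), rng))
        self.bias = Parameter(np.zeros((D, 1))) if bias else None

    def forward(self, wm: Tensor, mp: Tensor) -> Tensor:
        z = concat([wm, mp], axis=1)
        z = self.norm.forward(z).gelu()
        out = self.W_a @ z
        if self.bias is not None:
            out = out + self.bias
        return out


class UpdateMemory(Module):
    """U: LTM_{t+1} = GeLU(W_u @ Attn + LTM_t)."""

    def __init__(self, D: int, n: int, rng: np.random.Generator):
        super().__init__()
        self.W_u = Parameter(trunc_normal((n, D), rng))

    def forward(self, attn: Tensor, ltm: Tensor) -> Tensor:
        return (self.W_u @ attn + ltm).gelu()


class Analyze(Module):
    """N: position-wise two-layer feed-forward network with GeLU."""

    def __init__(self, D: int, ratio: float, rng: np.random.Generator):
        super().__init__()
        hidden = max(1, int(round(ratio * D)))
        self.W1 = Parameter(trunc_normal((hidden, D), rng))
        self.b1 = Parameter(np.zeros((hidden, 1)))
        self.W2 = Parameter(trunc_normal((D, hidden), rng))
        self.b2 = Parameter(np.zeros((D, 1)))

    def forward(self, attn: Tensor) -> Tensor:
        return self.W2 @ (self.W1 @ attn + self.b1).gelu() + self.b2


class VcnuBlock(Module):
    """One dual-input / dual-output cognitive block.

    ``forward`` maps a feature map ``x`` of shape (B, D, H, W) and a memory
    state of shape (B, n, HW) to an output feature map of the same shape and
    the updated memory.  Disabled operators degrade gracefully: without P,
    MP is the input itself; without M, WM is zero; without A, Attn is the
    plain sum WM + MP; without U the memory is passed through untouched;
    without N the output is Attn itself.
    """

    def __init__(self, cfg: VcnuConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.perceive = Perceive(cfg, rng) if cfg.enable_p else None
        self.recall = Recall(cfg.D, cfg.n, rng, cfg.bias) if cfg.enable_m else None
        self.attend = Attend(cfg.D, rng, cfg.bias) if cfg.enable_a else None
        self.update = UpdateMemory(cfg.D, cfg.n, rng) if cfg.enable_u else None
        self.analyze = Analyze(cfg.D, cfg.ffn_ratio, rng) if cfg.enable_n else None

    def _perception(self, x: Tensor) -> Tensor:
        return self.perceive.forward(x) if self.perceive is not None else x

    def forward(self, x: Tensor, ltm: Tensor) -> tuple[Tensor, Tensor]:
        B, D, H, W = x.shape
        mp = self._perception(x).reshape(B, D, H * W)
        if self.recall is not None:
            wm = self.recall.forward(ltm)
        else:
            wm = Tensor(np.zeros((B, D, H * W)))
        if self.attend is not None:
            attn = self.attend.forward(wm, mp)
        else:
            attn = wm + mp
        ltm_next = self.update.forward(attn, ltm) if self.update is not None else ltm
        y = self.analyze.forward(attn) if self.analyze is not None else attn
        return y.reshape(B, D, H, W), ltm_next


class PbmWrapper(Module):
    """Prior-based memory: the M/A/U closed loop around an arbitrary operator.

    The wrapped operator replaces the perception stage; recall, attention
    coupling, memory update and the feed-forward analyzer surround it,
    turning any channel-preserving feature extractor into a dual-input /
    dual-output memory-augmented block.  Wrapping strictly adds parameters
    ({W_m, W_a, W_u, norm affine, FFN}) on top of the base operator's own.
    """

    def __init__(self, base_op, cfg: VcnuConfig, rng: np.random.Generator):
        super().__init__()
        self.base_op = base_op if isinstance(base_op, Module) else None
        self._base_fn = base_op if not isinstance(base_op, Module) else None
        self.cfg = cfg
        self.recall = Recall(cfg.D, cfg.n, rng, cfg.bias)
        self.attend = Attend(cfg.D, rng, cfg.bias)
        self.update = UpdateMemory(cfg.D, cfg.n, rng) if cfg.enable_u else None
        self.analyze = Analyze(cfg.D, cfg.ffn_ratio, rng)

    def forward(self, x: Tensor, ltm: Tensor) -> tuple[Tensor, Tensor]:
        B, D, H, W = x.shape
        base = self.base_op.forward(x) if self.base_op is not None else self._base_fn(x)
        if base.shape[1] != self.cfg.D:
            raise ValueError(
                f"base operator produced {base.shape[1]} channels, "
                f"config expects {self.cfg.D}"
            )
        mp = base.reshape(B, D, H * W)
        wm = self.recall.forward(ltm)
        attn = self.attend.forward(wm, mp)
        ltm_next = self.update.forward(attn, ltm) if self.update is not None else ltm
        y = self.analyze.forward(attn)
        return y.reshape(B, D, H, W), ltm_next


def pbm_wrap(base_op, cfg: VcnuConfig, rng: np.random.Generator | int = 0) -> PbmWrapper:
    """Wrap a channel-preserving operator with the prior-based memory loop."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    return PbmWrapper(base_op, cfg, rng)
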